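"""Orchestration: train → classify → report → evaluate on file-based I/O.

Binds the feature, scheduler, HMM and EDA modules into the end-to-end
workflow: labeled sequences are built by pairing each answered questionnaire
prompt with the observation assembled from the last valid probe readings,
split chronologically into train/test, fitted by supervised counting, and
the fitted model then scores raw context streams into context triplets.
Daily statistics and an EDA agreement report provide the visualization and
clinical-evaluation outputs as plain CSV/JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Sequence

import numpy as np
import pandas as pd

from . import eda as eda_mod
from .features import (
    PROBE_ORDER,
    DiscretizationConfig,
    ObservationVector,
    build_observation,
    observations_to_frame,
)
from .stress_hmm import (
    ContextTriplet,
    LabeledSequence,
    StressHMM,
    classify,
    supervised_fit,
)

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400.0


@dataclass
class RunConfig:
    """Flat settings document mirrored by the YAML config file."""

    lookback_seconds: float = 900.0
    hmm_mode: str = "factorized"
    smoothing_alpha: float = 1.0
    window_size: int = 4
    train_fraction: float = 0.7
    timezone_offset_hours: float = 0.0
    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def build_labeled_sequences(
    events,
    responses: pd.DataFrame,
    config: RunConfig,
) -> list[tuple[float, ObservationVector, int]]:
    """Pair each answered prompt with its last-valid-features observation.

    Returns time-sorted ``(prompt_time, observation, label)`` triples;
    unanswered prompts are dropped.
    """
    answered = responses[responses["answered"].astype(bool)].dropna(subset=["label"])
    out = []
    for row in answered.itertuples():
        t = float(row.prompt_time)
        obs = build_observation(events, t, config.lookback_seconds, config.discretization)
        out.append((t, obs, int(row.label)))
    out.sort(key=lambda r: r[0])
    return out


def _group_by_day(items: Sequence[tuple[float, object]], offset_s: float = 0.0):
    by_day: dict[int, list] = {}
    for t, item in items:
        by_day.setdefault(int((t + offset_s) // SECONDS_PER_DAY), []).append(item)
    return [by_day[d] for d in sorted(by_day)]


@dataclass
class TrainReport:
    n_train: int
    n_test: int
    exact_accuracy: float | None
    within_one_accuracy: float | None


def run_train(
    events,
    responses: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[StressHMM, TrainReport]:
    """Fit the tension HMM on a chronological split of the labeled prompts.

    The earliest ``train_fraction`` of answered prompts forms the training
    set (one labeled sequence per calendar day, preserving within-day
    transition structure); the remainder is held out and scored with
    windowed Viterbi classification to report exact and within-±1 accuracy
    against the held-out labels.
    """
    config = config or RunConfig()
    labeled = build_labeled_sequences(events, responses, config)
    if len(labeled) < 2:
        raise ValueError("insufficient labels: need at least 2 answered prompts")
    n_train = max(1, int(round(config.train_fraction * len(labeled))))
    train, test = labeled[:n_train], labeled[n_train:]
    if len(train) < 2:
        raise ValueError("insufficient labels in the training split")

    day_seqs = _group_by_day([(t, (obs, lab)) for t, obs, lab in train])
    sequences = [
        LabeledSequence(observations=[o for o, _ in day], labels=[l for _, l in day])
        for day in day_seqs
    ]
    model = supervised_fit(sequences, alpha=config.smoothing_alpha, mode=config.hmm_mode)

    exact = within_one = None
    if test:
        obs_seq = [obs for _, obs, _ in test]
        triplets = classify(model, obs_seq, window_size=config.window_size)
        pred = np.array([tr.tension_score for tr in triplets])
        truth = np.array([lab for _, _, lab in test])
        exact = float(np.mean(pred == truth))
        within_one = float(np.mean(np.abs(pred - truth) <= 1))
    return model, TrainReport(
        n_train=len(train), n_test=len(test), exact_accuracy=exact, within_one_accuracy=within_one
    )


def run_classify(
    events,
    model: StressHMM,
    config: RunConfig | None = None,
    eval_times: Sequence[float] | None = None,
) -> list[ContextTriplet]:
    """Score a context stream into context triplets.

    Consumes only probe events — never questionnaire responses (after
    training the system requires no further user input).  By default one
    evaluation per distinct event timestamp; pass ``eval_times`` for a
    custom cadence.
    """
    config = config or RunConfig()
    if tuple(model.probe_order) != tuple(PROBE_ORDER):
        raise ValueError("model probe order does not match the configured probe order")
    if eval_times is None:
        eval_times = sorted({e.timestamp for e in events})
    observations = [
        build_observation(events, t, config.lookback_seconds, config.discretization)
        for t in eval_times
    ]
    return classify(model, observations, window_size=config.window_size)


@dataclass
class DailyStats:
    """Per-calendar-day tension summaries for visualization."""

    date: str
    mean: float
    minimum: int
    maximum: int
    mode: int
    counts: dict[int, int]
    triplets: list[ContextTriplet]


def daily_stats(
    triplets: Sequence[ContextTriplet], timezone_offset_hours: float = 0.0
) -> list[DailyStats]:
    """Group triplets by calendar day and summarize the tension scores."""
    if not triplets:
        raise ValueError("no triplets to summarize")
    offset = timezone_offset_hours * 3600.0
    by_day: dict[int, list[ContextTriplet]] = {}
    for tr in triplets:
        by_day.setdefault(int((tr.timestamp + offset) // SECONDS_PER_DAY), []).append(tr)
    out = []
    for day in sorted(by_day):
        day_triplets = by_day[day]
        scores = np.array([tr.tension_score for tr in day_triplets])
        counts = {s: int(np.sum(scores == s)) for s in range(1, 8)}
        date = datetime.fromtimestamp(day * SECONDS_PER_DAY, tz=timezone.utc).date().isoformat()
        out.append(
            DailyStats(
                date=date,
                mean=float(scores.mean()),
                minimum=int(scores.min()),
                maximum=int(scores.max()),
                mode=int(np.bincount(scores, minlength=8)[1:].argmax() + 1),
                counts=counts,
                triplets=day_triplets,
            )
        )
    return out


def daily_stats_to_chart_json(stats: Sequence[DailyStats]) -> dict:
    """Chart-ready JSON: an upper daily-summary series plus per-day drilldown."""
    return {
        "daily": [
            {
                "date": s.date,
                "mean": s.mean,
                "min": s.minimum,
                "max": s.maximum,
                "mode": s.mode,
                "counts": {str(k): v for k, v in s.counts.items()},
            }
            for s in stats
        ],
        "drilldown": {
            s.date: [
                {
                    "timestamp": tr.timestamp,
                    "tension_score": tr.tension_score,
                    "observation": list(tr.observation.values),
                }
                for tr in s.triplets
            ]
            for s in stats
        },
    }


def triplets_to_frame(triplets: Sequence[ContextTriplet]) -> pd.DataFrame:
    frame = observations_to_frame([tr.observation for tr in triplets])
    frame.insert(1, "tension_score", [tr.tension_score for tr in triplets])
    return frame


def run_evaluate(
    rec: eda_mod.EDARecording,
    labels: Sequence[tuple[float, int]],
    window: float = 900.0,
) -> dict:
    """Run the full EDA chain and compare indicators against tension labels.

    Flags artifacts, decomposes the signal, detects and mask-filters SCRs,
    estimates the baseline, attributes SCRs to the label prompts (stimulus
    proxies), and reports rank agreement plus an exportable aligned-series
    table (tonic, phasic, detected peaks, label markers).
    """
    mask = eda_mod.flag_artifacts(rec)
    deco = eda_mod.decompose(rec)
    events = eda_mod.detect_scrs(deco.phasic, rec, mask=mask)
    try:
        baseline = eda_mod.find_baseline(rec, mask, decomposition=deco, events=events)
    except eda_mod.InsufficientCleanDataError as err:
        logger.warning("baseline estimation failed (%s); using unnormalized amplitudes", err)
        baseline = None
    events = eda_mod.attribute_scrs(events, [t for t, _ in labels])
    t_lo, t_hi = rec.times[0], rec.times[-1]
    usable = [(t, lab) for t, lab in labels if t_lo <= t <= t_hi]
    skipped_out_of_range = len(labels) - len(usable)
    if skipped_out_of_range:
        logger.warning("%d labels outside the recording span were skipped", skipped_out_of_range)
    report = eda_mod.compare_labels(events, usable, window=window, baseline=baseline, mask=mask, rec=rec)
    return {
        "agreement": {
            "rate_spearman": report.rate_spearman,
            "rate_pvalue": report.rate_pvalue,
            "height_spearman": report.height_spearman,
            "height_pvalue": report.height_pvalue,
            "bias": report.bias,
            "n_labels_used": report.n_labels_used,
            "n_labels_skipped": report.n_labels_skipped + skipped_out_of_range,
        },
        "per_label": report.per_label,
        "events": events,
        "baseline": baseline,
        "series": pd.DataFrame(
            {
                "time": rec.times,
                "conductance_uS": rec.conductance,
                "tonic_uS": deco.tonic,
                "phasic_uS": deco.phasic,
                "artifact": mask.mask.astype(int),
            }
        ),
        "reconstruction_rmse": deco.rmse,
    }


def write_evaluation(result: dict, prefix: str) -> None:
    """Write the evaluation outputs: agreement JSON, SCR table, aligned series."""
    with open(f"{prefix}_agreement.json", "w") as fh:
        json.dump(result["agreement"], fh, indent=2)
    eda_mod.scr_events_to_frame(result["events"]).to_csv(f"{prefix}_scrs.csv", index=False)
    result["series"].to_csv(f"{prefix}_series.csv", index=False)
    result["per_label"].to_csv(f"{prefix}_labels.csv", index=False)
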