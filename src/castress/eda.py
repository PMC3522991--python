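"""Electrodermal activity analysis: tonic/phasic decomposition and SCRs.

Skin conductance (microsiemens, μS) is modeled as a slowly varying tonic
level (SCL) plus a train of phasic skin conductance responses (SCRs), each
the convolution of a non-negative sudomotor driver impulse with a
biexponential (Bateman-shaped) kernel ``k(t) = exp(-t/tau2) - exp(-t/tau1)``,
``tau1 < tau2``, normalized to unit peak so driver impulses are in μS of
response amplitude.

The decomposition is a two-pass nonnegative deconvolution: a coarse tonic
estimate (rolling low-percentile, smoothed) is subtracted, the residual is
fit by sparse nonnegative least squares against the kernel, the slow
component of the fitted phasic signal is leaked back into the tonic
estimate, and the deconvolution is repeated on the corrected residual.  The
second pass keeps the driver near zero for purely tonic drifts while leaving
genuine transients intact.

SCR peaks are detected on the phasic component with a minimum-prominence
rule; each event carries the standard morphology: onset, peak, amplitude,
rise time (onset to peak) and half-recovery time (peak to 50% amplitude
decay).  Events are attributed to stimuli whose onset precedes the SCR
onset by 1.5–6.5 s (the conventional latency window).  Motion and
temperature artifacts, flagged from the co-recorded accelerometer and
thermometer channels, mask both detection and baseline estimation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

logger = logging.getLogger(__name__)


class InsufficientCleanDataError(ValueError):
    """No artifact-free window qualifies for baseline estimation."""


@dataclass
class EDARecording:
    """Regularly sampled skin conductance with accelerometer and temperature.

    ``conductance`` in μS, ``accel`` as an (N, 3) array in g, ``temperature``
    in °C, all sampled at ``sampling_rate`` Hz starting at ``start_time``
    (epoch seconds).
    """

    sampling_rate: float
    conductance: np.ndarray
    accel: np.ndarray
    temperature: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.conductance = np.asarray(self.conductance, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        n = len(self.conductance)
        if self.accel.shape != (n, 3):
            raise ValueError(f"accel must be ({n}, 3), got {self.accel.shape}")
        if len(self.temperature) != n:
            raise ValueError("temperature length must match conductance")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if np.any(self.conductance < 0):
            raise ValueError("conductance must be non-negative")

    def __len__(self) -> int:
        return len(self.conductance)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) / self.sampling_rate

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# start_time={self.start_time}\n")
            fh.write(f"# sampling_rate_hz={self.sampling_rate}\n")
            pd.DataFrame(
                {
                    "eda_uS": self.conductance,
                    "accel_x": self.accel[:, 0],
                    "accel_y": self.accel[:, 1],
                    "accel_z": self.accel[:, 2],
                    "temp_C": self.temperature,
                }
            ).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "EDARecording":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition("=")
                    meta[key.strip()] = float(value)
                    pos = fh.tell()
                else:
                    fh.seek(pos)
                    break
            df = pd.read_csv(fh)
        return cls(
            sampling_rate=meta.get("sampling_rate_hz", 4.0),
            conductance=df["eda_uS"].to_numpy(),
            accel=df[["accel_x", "accel_y", "accel_z"]].to_numpy(),
            temperature=df["temp_C"].to_numpy(),
            start_time=meta.get("start_time", 0.0),
        )


@dataclass
class SCREvent:
    """One skin conductance response with its morphology.

    ``amplitude`` is the phasic rise from onset to peak (μS); ``rise_time``
    the onset-to-peak interval; ``half_recovery_time`` the peak-to-50%-decay
    interval (None when a following SCR overlaps the recovery); ``latency``
    the stimulus-onset-to-SCR-onset interval, set only once attributed.
    """

    onset_time: float
    peak_time: float
    amplitude: float
    rise_time: float
    half_recovery_time: float | None = None
    latency: float | None = None
    attributed_stimulus: int | None = None

    def __post_init__(self) -> None:
        if self.peak_time <= self.onset_time:
            raise ValueError("peak_time must be after onset_time")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if abs(self.rise_time - (self.peak_time - self.onset_time)) > 1e-9:
            raise ValueError("rise_time must equal peak_time - onset_time")


@dataclass
class BaselineEstimate:
    """Rest-condition extremes of the tonic level plus the maximal SCR.

    ``scl_min`` is the mean tonic level of the lowest smooth artifact-free
    window (the rest baseline), ``scl_max`` of the highest; ``scr_max`` the
    largest detected SCR amplitude.
    """

    scl_min: float
    scl_max: float
    scr_max: float
    min_window: tuple[float, float]
    max_window: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.scl_min < self.scl_max:
            raise ValueError("scl_min must be < scl_max")
        if self.scr_max <= 0:
            raise ValueError("scr_max must be positive")


@dataclass
class ArtifactMask:
    """Per-sample artifact flags aligned to a recording."""

    mask: np.ndarray
    motion: np.ndarray
    temperature: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.motion = np.asarray(self.motion, dtype=bool)
        self.temperature = np.asarray(self.temperature, dtype=bool)
        if not len(self.mask) == len(self.motion) == len(self.temperature):
            raise ValueError("mask channels must have equal length")


@dataclass
class Decomposition:
    """Result of the tonic/phasic split: ``conductance ≈ tonic + phasic``."""

    tonic: np.ndarray
    driver: np.ndarray
    phasic: np.ndarray
    rmse: float
    kernel: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Artifact masking
# ---------------------------------------------------------------------------


def flag_artifacts(
    rec: EDARecording,
    accel_threshold: float = 0.2,
    temp_range: tuple[float, float] = (30.0, 37.0),
    dilation: float = 5.0,
) -> ArtifactMask:
    """Flag motion and temperature artifacts, dilated by ±``dilation`` s.

    A sample is motion-flagged when the acceleration magnitude deviates from
    the recording's median (the gravity baseline) by more than
    ``accel_threshold`` g, and temperature-flagged when the thermometer
    leaves ``temp_range`` °C.
    """
    if accel_threshold <= 0 or dilation < 0:
        raise ValueError("accel_threshold must be positive, dilation non-negative")
    lo, hi = temp_range
    if not lo < hi:
        raise ValueError("temp_range must be a non-empty interval")
    mag = np.linalg.norm(rec.accel, axis=1)
    motion = np.abs(mag - np.median(mag)) > accel_threshold
    temp = (rec.temperature < lo) | (rec.temperature > hi)
    if dilation > 0:
        width = int(round(dilation * rec.sampling_rate))
        structure = np.ones(2 * width + 1, dtype=bool)
        motion = ndimage.binary_dilation(motion, structure=structure)
        temp = ndimage.binary_dilation(temp, structure=structure)
    return ArtifactMask(mask=motion | temp, motion=motion, temperature=temp)


# ---------------------------------------------------------------------------
# Nonnegative deconvolution
# ---------------------------------------------------------------------------


def scr_kernel(sampling_rate: float, tau1: float = 0.75, tau2: float = 2.0) -> np.ndarray:
    """Peak-normalized biexponential SCR kernel sampled at ``sampling_rate``.

    ``k(t) = exp(-t/tau2) - exp(-t/tau1)``, truncated where it falls below
    0.1% of its peak, scaled to unit peak so a unit driver impulse produces
    a 1 μS response amplitude.
    """
    if not 0 < tau1 < tau2:
        raise ValueError("require 0 < tau1 < tau2")
    # analytic support: decays with tau2; keep ~10 time constants
    t = np.arange(0, 10.0 * tau2, 1.0 / sampling_rate)
    k = np.exp(-t / tau2) - np.exp(-t / tau1)
    k /= k.max()
    keep = k >= 1e-3
    last = np.max(np.nonzero(keep))
    return k[: last + 1]


def _nnls_deconvolve(
    kernel: np.ndarray,
    residual: np.ndarray,
    regularization: float,
    max_iter: int = 4000,
    grad_tol: float = 1e-3,
) -> np.ndarray:
    """Nonnegative ridge-regularized deconvolution by accelerated projection.

    Minimizes ``||k * d - r||^2 + lam * ||d||^2`` over ``d >= 0`` with FISTA;
    the convolution operator is applied directly (FFT overlap-add), so cost
    is linear in the recording length.  The ridge term makes the objective
    strongly convex, giving linear convergence; iteration stops when the
    projected-gradient norm falls below ``grad_tol`` relative to its initial
    value.

    Raises
    ------
    RuntimeError
        If the projected gradient has not met the tolerance after
        ``max_iter`` iterations.
    """
    n = len(residual)
    kr = kernel[::-1]
    kl = len(kernel)

    def forward(x: np.ndarray) -> np.ndarray:
        return signal.oaconvolve(x, kernel)[:n]

    def adjoint(y: np.ndarray) -> np.ndarray:
        return signal.oaconvolve(y, kr)[kl - 1 : kl - 1 + n]

    lipschitz = kernel.sum() ** 2 + regularization
    # scale-aware absolute floor: gradients this small are numerically zero
    # relative to the data magnitude
    pg_floor = 1e-12 * max(np.linalg.norm(residual) * kernel.sum(), 1e-30)
    x = np.zeros(n)
    y = x.copy()
    t = 1.0
    pg0 = None
    x_prev_check = x.copy()
    for it in range(max_iter):
        grad = adjoint(forward(y) - residual) + regularization * y
        x_new = np.maximum(y - grad / lipschitz, 0.0)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = x_new + (t - 1.0) / t_new * (x_new - x)
        x, t = x_new, t_new
        if it % 25 == 24:
            g = adjoint(forward(x) - residual) + regularization * x
            pg = np.linalg.norm(np.where(x > 0, g, np.minimum(g, 0.0)))
            if pg0 is None:
                pg0 = max(pg, pg_floor)
            stalled = np.linalg.norm(x - x_prev_check) <= 1e-10 * max(1.0, np.linalg.norm(x))
            if pg <= grad_tol * pg0 or pg <= pg_floor or stalled:
                return x
            x_prev_check = x.copy()
    g = adjoint(forward(x) - residual) + regularization * x
    pg = np.linalg.norm(np.where(x > 0, g, np.minimum(g, 0.0)))
    raise RuntimeError(
        f"nonnegative deconvolution did not converge in {max_iter} iterations "
        f"(projected gradient {pg:.3e}, initial {pg0 if pg0 else float('nan'):.3e})"
    )


def decompose(
    rec: EDARecording,
    tau1: float = 0.75,
    tau2: float = 2.0,
    regularization: float = 1e-3,
    tonic_window: float = 60.0,
    tonic_percentile: float = 10.0,
) -> Decomposition:
    """Split conductance into tonic level and nonnegative-driver phasic train.

    Pass 1 estimates the tonic level as a smoothed rolling low percentile of
    the conductance (tonic changes occur over minutes) and deconvolves the
    residual against the SCR kernel under a non-negativity constraint on the
    driver.  Slow structure captured by the pass-1 phasic fit — percentile
    bias under drifts — is transferred back to the tonic estimate and the
    deconvolution is repeated.

    Returns a :class:`Decomposition` with ``driver >= 0`` everywhere and the
    reconstruction RMSE of ``tonic + phasic`` against the raw conductance.
    """
    cond = rec.conductance
    n = len(cond)
    kernel = scr_kernel(rec.sampling_rate, tau1, tau2)
    if n < 3 * len(kernel):
        raise ValueError("recording too short relative to the SCR kernel")
    if not np.any(cond):
        zero = np.zeros(n)
        return Decomposition(tonic=zero, driver=zero.copy(), phasic=zero.copy(), rmse=0.0, kernel=kernel)

    fs = rec.sampling_rate
    win = max(3, int(round(tonic_window * fs)))
    smooth_sigma = tonic_window / 4.0 * fs

    tonic = ndimage.gaussian_filter1d(
        ndimage.percentile_filter(cond, tonic_percentile, size=win, mode="nearest"),
        smooth_sigma,
        mode="nearest",
    )
    driver = _nnls_deconvolve(kernel, cond - tonic, regularization)
    phasic = signal.fftconvolve(driver, kernel)[:n]
    # pass 2: return the slow floor of the fitted phasic train to the tonic.
    # A low percentile over the tonic window is ~0 around isolated SCRs but
    # tracks the constant offset a percentile-biased tonic leaves under drifts.
    slow = ndimage.gaussian_filter1d(
        ndimage.percentile_filter(phasic, tonic_percentile, size=win, mode="nearest"),
        smooth_sigma,
        mode="nearest",
    )
    tonic = tonic + slow
    driver = _nnls_deconvolve(kernel, cond - tonic, regularization)
    phasic = signal.fftconvolve(driver, kernel)[:n]

    rmse = float(np.sqrt(np.mean((cond - tonic - phasic) ** 2)))
    return Decomposition(tonic=tonic, driver=driver, phasic=phasic, rmse=rmse, kernel=kernel)


# ---------------------------------------------------------------------------
# SCR detection, baseline, normalization, attribution
# ---------------------------------------------------------------------------


def detect_scrs(
    phasic: np.ndarray,
    rec: EDARecording,
    min_amplitude: float = 0.01,
    mask: ArtifactMask | None = None,
) -> list[SCREvent]:
    """Detect SCR events as prominent local maxima of the phasic component.

    Onset is the preceding local minimum of the phasic signal; amplitude the
    onset-to-peak rise; half-recovery the first 50% decay after the peak,
    undefined when the next SCR onset arrives first.  Events whose
    onset-to-peak span overlaps the artifact mask are dropped.
    """
    phasic = np.asarray(phasic, dtype=float)
    fs = rec.sampling_rate
    peaks, _ = signal.find_peaks(phasic, prominence=min_amplitude)
    events: list[SCREvent] = []
    for i, peak in enumerate(peaks):
        onset = peak
        while onset > 0 and phasic[onset - 1] < phasic[onset]:
            onset -= 1
        amplitude = phasic[peak] - phasic[onset]
        if amplitude < min_amplitude or onset == peak:
            continue
        # snap onset forward past the regularization-smeared foot: last
        # pre-peak sample still within 1% of the rise above the local minimum
        thresh = phasic[onset] + 0.01 * amplitude
        low = np.nonzero(phasic[onset:peak] <= thresh)[0]
        if low.size:
            onset = onset + int(low[-1])
        if mask is not None and mask.mask[onset : peak + 1].any():
            continue
        half_level = phasic[peak] - amplitude / 2.0
        if i + 1 < len(peaks):
            next_onset = peaks[i + 1]
            while next_onset > peak and phasic[next_onset - 1] < phasic[next_onset]:
                next_onset -= 1
        else:
            next_onset = len(phasic)
        half_recovery = None
        below = np.nonzero(phasic[peak:next_onset] <= half_level)[0]
        if below.size:
            half_recovery = below[0] / fs
        t0 = rec.start_time
        events.append(
            SCREvent(
                onset_time=t0 + onset / fs,
                peak_time=t0 + peak / fs,
                amplitude=float(amplitude),
                rise_time=(peak - onset) / fs,
                half_recovery_time=half_recovery,
            )
        )
    return events


def find_baseline(
    rec: EDARecording,
    mask: ArtifactMask | None = None,
    window_length: float = 120.0,
    smoothness_max_slope: float = 0.01,
    min_span: float = 0.1,
    decomposition: Decomposition | None = None,
    events: list[SCREvent] | None = None,
) -> BaselineEstimate:
    """Locate the lowest and highest smooth rest periods of the tonic level.

    Candidate windows of ``window_length`` seconds (half-window stride) must
    be fully artifact-free and have tonic slope below
    ``smoothness_max_slope`` μS/s in magnitude.  ``scl_min``/``scl_max`` are
    the mean tonic levels of the lowest/highest candidates; ``scr_max`` the
    largest detected SCR amplitude outside masked spans.

    Raises
    ------
    InsufficientCleanDataError
        If no window qualifies, if the qualifying extremes span less than
        ``min_span`` μS (flat recording: the SCL range is unidentifiable),
        or if no SCR was detected.
    """
    if decomposition is None:
        decomposition = decompose(rec)
    if events is None:
        events = detect_scrs(decomposition.phasic, rec, mask=mask)
    tonic = decomposition.tonic
    fs = rec.sampling_rate
    wlen = int(round(window_length * fs))
    if wlen < 2 or wlen > len(tonic):
        raise InsufficientCleanDataError("window_length does not fit the recording")
    stride = max(1, wlen // 2)
    masked = mask.mask if mask is not None else np.zeros(len(tonic), dtype=bool)
    t_rel = np.arange(wlen) / fs

    candidates: list[tuple[float, float, float]] = []  # (mean level, t_start, t_end)
    for start in range(0, len(tonic) - wlen + 1, stride):
        seg = tonic[start : start + wlen]
        if masked[start : start + wlen].any():
            continue
        slope = np.polyfit(t_rel, seg, 1)[0]
        if abs(slope) >= smoothness_max_slope:
            continue
        t0 = rec.start_time + start / fs
        candidates.append((float(seg.mean()), t0, t0 + window_length))
    if not candidates:
        raise InsufficientCleanDataError("no smooth artifact-free window found")
    lo = min(candidates, key=lambda c: c[0])
    hi = max(candidates, key=lambda c: c[0])
    if hi[0] - lo[0] < min_span:
        raise InsufficientCleanDataError(
            "tonic extremes nearly coincide; cannot span an SCL range on this recording"
        )
    if not events:
        raise InsufficientCleanDataError("no SCR detected; SCR_max undefined")
    scr_max = max(e.amplitude for e in events)
    return BaselineEstimate(
        scl_min=lo[0],
        scl_max=hi[0],
        scr_max=scr_max,
        min_window=(lo[1], lo[2]),
        max_window=(hi[1], hi[2]),
    )


def scl_rel(scl: float | np.ndarray, baseline: BaselineEstimate):
    """Tonic level as a proportion of the individual's observed SCL range.

    ``(SCL - SCL_min) / (SCL_max - SCL_min)``; values outside [0, 1] are
    returned unclipped with a logged warning (the level left the observed
    range).
    """
    span = baseline.scl_max - baseline.scl_min
    if span <= 0:
        raise ValueError("scl_max must exceed scl_min")
    rel = (np.asarray(scl, dtype=float) - baseline.scl_min) / span
    if np.any(rel < 0) or np.any(rel > 1):
        logger.warning("SCL outside the [SCL_min, SCL_max] range; proportion not clipped")
    return float(rel) if np.ndim(scl) == 0 else rel


def scr_rel(scr_amplitude: float | np.ndarray, baseline: BaselineEstimate):
    """SCR amplitude as a proportion of the maximal response: ``SCR / SCR_max``."""
    if baseline.scr_max <= 0:
        raise ValueError("scr_max must be positive")
    rel = np.asarray(scr_amplitude, dtype=float) / baseline.scr_max
    return float(rel) if np.ndim(scr_amplitude) == 0 else rel


def attribute_scrs(
    events: Sequence[SCREvent],
    stimulus_times: Sequence[float],
    latency_window: tuple[float, float] = (1.5, 6.5),
) -> list[SCREvent]:
    """Attribute each SCR to the stimulus it plausibly responds to.

    An SCR is attributed to stimulus ``s`` iff its onset falls in
    ``[s + lo, s + hi]`` (inclusive both ends).  When several stimuli
    qualify, the most recent one wins.  Returns new events with ``latency``
    and ``attributed_stimulus`` set; unattributed events pass through
    unchanged.
    """
    lo, hi = latency_window
    if not lo < hi:
        raise ValueError("latency window must satisfy lo < hi")
    stim = sorted(enumerate(stimulus_times), key=lambda p: p[1])
    out: list[SCREvent] = []
    for ev in events:
        best: tuple[int, float] | None = None
        for sid, st in stim:
            delta = ev.onset_time - st
            if lo <= delta <= hi and (best is None or st >= best[1]):
                best = (sid, st)
        if best is None:
            out.append(ev)
        else:
            out.append(
                SCREvent(
                    onset_time=ev.onset_time,
                    peak_time=ev.peak_time,
                    amplitude=ev.amplitude,
                    rise_time=ev.rise_time,
                    half_recovery_time=ev.half_recovery_time,
                    latency=ev.onset_time - best[1],
                    attributed_stimulus=best[0],
                )
            )
    return out


@dataclass
class AgreementReport:
    """Rank agreement between questionnaire labels and EDA indicators."""

    rate_spearman: float
    rate_pvalue: float
    height_spearman: float
    height_pvalue: float
    bias: float
    per_label: pd.DataFrame
    n_labels_used: int
    n_labels_skipped: int


def compare_labels(
    events: Sequence[SCREvent],
    labels: Sequence[tuple[float, int]],
    window: float = 900.0,
    baseline: BaselineEstimate | None = None,
    mask: ArtifactMask | None = None,
    rec: EDARecording | None = None,
) -> AgreementReport:
    """Compare self-reported tension labels against trailing EDA indicators.

    For each ``(timestamp, label)`` pair the SCR peak rate (events/min) and
    the mean relative peak height over the trailing ``window`` seconds are
    computed; the report carries Spearman rank correlations of each
    indicator against the labels, plus a bias diagnostic (the difference
    between the mean normalized label and the mean normalized rate, positive
    when the reporter overestimates relative to physiology).  Labels whose
    window is entirely artifact-masked are skipped with a warning.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels for rank comparison")
    peak_times = np.array([e.peak_time for e in events])
    amplitudes = np.array([e.amplitude for e in events])
    rows = []
    skipped = 0
    for ts, lab in labels:
        if mask is not None and rec is not None:
            idx_lo = int(max(0, (ts - window - rec.start_time) * rec.sampling_rate))
            idx_hi = int(min(len(rec), (ts - rec.start_time) * rec.sampling_rate))
            if idx_hi <= idx_lo or mask.mask[idx_lo:idx_hi].all():
                warnings.warn(f"label at {ts}: window fully masked, skipped", stacklevel=2)
                skipped += 1
                continue
        in_win = (peak_times > ts - window) & (peak_times <= ts)
        rate = in_win.sum() / (window / 60.0)
        if in_win.any():
            heights = amplitudes[in_win]
            mean_height = float(
                np.mean(scr_rel(heights, baseline)) if baseline is not None else np.mean(heights)
            )
        else:
            mean_height = 0.0
        rows.append({"timestamp": ts, "label": lab, "scr_rate_per_min": rate, "mean_rel_height": mean_height})
    if len(rows) < 3:
        raise ValueError("fewer than 3 labels have usable windows")
    table = pd.DataFrame(rows)
    rate_rho, rate_p = stats.spearmanr(table["label"], table["scr_rate_per_min"])
    height_rho, height_p = stats.spearmanr(table["label"], table["mean_rel_height"])
    label_norm = (table["label"] - 1) / 6.0
    rate_max = table["scr_rate_per_min"].max()
    rate_norm = table["scr_rate_per_min"] / rate_max if rate_max > 0 else table["scr_rate_per_min"]
    return AgreementReport(
        rate_spearman=float(rate_rho),
        rate_pvalue=float(rate_p),
        height_spearman=float(height_rho),
        height_pvalue=float(height_p),
        bias=float(label_norm.mean() - rate_norm.mean()),
        per_label=table,
        n_labels_used=len(rows),
        n_labels_skipped=skipped,
    )


def scr_events_to_frame(events: Sequence[SCREvent]) -> pd.DataFrame:
    """Tabulate SCR events for CSV export."""
    return pd.DataFrame(
        [
            {
                "onset": e.onset_time,
                "peak": e.peak_time,
                "amplitude_uS": e.amplitude,
                "rise_s": e.rise_time,
                "half_recovery_s": e.half_recovery_time,
                "latency_s": e.latency,
                "stimulus_id": e.attributed_stimulus,
            }
            for e in events
        ]
    )
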