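"""Context-aware stress calculation engine: a supervised discrete HMM.

The latent state is the *tension score*, a 7-level stress variable
(1 slight ... 7 intense).  Observations are 8-dimensional discrete context
vectors, each sensor taking three codes.  Parameters are initialized by
supervised counting on labeled observation sequences (self-reports paired
with their context windows) with Laplace smoothing; classification runs the
Viterbi algorithm over a trailing observation window and reports the final
window state, packaged with timestamp and observation as a *context triplet*.
A Bayes-filter update (predict through the transition matrix, multiply by
the observation likelihood, renormalize) is provided as the recursive
alternative scorer.

Two emission parameterizations are supported:

``factorized``
    Per-state, per-sensor categorical distributions (shape ``S x 8 x 3``);
    sensors are conditionally independent given the state.  Default — a
    6561-symbol joint alphabet is unlearnable from one week of prompts.
``joint``
    One categorical per state over all ``3^8 = 6561`` joint symbols
    (mixed-radix encoding of the vector).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import (
    N_CODES,
    N_JOINT,
    N_SENSORS,
    PROBE_ORDER,
    ObservationVector,
    encode_joint,
)

logger = logging.getLogger(__name__)

N_STATES = 7  # tension scores 1..7; state index i <-> score i+1

_SERIALIZATION_VERSION = 1


class ImpossibleEvidenceError(ValueError):
    """All states assign zero likelihood to the observation."""


def _as_codes(obs: ObservationVector | Sequence[int]) -> tuple[int, ...]:
    return obs.values if isinstance(obs, ObservationVector) else tuple(obs)


@dataclass
class StressHMM:
    """Discrete hidden Markov model over tension states.

    Attributes
    ----------
    pi : ndarray, shape (S,)
        Initial state distribution ``P(x0 = i)``.
    T : ndarray, shape (S, S)
        Row-stochastic transition matrix, ``T[i, j] = P(X_t = j | X_{t-1} = i)``.
    emissions : ndarray
        ``(S, 8, 3)`` per-sensor categoricals in factorized mode, or
        ``(S, 6561)`` joint-symbol categoricals in joint mode.
    mode : {"factorized", "joint"}
    smoothing_alpha : float
        Laplace pseudo-count used at fit time (recorded for provenance).
    probe_order : tuple of str
        Sensor order the emission axes refer to.

    ``n_states`` defaults to 7 but arbitrary sizes are accepted so that
    small-state toy models can be checked against exhaustive enumeration.
    """

    pi: np.ndarray
    T: np.ndarray
    emissions: np.ndarray
    mode: str = "factorized"
    smoothing_alpha: float = 1.0
    probe_order: tuple[str, ...] = PROBE_ORDER

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.pi)

    def validate(self, atol: float = 1e-9) -> None:
        s = self.n_states
        if self.T.shape != (s, s):
            raise ValueError(f"T must be {s}x{s}, got {self.T.shape}")
        if self.mode == "factorized":
            if self.emissions.shape != (s, N_SENSORS, N_CODES):
                raise ValueError(
                    f"factorized emissions must be ({s},{N_SENSORS},{N_CODES})"
                )
        elif self.mode == "joint":
            if self.emissions.shape != (s, N_JOINT):
                raise ValueError(f"joint emissions must be ({s},{N_JOINT})")
        else:
            raise ValueError(f"unknown emission mode {self.mode!r}")
        for name, arr, axis in (
            ("pi", self.pi, 0),
            ("T", self.T, 1),
            ("emissions", self.emissions, self.emissions.ndim - 1),
        ):
            if np.any(arr < -atol):
                raise ValueError(f"{name} has negative entries")
            sums = arr.sum(axis=axis)
            if not np.allclose(sums, 1.0, atol=atol):
                raise ValueError(f"{name} rows must sum to 1 (max dev {np.abs(sums - 1).max():.2e})")

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "version": _SERIALIZATION_VERSION,
            "mode": self.mode,
            "smoothing_alpha": self.smoothing_alpha,
            "probe_order": list(self.probe_order),
            "pi": self.pi.tolist(),
            "T": self.T.tolist(),
            "emissions": self.emissions.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "StressHMM":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("version") != _SERIALIZATION_VERSION:
            raise ValueError(f"unsupported model version {payload.get('version')}")
        return cls(
            pi=np.array(payload["pi"]),
            T=np.array(payload["T"]),
            emissions=np.array(payload["emissions"]),
            mode=payload["mode"],
            smoothing_alpha=payload["smoothing_alpha"],
            probe_order=tuple(payload["probe_order"]),
        )


@dataclass
class LabeledSequence:
    """A time-ordered observation sequence paired with tension-score labels."""

    observations: list[ObservationVector]
    labels: list[int]

    def __post_init__(self) -> None:
        if len(self.observations) != len(self.labels):
            raise ValueError("observations and labels must have equal length")
        for lab in self.labels:
            if not 1 <= lab <= N_STATES:
                raise ValueError(f"label {lab} outside 1..{N_STATES}")


@dataclass(frozen=True)
class ContextTriplet:
    """(timestamp, tension score, observation) record stored per classification."""

    timestamp: float
    tension_score: int
    observation: ObservationVector

    def __post_init__(self) -> None:
        if not 1 <= self.tension_score <= N_STATES:
            raise ValueError(f"tension_score {self.tension_score} outside 1..{N_STATES}")


# ---------------------------------------------------------------------------
# Supervised parameter initialization
# ---------------------------------------------------------------------------


def supervised_fit(
    sequences: Sequence[LabeledSequence],
    alpha: float = 1.0,
    mode: str = "factorized",
) -> StressHMM:
    """Estimate HMM parameters by smoothed counting on labeled sequences.

    ``pi`` is the smoothed frequency of first labels, ``T`` the smoothed
    row-normalized count of consecutive label pairs, and the emissions the
    smoothed frequency of observed codes per labeled state.  With
    ``alpha > 0`` no probability is exactly zero; with ``alpha = 0`` rows
    whose state was never visited fall back to uniform.
    """
    if not sequences or all(len(s.labels) == 0 for s in sequences):
        raise ValueError("at least one non-empty labeled sequence is required")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if mode not in ("factorized", "joint"):
        raise ValueError(f"unknown emission mode {mode!r}")

    s = N_STATES
    pi_counts = np.zeros(s)
    t_counts = np.zeros((s, s))
    if mode == "factorized":
        e_counts = np.zeros((s, N_SENSORS, N_CODES))
    else:
        e_counts = np.zeros((s, N_JOINT))

    for seq in sequences:
        if not seq.labels:
            continue
        states = [lab - 1 for lab in seq.labels]
        pi_counts[states[0]] += 1
        for a, b in zip(states, states[1:]):
            t_counts[a, b] += 1
        for state, obs in zip(states, seq.observations):
            if mode == "factorized":
                for sensor, code in enumerate(_as_codes(obs)):
                    e_counts[state, sensor, code] += 1
            else:
                e_counts[state, encode_joint(obs)] += 1

    def _normalize(counts: np.ndarray) -> np.ndarray:
        smoothed = counts + alpha
        sums = smoothed.sum(axis=-1, keepdims=True)
        out = np.empty_like(smoothed)
        nonzero = np.broadcast_to(sums > 0, smoothed.shape)
        out[nonzero] = (smoothed / np.where(sums > 0, sums, 1.0))[nonzero]
        # unvisited rows (all-zero counts, alpha = 0): uniform fallback
        out[~nonzero] = 1.0 / counts.shape[-1]
        return out

    return StressHMM(
        pi=_normalize(pi_counts),
        T=_normalize(t_counts),
        emissions=_normalize(e_counts),
        mode=mode,
        smoothing_alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Likelihoods, filtering, decoding
# ---------------------------------------------------------------------------


def emission_logprobs(model: StressHMM, obs: ObservationVector | Sequence[int]) -> np.ndarray:
    """``log P(e | X = i)`` for every state, as a length-S vector."""
    with np.errstate(divide="ignore"):
        if model.mode == "factorized":
            codes = _as_codes(obs)
            probs = model.emissions[:, np.arange(len(codes)), codes]
            return np.log(probs).sum(axis=1)
        return np.log(model.emissions[:, encode_joint(obs)])


def emission_logprob(model: StressHMM, state: int, obs) -> float:
    """``log P(e | X = state)`` for a single 0-based state index."""
    if not 0 <= state < model.n_states:
        raise ValueError(f"state {state} outside 0..{model.n_states - 1}")
    return float(emission_logprobs(model, obs)[state])


def filter_update(model: StressHMM, prior: np.ndarray, obs) -> np.ndarray:
    """One Bayes-filter step: predict through ``T``, weight by likelihood.

    ``posterior_i ∝ P(e_t | X_t = i) * sum_j prior_j T[j, i]``, renormalized.

    Raises
    ------
    ImpossibleEvidenceError
        If every state assigns zero likelihood to the observation (possible
        with unsmoothed models); the caller may fall back to the predicted
        prior.
    """
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (model.n_states,) or not np.isclose(prior.sum(), 1.0, atol=1e-6):
        raise ValueError("prior must be a length-S distribution summing to 1")
    predicted = model.T.T @ prior
    loglik = emission_logprobs(model, obs)
    finite = np.isfinite(loglik)
    like = np.zeros_like(predicted)
    if finite.any():
        like[finite] = np.exp(loglik[finite] - loglik[finite].max())
    unnorm = like * predicted
    z = unnorm.sum()
    if z <= 0:
        raise ImpossibleEvidenceError("all states assign zero likelihood to the observation")
    return unnorm / z


def forward_filter(model: StressHMM, obs_seq: Sequence) -> np.ndarray:
    """Normalized forward-algorithm marginals ``P(X_t | e_1..e_t)``, row per step.

    The first step filters the initial distribution directly (no transition
    before the first observation); subsequent steps apply
    :func:`filter_update` recursively.
    """
    if len(obs_seq) == 0:
        raise ValueError("empty observation sequence")
    loglik0 = emission_logprobs(model, obs_seq[0])
    with np.errstate(invalid="ignore"):
        unnorm = np.where(np.isfinite(loglik0), np.exp(loglik0 - np.nanmax(loglik0[np.isfinite(loglik0)])), 0.0) * model.pi
    z = unnorm.sum()
    if z <= 0:
        raise ImpossibleEvidenceError("all states assign zero likelihood to the first observation")
    posts = [unnorm / z]
    for obs in obs_seq[1:]:
        posts.append(filter_update(model, posts[-1], obs))
    return np.vstack(posts)


def viterbi_decode(model: StressHMM, obs_seq: Sequence) -> tuple[np.ndarray, float]:
    """Most likely hidden state sequence and its joint log-probability.

    Log-space dynamic program; ties are broken toward the lower state index
    at every backtrack step so decoding is deterministic.  Returned states
    are 1-based tension scores.
    """
    L = len(obs_seq)
    if L == 0:
        raise ValueError("empty observation sequence")
    s = model.n_states
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.pi)
        log_T = np.log(model.T)
    delta = log_pi + emission_logprobs(model, obs_seq[0])
    back = np.zeros((L, s), dtype=int)
    for t in range(1, L):
        scores = delta[:, None] + log_T  # scores[i, j]: best path ending i -> j
        back[t] = np.argmax(scores, axis=0)  # first max = lowest index
        delta = scores[back[t], np.arange(s)] + emission_logprobs(model, obs_seq[t])
    states = np.empty(L, dtype=int)
    states[-1] = int(np.argmax(delta))
    log_joint = float(delta[states[-1]])
    for t in range(L - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return states + 1, log_joint


def classify(
    model: StressHMM,
    observations: Sequence[ObservationVector],
    window_size: int = 4,
) -> list[ContextTriplet]:
    """Score every observation by Viterbi-decoding its trailing window.

    For each evaluation timestamp the trailing ``window_size`` observations
    are decoded and the final window state is reported as the tension score.
    Early timestamps with fewer than ``window_size`` observations use all
    available history.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if observations and len(observations) < window_size:
        logger.info(
            "only %d observations for window_size %d; using all available",
            len(observations),
            window_size,
        )
    triplets = []
    for idx, obs in enumerate(observations):
        window = observations[max(0, idx + 1 - window_size) : idx + 1]
        states, _ = viterbi_decode(model, window)
        triplets.append(
            ContextTriplet(timestamp=obs.timestamp, tension_score=int(states[-1]), observation=obs)
        )
    return triplets


def joint_from_factorized(model: StressHMM) -> StressHMM:
    """Expand a factorized model into the equivalent joint-emission model."""
    if model.mode != "factorized":
        raise ValueError("model is not factorized")
    joint = np.empty((model.n_states, N_JOINT))
    for sym in range(N_JOINT):
        codes = np.array(_decode_cached(sym))
        joint[:, sym] = model.emissions[:, np.arange(N_SENSORS), codes].prod(axis=1)
    return StressHMM(
        pi=model.pi.copy(),
        T=model.T.copy(),
        emissions=joint,
        mode="joint",
        smoothing_alpha=model.smoothing_alpha,
        probe_order=model.probe_order,
    )


def _decode_cached(symbol: int) -> tuple[int, ...]:
    from .features import decode_joint

    return decode_joint(symbol)
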