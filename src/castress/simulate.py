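"""Synthetic data generator coupling context, self-reports and EDA.

A latent tension Markov chain (7 levels, 5-minute steps by default) drives
three observable streams:

* **context probe events** — each of the eight probes emits one raw reading
  per latent step whose discretized code follows the configured per-state
  emission distribution; raw payloads are chosen so that
  :func:`castress.features.discretize_event` maps them back to the intended
  code (round-trip guarantee);
* **questionnaire responses** — at each scheduled prompt the reporter
  answers with probability ``response_rate``; the answer is the true state
  plus an optional constant bias and ±1 jitter, clipped to 1..7; unanswered
  prompts are recorded as missing;
* **EDA recordings** — a bounded, slowly drifting tonic level plus SCR
  kernels arriving as a Poisson process whose rate (and lognormal amplitude
  scale) follows the latent tension level, Gaussian sensor noise, and
  optional injected motion bursts and temperature excursions.

Everything is deterministic under a fixed seed.  Default parameters are
chosen to emulate a one-week free-living collection: sticky tension dynamics,
well-separated context emissions, an 80% prompt response rate, and wristband-
style 4 Hz EDA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import (
    CATEGORICAL_PROBES,
    N_CODES,
    N_SENSORS,
    PROBE_ORDER,
    DiscretizationConfig,
    ProbeEvent,
)
from .scheduler import PromptSchedule

N_STATES = 7


def default_transition_matrix(stay: float = 0.6, neighbor: float = 0.18) -> np.ndarray:
    """Sticky tension dynamics: mostly stay, mostly drift to adjacent levels."""
    T = np.full((N_STATES, N_STATES), 1e-3)
    for i in range(N_STATES):
        T[i, i] = stay
        for j in (i - 1, i + 1):
            if 0 <= j < N_STATES:
                T[i, j] = neighbor
    return T / T.sum(axis=1, keepdims=True)


#: Per-state preferred code patterns with pairwise Hamming distance >= 5,
#: so the eight sensors jointly identify the state with near certainty.
_STATE_PATTERNS = (
    (0, 0, 0, 0, 0, 0, 0, 0),
    (1, 1, 1, 1, 1, 1, 1, 1),
    (2, 2, 2, 2, 2, 2, 2, 2),
    (0, 1, 2, 0, 1, 2, 0, 1),
    (1, 2, 0, 1, 2, 0, 1, 2),
    (2, 0, 1, 2, 0, 1, 2, 0),
    (2, 1, 0, 2, 1, 0, 2, 1),
)


def default_emissions(concentration: float = 0.8) -> np.ndarray:
    """Well-separated per-sensor emissions.

    State ``i`` prefers code ``_STATE_PATTERNS[i][sensor]`` on every sensor
    with probability ``concentration``; the remaining mass splits evenly.
    """
    rest = (1.0 - concentration) / (N_CODES - 1)
    em = np.full((N_STATES, N_SENSORS, N_CODES), rest)
    for i in range(N_STATES):
        for s in range(N_SENSORS):
            em[i, s, _STATE_PATTERNS[i][s]] = concentration
    return em


@dataclass
class EDASimConfig:
    """EDA channel of the simulator."""

    sampling_rate: float = 4.0  # Hz, typical wristband EDA rate
    scr_rate_per_level: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0)  # events/min
    scr_amp_mu: float = float(np.log(0.3))  # lognormal location, log μS
    scr_amp_sigma: float = 0.5
    tonic_start: float = 5.0  # μS
    tonic_bounds: tuple[float, float] = (1.0, 12.0)
    tonic_step_sd: float = 0.003  # μS per sample before smoothing
    noise_sd: float = 0.01  # μS Gaussian sensor noise
    motion_rate_per_hour: float = 0.5
    motion_duration: float = 2.0  # s
    motion_accel_g: float = 1.0
    motion_conductance_spike: float = 2.0  # μS
    temp_mean: float = 33.0  # °C
    temp_excursion_rate_per_hour: float = 0.0
    temp_excursion_value: float = 39.0
    temp_excursion_duration: float = 60.0
    tau1: float = 0.75
    tau2: float = 2.0


@dataclass
class SimConfig:
    """Ground-truth generative parameters for one synthetic collection."""

    true_pi: np.ndarray = field(default_factory=lambda: np.full(N_STATES, 1.0 / N_STATES))
    true_T: np.ndarray = field(default_factory=default_transition_matrix)
    true_emissions: np.ndarray = field(default_factory=default_emissions)
    step_minutes: float = 5.0
    n_days: int = 7
    reporter_bias: int = 0
    reporter_noise: float = 0.1  # probability of a ±1 label jitter
    response_rate: float = 0.8
    eda: EDASimConfig = field(default_factory=EDASimConfig)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.true_pi = np.asarray(self.true_pi, dtype=float)
        self.true_T = np.asarray(self.true_T, dtype=float)
        self.true_emissions = np.asarray(self.true_emissions, dtype=float)
        if not np.isclose(self.true_pi.sum(), 1.0):
            raise ValueError("true_pi must sum to 1")
        if not np.allclose(self.true_T.sum(axis=1), 1.0):
            raise ValueError("true_T rows must sum to 1")
        if not np.allclose(self.true_emissions.sum(axis=-1), 1.0):
            raise ValueError("true_emissions rows must sum to 1")
        if not 0.0 <= self.response_rate <= 1.0:
            raise ValueError("response_rate must be in [0, 1]")
        if any(r < 0 for r in self.eda.scr_rate_per_level):
            raise ValueError("SCR rates must be >= 0")


@dataclass
class GroundTruth:
    """Latent trajectory and injected events underlying one simulation."""

    times: np.ndarray  # epoch seconds, one per latent step
    true_states: np.ndarray  # tension scores 1..7
    scr_times: np.ndarray = field(default_factory=lambda: np.array([]))
    scr_amplitudes: np.ndarray = field(default_factory=lambda: np.array([]))
    artifact_intervals: list[tuple[float, float]] = field(default_factory=list)

    def state_at(self, t: float | np.ndarray) -> np.ndarray:
        """Piecewise-constant latent state lookup (last step at or before t)."""
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, len(self.times) - 1)
        return self.true_states[idx]


def _rng_for(config: SimConfig, stream: int) -> np.random.Generator:
    # independent substream per generator so adding one stream never
    # perturbs the others under the same master seed
    return np.random.default_rng(None if config.seed is None else (config.seed, stream))


def simulate_tension(config: SimConfig, start_epoch: float = 0.0) -> GroundTruth:
    """Sample the latent tension chain at ``step_minutes`` cadence."""
    rng = _rng_for(config, 0)
    n_steps = int(round(config.n_days * 24 * 60 / config.step_minutes))
    states = np.empty(n_steps, dtype=int)
    states[0] = rng.choice(N_STATES, p=config.true_pi)
    for t in range(1, n_steps):
        states[t] = rng.choice(N_STATES, p=config.true_T[states[t - 1]])
    times = start_epoch + np.arange(n_steps) * config.step_minutes * 60.0
    return GroundTruth(times=times, true_states=states + 1)


def simulate_context(
    truth: GroundTruth,
    config: SimConfig,
    disc: DiscretizationConfig | None = None,
) -> list[ProbeEvent]:
    """Emit one raw reading per probe per latent step from the true emissions.

    Raw payloads are constructed so that discretization maps each event back
    to the sampled code: categorical probes use the first configured label of
    the code, rate probes draw uniformly inside the code's bin.
    """
    disc = disc or DiscretizationConfig()
    rng = _rng_for(config, 1)
    states = truth.true_states - 1
    n_steps = len(states)
    cum = config.true_emissions.cumsum(axis=-1)
    # codes[step, sensor] sampled by inverse CDF, vectorized over steps
    u = rng.random((n_steps, N_SENSORS))
    codes = (u[:, :, None] > cum[states][:, :, :-1]).sum(axis=-1)

    cat_labels = {
        probe: {
            code: next(lab for lab, c in disc.categorical_maps[probe].items() if c == code)
            for code in (0, 1, 2)
        }
        for probe in CATEGORICAL_PROBES
    }
    rate_bins = {
        probe: ((0.0, low), (low, high), (high, 2.0 * high))
        for probe, (low, high) in disc.rate_cuts.items()
    }
    v = rng.random((n_steps, N_SENSORS))  # bin position for rate probes

    events: list[ProbeEvent] = []
    for step, t in enumerate(truth.times):
        for s, probe in enumerate(PROBE_ORDER):
            code = int(codes[step, s])
            if probe in CATEGORICAL_PROBES:
                raw: str | float = cat_labels[probe][code]
            else:
                lo, hi = rate_bins[probe][code]
                raw = lo + (hi - lo) * float(v[step, s])
            events.append(ProbeEvent(probe, float(t), raw))
    return events


def simulate_responses(
    truth: GroundTruth,
    schedule: PromptSchedule,
    config: SimConfig,
) -> pd.DataFrame:
    """Answer scheduled prompts with biased/noisy Likert labels.

    Returns a frame with one row per prompt: ``prompt_time``, ``answered``
    and ``label`` (pandas NA when the prompt went unanswered — the missing-
    measurement phenomenon of signal-contingent recording).
    """
    rng = _rng_for(config, 2)
    rows = []
    for t in schedule.prompt_times:
        answered = bool(rng.random() < config.response_rate)
        label: int | None = None
        if answered:
            true = int(truth.state_at(t))
            jitter = 0
            if rng.random() < config.reporter_noise:
                jitter = int(rng.choice([-1, 1]))
            label = int(np.clip(true + config.reporter_bias + jitter, 1, N_STATES))
        rows.append({"prompt_time": t, "answered": answered, "label": label})
    df = pd.DataFrame(rows)
    df["label"] = df["label"].astype("Int64")
    return df


def simulate_eda(truth: GroundTruth, config: SimConfig):
    """Synthesize a wristband-style EDA recording coupled to the tension chain.

    Returns ``(recording, truth)`` where ``truth`` is the input ground truth
    augmented with the injected SCR times/amplitudes and artifact intervals.
    """
    from .eda import EDARecording, scr_kernel

    cfg = config.eda
    rng = _rng_for(config, 3)
    fs = cfg.sampling_rate
    duration = truth.times[-1] - truth.times[0] + config.step_minutes * 60.0
    n = int(round(duration * fs))
    t = truth.times[0] + np.arange(n) / fs

    # tonic: bounded reflected random walk, smoothed over ~1 min
    steps = rng.normal(0.0, cfg.tonic_step_sd, size=n)
    walk = cfg.tonic_start + np.cumsum(steps)
    lo, hi = cfg.tonic_bounds
    span = hi - lo
    walk = lo + span - np.abs((walk - lo) % (2 * span) - span)  # reflect into bounds
    from scipy.ndimage import gaussian_filter1d

    tonic = gaussian_filter1d(walk, 60.0 * fs, mode="nearest")

    # state-dependent Poisson SCR arrivals
    rates = np.array(cfg.scr_rate_per_level)[truth.state_at(t) - 1] / 60.0  # per second
    arrivals = rng.random(n) < rates / fs
    scr_idx = np.nonzero(arrivals)[0]
    amps = rng.lognormal(cfg.scr_amp_mu, cfg.scr_amp_sigma, size=scr_idx.size)
    driver = np.zeros(n)
    driver[scr_idx] = amps
    kernel = scr_kernel(fs, cfg.tau1, cfg.tau2)
    phasic = np.convolve(driver, kernel)[:n]

    conductance = tonic + phasic + rng.normal(0.0, cfg.noise_sd, size=n)
    accel = np.tile([0.0, 0.0, 1.0], (n, 1)) + rng.normal(0.0, 0.01, size=(n, 3))
    temperature = np.full(n, cfg.temp_mean) + rng.normal(0.0, 0.05, size=n)

    artifact_intervals: list[tuple[float, float]] = []
    hours = duration / 3600.0
    n_motion = rng.poisson(cfg.motion_rate_per_hour * hours)
    for _ in range(n_motion):
        start = rng.uniform(0.0, duration - cfg.motion_duration)
        i0 = int(start * fs)
        i1 = min(n, i0 + int(cfg.motion_duration * fs))
        # alternating-sign jolts along gravity: magnitude deviation is at
        # least half the configured burst amplitude at every burst sample
        signs = rng.choice([-1.0, 1.0], size=i1 - i0)
        accel[i0:i1, 2] += signs * cfg.motion_accel_g * (0.5 + 0.5 * rng.random(i1 - i0))
        bump = cfg.motion_conductance_spike * np.bartlett(max(3, i1 - i0))[: i1 - i0]
        conductance[i0:i1] += bump
        artifact_intervals.append((t[i0], t[min(i1, n - 1)]))
    n_temp = rng.poisson(cfg.temp_excursion_rate_per_hour * hours)
    for _ in range(n_temp):
        start = rng.uniform(0.0, duration - cfg.temp_excursion_duration)
        i0 = int(start * fs)
        i1 = min(n, i0 + int(cfg.temp_excursion_duration * fs))
        temperature[i0:i1] = cfg.temp_excursion_value
        artifact_intervals.append((t[i0], t[min(i1, n - 1)]))

    conductance = np.maximum(conductance, 0.0)
    rec = EDARecording(
        sampling_rate=fs,
        conductance=conductance,
        accel=accel,
        temperature=temperature,
        start_time=float(truth.times[0]),
    )
    out = GroundTruth(
        times=truth.times,
        true_states=truth.true_states,
        scr_times=t[scr_idx],
        scr_amplitudes=amps,
        artifact_intervals=artifact_intervals,
    )
    return rec, out
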