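# Methods

## The model

`castress` treats a person's momentary stress as a latent discrete variable —
the *tension score* X_t ∈ {1, …, 7} (1 slight, 7 intense) — evolving as a
first-order Markov chain and observed only indirectly through an
8-dimensional context vector e_t. The HMM is parameterized by

- an initial distribution π_i = P(X_0 = i),
- a 7×7 row-stochastic transition matrix T with t_ij = P(X_t = j | X_{t−1} = i),
- an observation model O with o_i(e) = P(e_t | X_t = i).

The eight context sensors (mobile location, ambient volume, physical
activity, call status, ringer status, PC keystroke / backspace / mouse-click
rates) are each discretized to three levels {0, 1, 2}, so an observation
lives in {0,1,2}^8.

**Emission parameterization.** How an 8-dimensional discrete observation
enters the observation model is a genuine design choice. The default is a
*factorized* model — sensors conditionally independent given the state, i.e.
P(e | X = i) = ∏_s P(e_s | X = i), 7×8×3 = 168 parameters — because the
alternative *joint* model over all 3^8 = 6561 symbols (7×6561 parameters)
cannot be estimated from roughly a hundred labeled prompts collected in one
week. The joint mode is implemented and exposed for comparison;
`joint_from_factorized` expands a factorized model exactly, and the two give
identical likelihoods on such models (tested to 1e-12).

**Supervised fitting.** Parameters are initialized by counting over labeled
sequences (self-reported tension paired with the observation assembled at
the prompt time), with Laplace smoothing α (default 1) so one week of data
never produces a structurally impossible zero; transition rows for states
never visited fall back to uniform. No Baum–Welch refinement is performed —
the supervised initialization *is* the estimator.

**Scoring.** Two scorers are provided. The default classifier
Viterbi-decodes the trailing window of observations (default window 4) and
reports the final window state; the recursive Bayes filter
(predict-through-T, multiply by likelihood, renormalize) is available as
`filter_update` / `forward_filter` and is tested to agree with the forward
algorithm's filtering marginals to 1e-9. Viterbi runs in log space; ties
break toward the lower state at every backtrack step, so decoding is
deterministic. Each classification is stored as a *context triplet*
(timestamp, tension score, observation).

## Questionnaire scheduling

Labels are collected by signal-contingent recording: one prompt per 60-minute
block of the waking window (default 07:00–23:00, i.e. 16 blocks/day, 7 days),
with consecutive prompts at least 15 minutes apart. The prompt for block k is
drawn uniformly from the block clipped below at `previous + min_gap`; since
the gap is smaller than the block, the clipped interval is never empty, so
the construction is rejection-free and a pure function of (parameters, seed).
The clipping slightly biases draws away from a block's opening minutes when
the previous prompt fell late — accepted in exchange for determinism and a
hard spacing guarantee. The spacing constraint is enforced within days only;
the first prompt of a day is unconstrained by the previous evening (the
overnight gap dominates the minimum spacing anyway). The schedule never
reads context or physiology: independence from external events is enforced
by the interface, which accepts nothing but parameters and a seed.

## Feature discretization

Categorical probes map by label table (location: unknown 0 / home 1 /
at work 2; call: idle 0 / ringing 1 / in a call 2; ringer: silent 0 /
vibrator 1 / normal 2); unknown labels map to 0 — the unknown/idle level —
with a logged warning. Rate probes bin half-open: [0, low) → 0,
[low, high) → 1, [high, ∞) → 2. The cut points are calibration choices, not
measurements: PC keys (10, 60)/min, PC backspace (2, 10)/min, PC clicks
(5, 30)/min, ambient volume (40, 70) dB, physical activity (20, 100)
counts/min; all overridable in `DiscretizationConfig`.

Observations use last-valid-reading semantics: for each probe, the most
recent event in `(t − lookback, t]` (default 15 min, matching the minimum
prompt spacing so one observation window cannot span two prompts); probes
without a reading default to code 0 and are flagged `defaulted`.

## EDA decomposition and SCR analysis

Skin conductance (μS) is modeled as tonic level (SCL) plus a train of skin
conductance responses (SCRs), each the convolution of a non-negative
sudomotor driver impulse with a biexponential kernel
k(t) = exp(−t/τ2) − exp(−t/τ1), τ1 = 0.75 s, τ2 = 2 s (standard SCR shape
constants), normalized to unit peak so driver impulses carry response
amplitude in μS.

The decomposition runs in two passes:

1. coarse tonic = rolling 10th percentile over 60-s windows, Gaussian-smoothed
   (σ = 15 s); the residual is deconvolved against the kernel by nonnegative
   least squares with a small ridge penalty (λ = 1e−3);
2. the slow floor of the fitted phasic train (10th percentile over the same
   window, smoothed) is transferred back into the tonic estimate and the
   deconvolution repeats on the corrected residual.

The second pass exists because a percentile-based tonic lags under drifts,
leaving a constant positive residual that pass 1 spuriously explains with a
low sustained driver; the floor transfer removes it while leaving isolated
transients untouched (a pure 0.01 μS/s ramp yields a driver below 1% of the
ramp range; a single injected 0.5 μS SCR is recovered with >99% of driver
mass within ±1 s and amplitude error under 1%).

The nonnegative solve minimizes ‖k∗d − r‖² + λ‖d‖² over d ≥ 0 with an
accelerated projected-gradient iteration (FISTA); the convolution operator
is applied by FFT overlap-add, so cost is linear in recording length.
Iteration stops when the projected gradient falls below 1e−3 of its initial
norm (with an absolute floor scaled to the data and a stagnation check for
already-optimal iterates); non-convergence raises with diagnostics.

SCR peaks are local maxima of the phasic component with prominence ≥ 0.01 μS
(conventional minimum amplitude). Onset is the preceding local minimum,
snapped forward past the regularization-smeared foot to the last sample
within 1% of the rise; amplitude is the onset-to-peak rise; half-recovery is
the first 50% decay after the peak, undefined when the next SCR interrupts
recovery. Events overlapping the artifact mask are dropped.

**Artifacts.** Samples are masked when the accelerometer magnitude deviates
from its median (the gravity baseline) by more than 0.2 g or the thermometer
leaves 30–37 °C, dilated by ±5 s.

**Baseline.** SCL_min / SCL_max are the mean tonic levels of the
lowest/highest artifact-free windows (120 s, |slope| < 0.01 μS/s);
SCR_max is the largest detected SCR amplitude over the recording — a global
rather than per-stimulus maximum, which is an interpretation choice.
Recordings whose qualifying tonic extremes span less than 0.1 μS are
rejected as unidentifiable rather than returning a meaningless ratio.
Normalizations: SCL_rel = (SCL − SCL_min)/(SCL_max − SCL_min), unclipped
(values outside [0, 1] flag a range excursion); SCR_rel = SCR/SCR_max with
SCR_min taken as zero.

**Attribution.** An SCR is attributed to a stimulus when its onset falls
1.5–6.5 s after stimulus onset (inclusive bounds); when several stimuli
qualify, the most recent wins. Attribution is translation-invariant.

**Label agreement.** For each self-report, the SCR peak rate (events/min)
and mean relative peak height over the trailing window (default 15 min) are
compared to the Likert labels by Spearman rank correlation — rank-based on
purpose, so a reporter who systematically under- or over-estimates (a
constant Likert shift) leaves the agreement measure unchanged. A bias
diagnostic (mean normalized label minus mean normalized rate) indicates the
direction of systematic mis-reporting.

## The synthetic-data generator

The generator emulates a one-week free-living collection and is the only
data source the tests use. Defaults, chosen once as plausible free-living
values:

- latent chain: 5-min steps, sticky transitions (0.6 self-loop, 0.18 to each
  neighbor, ~1e-3 elsewhere), uniform initial distribution;
- context emissions: each state prefers a distinct 8-sensor code pattern
  (pairwise Hamming distance ≥ 5) with probability 0.8 per sensor — the
  "well-separated" regime in which context is genuinely informative about
  the state;
- reporter: 80% prompt response rate, 10% chance of ±1 Likert jitter,
  optional constant bias (clipped to 1..7); unanswered prompts are recorded
  as missing;
- EDA: 4 Hz (typical wristband rate), SCR Poisson rates increasing with
  tension (0.5, 1, 1.5, 2, 3, 4, 5 events/min), lognormal amplitudes
  (μ = log 0.3 μS, σ = 0.5), tonic = bounded reflected random walk in
  [1, 12] μS smoothed over 1 min, 0.01 μS Gaussian sensor noise, optional
  motion bursts (2-s alternating jolts ≥ 0.5 g plus a 2 μS conductance
  spike) and temperature excursions, all logged as ground truth.

Raw probe payloads are constructed to discretize back to the sampled code
(first matching label for categorical probes, uniform draw inside the bin
for rate probes), so the feature module's mapping is exercised end-to-end.
All four generators draw from independent seeded substreams, so the full
simulation is bit-reproducible and adding one stream never perturbs another.

What the generator does **not** emulate: circadian structure, within-day
routine (commutes, meetings), autocorrelated probe dropout, sensor drift and
electrode detachment, state-dependent response rates, and any coupling of
motion artifacts to genuine arousal. Passing tests therefore demonstrate
that the estimator and the signal chain are correct under the assumed
statistical structure, not that the system achieves comparable accuracy on
real field data.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations to the
smallest scale at which the checked property is statistically meaningful:
1,000 days for the scheduler constraint, ~10,000 labeled steps for parameter
recovery (the counting estimator's error scales as n^(−1/2); 0.05 bounds
need ~1,500 visits per state), 200 random instances for the Viterbi oracle,
10-minute synthetic recordings for deconvolution round-trips, and one
7-day collection for the end-to-end accuracy property. Held-out accuracy is
measured on the final 30% of the collection timeline against simulator
ground truth.

Degenerate inputs are defined rather than left to chance: empty event
windows produce the all-default observation; an all-zero-likelihood
observation raises `ImpossibleEvidenceError` (callers may fall back to the
predicted prior); flat recordings fail baseline estimation explicitly;
empty SCR lists are valid output.

## Known limitations

- The factorized emission model ignores sensor correlations (e.g. PC keys
  and PC clicks co-vary in reality); the joint model can express them but is
  data-starved at realistic label counts.
- The classifier reports the Viterbi window's final state; smoothing
  (forward–backward) over the full history is not implemented.
- The deconvolution's ridge penalty trades a slightly smeared driver foot
  for stability; onset snapping compensates in detection but closely
  overlapping SCRs (< ~1.5 s apart) merge.
- Baseline estimation requires the recording to visit distinct tonic levels;
  a short, flat recording has no identifiable SCL range.
- Daily statistics group by a fixed UTC offset, not a civil timezone
  database.
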