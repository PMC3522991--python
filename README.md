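# castress — context-aware chronic stress recognition

`castress` estimates a person's ongoing stress from passively collected
mobile-phone and PC context, without dedicated physiological hardware in the
loop. It is aimed at researchers in digital phenotyping and ambulatory
psychophysiology who want a complete, testable reference pipeline for
context-based stress inference: feature discretization, experience-sampling
prompt scheduling, a supervised hidden Markov model, and an electrodermal
activity (EDA) evaluation chain, plus a synthetic-data generator that
couples all three data streams to a common ground truth.

## The model

Momentary stress is a latent 7-level **tension score** X_t ∈ {1,…,7}
(1 slight … 7 intense) following a first-order Markov chain:

- transition model t_ij = P(X_t = j | X_{t−1} = i),
- observation model o_i(e) = P(e_t | X_t = i),
- initial distribution π_i = P(X_0 = i).

The evidence e_t is an 8-vector of discretized context sensors — location,
ambient volume, physical activity, call status, ringer status, and PC
keystroke/backspace/click rates — each coded into {0, 1, 2}. Labels for
supervised initialization come from signal-contingent self-reports: a
7-point Likert prompt fired once per hour-block at a random time, at least
15 minutes after the previous prompt, for seven days. Parameters are
estimated by Laplace-smoothed counting on (observation, label) sequences;
new observations are scored by Viterbi-decoding a trailing window (the
recursive Bayes filter P(x_t = i | e_t) ∝ P(e_t | X_t = i) P(X_t = i) is also
provided). Each result is stored as a context triplet
(timestamp, tension score, observation).

For validation against physiology, skin conductance is split into tonic
(SCL) and phasic components by nonnegative deconvolution against a
biexponential SCR kernel; detected SCR peaks are attributed to stimuli via
the 1.5–6.5 s latency window, normalized as
SCL_rel = (SCL − SCL_min)/(SCL_max − SCL_min) and SCR_rel = SCR/SCR_max,
and compared to the self-reports by rank correlation. See
[docs/methods.md](docs/methods.md) for assumptions, defaults, and
limitations.

## Worked example

Simulate a 7-day collection, train, classify, and summarize:

```sh
castress simulate --days 7 --seed 7 -o data
castress train --events data/events.jsonl --responses data/responses.csv -o model.json
castress classify --events data/events.jsonl --model model.json -o triplets.csv
castress report --triplets triplets.csv -o daily.json
```

prints

```
wrote events.jsonl, responses.csv, eda.csv, truth.json to data
trained on 62 labels, held out 26; exact accuracy 0.9230769230769231, within-±1 0.9615384615384616
wrote 2016 triplets to triplets.csv
wrote daily statistics for 7 days to daily.json
```

The training report says the model was fitted on the earliest 62 answered
prompts and, on the 26 held-out later prompts, reproduced the reported
tension exactly 92% of the time (96% within one level). `triplets.csv`
holds one (timestamp, tension score, observation) row per 5-minute context
step; `daily.json` contains chart-ready per-day summaries, e.g.

```
1970-01-01 mean 4.15 min 1 max 7 mode 3
1970-01-02 mean 4.44 min 1 max 7 mode 5
```

Comparing self-reports against the simulated wristband EDA channel:

```sh
castress simulate --days 1 --seed 7 -o data1
castress evaluate --eda data1/eda.csv --responses data1/responses.csv -o eval
```

```
SCR-rate Spearman rho=0.898, peak-height rho=0.650; wrote eval_agreement.json, ...
```

i.e. the SCR peak rate in the 15 minutes before each prompt rank-correlates
strongly (ρ = 0.90) with the reported tension — the simulated reporter is a
good assessor of their own physiology. `eval_series.csv` exports the
aligned tonic/phasic traces with detected peaks and label markers for
plotting.

Everything is equally usable as a library:

```python
from castress import SimConfig, simulate_tension, simulate_context, generate_schedule
from castress import simulate_responses, run_train, run_classify

cfg = SimConfig(n_days=7, seed=7)
truth = simulate_tension(cfg)
events = simulate_context(truth, cfg)
responses = simulate_responses(truth, generate_schedule(n_days=7, seed=7), cfg)
model, report = run_train(events, responses)
triplets = run_classify(events, model)
```

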