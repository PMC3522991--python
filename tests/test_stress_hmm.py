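"""Supervised fitting, Bayes filtering, Viterbi decoding, classification."""

import itertools

import numpy as np
import pytest

from castress.features import ObservationVector
from castress.stress_hmm import (
    N_STATES,
    ContextTriplet,
    ImpossibleEvidenceError,
    LabeledSequence,
    StressHMM,
    classify,
    emission_logprob,
    emission_logprobs,
    filter_update,
    forward_filter,
    joint_from_factorized,
    supervised_fit,
    viterbi_decode,
)


def obs(*codes, t=0.0):
    return ObservationVector(timestamp=t, values=tuple(codes))


def brute_force_viterbi(model, obs_seq):
    """Oracle: exhaustive enumeration of every state path."""
    best_path, best_lp = None, -np.inf
    n = model.n_states
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.pi)
        log_T = np.log(model.T)
    for path in itertools.product(range(n), repeat=len(obs_seq)):
        lp = log_pi[path[0]] + emission_logprob(model, path[0], obs_seq[0])
        for (a, b), o in zip(zip(path, path[1:]), obs_seq[1:]):
            lp += log_T[a, b] + emission_logprob(model, b, o)
        # mimic the documented tie-break: first (lexicographically smallest)
        # maximizing path wins, which product() enumerates first
        if lp > best_lp + 1e-12:
            best_path, best_lp = path, lp
    return np.array(best_path) + 1, best_lp


def forward_oracle(model, obs_seq):
    """Oracle: textbook normalized alpha recursion, written independently."""
    alphas = []
    alpha = model.pi * np.exp(emission_logprobs(model, obs_seq[0]))
    alpha = alpha / alpha.sum()
    alphas.append(alpha)
    for o in obs_seq[1:]:
        alpha = (model.T.T @ alpha) * np.exp(emission_logprobs(model, o))
        alpha = alpha / alpha.sum()
        alphas.append(alpha)
    return np.vstack(alphas)


class TestSupervisedFit:
    def test_self_loop_counts_and_uniform_fallback(self):
        seq = LabeledSequence(observations=[obs(0, 0, 0, 0, 0, 0, 0, 0)] * 3, labels=[1, 1, 1])
        model = supervised_fit([seq], alpha=0.0)
        assert model.T[0, 0] == 1.0
        # states never visited: uniform fallback rows
        assert np.allclose(model.T[1:], 1.0 / N_STATES)

    def test_alternating_two_state_transitions(self):
        seq = LabeledSequence(
            observations=[obs(0, 0, 0, 0, 0, 0, 0, 0)] * 4, labels=[1, 2, 1, 2]
        )
        model = supervised_fit([seq], alpha=0.0)
        assert model.T[0, 1] == 1.0
        assert model.T[1, 0] == 1.0

    def test_laplace_smoothing_floor(self):
        seq = LabeledSequence(observations=[obs(1, 1, 1, 1, 1, 1, 1, 1)] * 5, labels=[3] * 5)
        model = supervised_fit([seq], alpha=1.0)
        assert np.allclose(model.T.sum(axis=1), 1.0)
        assert model.T.min() >= 1.0 / (4 + N_STATES) - 1e-12
        assert model.emissions.min() > 0

    def test_emission_frequencies_counted_per_state(self):
        observations = [obs(0, 0, 0, 0, 0, 0, 0, 0), obs(2, 0, 0, 0, 0, 0, 0, 0),
                        obs(2, 0, 0, 0, 0, 0, 0, 0)]
        model = supervised_fit(
            [LabeledSequence(observations=observations, labels=[5, 5, 5])], alpha=0.0
        )
        assert model.emissions[4, 0, 0] == pytest.approx(1 / 3)
        assert model.emissions[4, 0, 2] == pytest.approx(2 / 3)

    def test_rejects_empty_and_bad_labels(self):
        with pytest.raises(ValueError):
            supervised_fit([])
        with pytest.raises(ValueError):
            LabeledSequence(observations=[obs(0, 0, 0, 0, 0, 0, 0, 0)], labels=[8])

    def test_joint_mode_counts_symbols(self):
        observations = [obs(0, 0, 0, 0, 0, 0, 0, 0), obs(0, 0, 0, 0, 0, 0, 0, 1)]
        model = supervised_fit(
            [LabeledSequence(observations=observations, labels=[1, 1])], alpha=0.0, mode="joint"
        )
        assert model.emissions[0, 0] == pytest.approx(0.5)
        assert model.emissions[0, 1] == pytest.approx(0.5)


class TestEmissionLogprob:
    def test_uniform_factorized_gives_three_to_minus_eight(self):
        em = np.full((N_STATES, 8, 3), 1 / 3)
        model = StressHMM(pi=np.full(7, 1 / 7), T=np.full((7, 7), 1 / 7), emissions=em)
        lp = emission_logprob(model, 0, obs(0, 1, 2, 0, 1, 2, 0, 1))
        assert lp == pytest.approx(np.log(3.0**-8))

    def test_deterministic_mismatch_is_minus_inf(self):
        em = np.full((N_STATES, 8, 3), 1 / 3)
        em[0, 0] = [1.0, 0.0, 0.0]  # sensor 0 must read code 0 in state 1
        model = StressHMM(pi=np.full(7, 1 / 7), T=np.full((7, 7), 1 / 7), emissions=em)
        assert emission_logprob(model, 0, obs(1, 0, 0, 0, 0, 0, 0, 0)) == -np.inf

    def test_joint_table_built_from_factors_matches(self, random_small_hmm):
        model = random_small_hmm(3)
        joint = joint_from_factorized(model)
        for codes in [(0,) * 8, (2,) * 8, (0, 1, 2, 0, 1, 2, 0, 1)]:
            np.testing.assert_allclose(
                emission_logprobs(model, obs(*codes)),
                emission_logprobs(joint, obs(*codes)),
                atol=1e-12,
            )


class TestFilterUpdate:
    def test_hand_normalization(self):
        # identity transitions, likelihood of symbol 0 = (0.2, 0.8, 0, ...)
        em = np.zeros((N_STATES, 6561))
        em[0, 0], em[1, 0] = 0.2, 0.8
        em[0, 1], em[1, 1] = 0.8, 0.2
        em[2:, 1] = 1.0  # states 3..7 cannot emit symbol 0
        em /= em.sum(axis=1, keepdims=True)
        model = StressHMM(
            pi=np.full(7, 1 / 7), T=np.eye(7), emissions=em, mode="joint"
        )
        post = filter_update(model, np.full(7, 1 / 7), obs(0, 0, 0, 0, 0, 0, 0, 0))
        assert post[0] == pytest.approx(0.2, abs=1e-9)
        assert post[1] == pytest.approx(0.8, abs=1e-9)

    def test_uninformative_evidence_returns_predicted_prior(self, rng):
        T = rng.dirichlet(np.ones(7), size=7)
        em = np.full((N_STATES, 8, 3), 1 / 3)
        model = StressHMM(pi=np.full(7, 1 / 7), T=T, emissions=em)
        prior = rng.dirichlet(np.ones(7))
        post = filter_update(model, prior, obs(0, 0, 0, 0, 0, 0, 0, 0))
        np.testing.assert_allclose(post, T.T @ prior, atol=1e-12)

    def test_certain_evidence_collapses_posterior(self):
        em = np.zeros((N_STATES, 8, 3))
        em[:, :, 0] = 1.0
        em[2, :, :] = 0.0
        em[2, :, 2] = 1.0  # only state 3 can emit all-2s
        model = StressHMM(pi=np.full(7, 1 / 7), T=np.full((7, 7), 1 / 7), emissions=em)
        post = filter_update(model, np.full(7, 1 / 7), obs(2, 2, 2, 2, 2, 2, 2, 2))
        np.testing.assert_allclose(post, np.eye(7)[2], atol=1e-12)

    def test_impossible_evidence_raises(self):
        em = np.zeros((N_STATES, 8, 3))
        em[:, :, 0] = 1.0
        model = StressHMM(pi=np.full(7, 1 / 7), T=np.full((7, 7), 1 / 7), emissions=em)
        with pytest.raises(ImpossibleEvidenceError):
            filter_update(model, np.full(7, 1 / 7), obs(1, 0, 0, 0, 0, 0, 0, 0))

    def test_chain_matches_forward_oracle(self, random_small_hmm, rng):
        for _ in range(100):
            model = random_small_hmm(int(rng.integers(2, 5)))
            seq = [obs(*rng.integers(0, 3, size=8)) for _ in range(5)]
            posts = forward_filter(model, seq)
            assert np.allclose(posts.sum(axis=1), 1.0, atol=1e-9)
            np.testing.assert_allclose(posts, forward_oracle(model, seq), atol=1e-9)


class TestViterbi:
    def test_length_one_reduces_to_map(self, random_small_hmm, rng):
        model = random_small_hmm(4)
        o = obs(*rng.integers(0, 3, size=8))
        states, lp = viterbi_decode(model, [o])
        scores = np.log(model.pi) + emission_logprobs(model, o)
        assert states[0] - 1 == int(np.argmax(scores))
        assert lp == pytest.approx(scores.max())

    def test_matches_exhaustive_enumeration(self, random_small_hmm, rng):
        for _ in range(50):
            n = int(rng.integers(2, 5))
            L = int(rng.integers(2, 7))
            model = random_small_hmm(n)
            seq = [obs(*rng.integers(0, 3, size=8)) for _ in range(L)]
            got_states, got_lp = viterbi_decode(model, seq)
            exp_states, exp_lp = brute_force_viterbi(model, seq)
            assert got_lp == pytest.approx(exp_lp, abs=1e-10)
            np.testing.assert_array_equal(got_states, exp_states)

    def test_matches_hmmlearn_on_joint_symbols(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        from castress.features import encode_joint

        for _ in range(5):
            pi = rng.dirichlet(np.ones(7))
            T = rng.dirichlet(np.ones(7), size=7)
            em = rng.dirichlet(np.ones(6561), size=7)
            model = StressHMM(pi=pi, T=T, emissions=em, mode="joint")
            seq = [obs(*rng.integers(0, 3, size=8)) for _ in range(12)]
            ref = hmmlearn.CategoricalHMM(n_components=7, n_features=6561)
            ref.startprob_, ref.transmat_, ref.emissionprob_ = pi, T, em
            symbols = np.array([[encode_joint(o)] for o in seq])
            ref_lp, ref_states = ref.decode(symbols, algorithm="viterbi")
            got_states, got_lp = viterbi_decode(model, seq)
            assert got_lp == pytest.approx(ref_lp, abs=1e-8)
            np.testing.assert_array_equal(got_states - 1, ref_states)

    def test_deterministic_emissions_decode_identity(self):
        em = np.zeros((N_STATES, 8, 3))
        # state i deterministically emits code i % 3 on every sensor -- not
        # unique per state, so pin states 1..3 only
        for i in range(N_STATES):
            em[i, :, i % 3] = 1.0
        model = StressHMM(pi=np.full(7, 1 / 7), T=np.full((7, 7), 1 / 7), emissions=em)
        seq = [obs(*(0,) * 8), obs(*(1,) * 8), obs(*(2,) * 8)]
        states, _ = viterbi_decode(model, seq)
        np.testing.assert_array_equal(states, [1, 2, 3])  # ties -> lowest state


class TestClassify:
    def test_window_one_is_per_observation_map(self, random_small_hmm, rng):
        model = random_small_hmm(4)
        seq = [obs(*rng.integers(0, 3, size=8), t=float(i)) for i in range(6)]
        triplets = classify(model, seq, window_size=1)
        assert len(triplets) == 6
        for tr, o in zip(triplets, seq):
            scores = np.log(model.pi) + emission_logprobs(model, o)
            assert tr.tension_score - 1 == int(np.argmax(scores))
            assert tr.timestamp == o.timestamp
            assert tr.observation is o

    def test_recovers_truth_from_well_separated_stream(self, rng):
        from castress.simulate import SimConfig, simulate_tension

        cfg = SimConfig(n_days=1, seed=99)
        truth = simulate_tension(cfg)
        em = cfg.true_emissions
        model = StressHMM(pi=cfg.true_pi, T=cfg.true_T, emissions=em)
        seq = []
        for t, score in zip(truth.times, truth.true_states):
            codes = [rng.choice(3, p=em[score - 1, s]) for s in range(8)]
            seq.append(obs(*codes, t=float(t)))
        triplets = classify(model, seq, window_size=4)
        pred = np.array([tr.tension_score for tr in triplets])
        acc = np.mean(pred == truth.true_states)
        assert acc > 0.8  # far above the 1/7 chance baseline

    def test_triplet_score_range_enforced(self):
        with pytest.raises(ValueError):
            ContextTriplet(timestamp=0.0, tension_score=9, observation=obs(*(0,) * 8))


class TestLabelBiasRobustness:
    def test_constant_bias_preserves_rank_structure(self):
        """Training on +1-shifted labels leaves the decoded/truth Spearman
        correlation nearly unchanged: constant reporter bias survives."""
        from scipy.stats import spearmanr

        from castress.pipeline import run_classify, run_train
        from castress.scheduler import generate_schedule
        from castress.simulate import (
            SimConfig,
            simulate_context,
            simulate_responses,
            simulate_tension,
        )

        rhos = {}
        for bias in (0, 1):
            cfg = SimConfig(n_days=7, seed=1234, reporter_bias=bias, reporter_noise=0.0)
            truth = simulate_tension(cfg)
            events = simulate_context(truth, cfg)
            sched = generate_schedule(n_days=7, seed=1234)
            resp = simulate_responses(truth, sched, cfg)
            model, _ = run_train(events, resp)
            triplets = run_classify(events, model)
            pred = np.array([t.tension_score for t in triplets])
            tt = truth.state_at(np.array([t.timestamp for t in triplets]))
            rhos[bias] = spearmanr(pred, tt).statistic
        assert rhos[0] > 0.5
        assert abs(rhos[1] - rhos[0]) < 0.1


def test_serialization_round_trip(tmp_path, random_small_hmm):
    model = random_small_hmm(4)
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = StressHMM.from_json(path)
    np.testing.assert_allclose(loaded.pi, model.pi)
    np.testing.assert_allclose(loaded.T, model.T)
    np.testing.assert_allclose(loaded.emissions, model.emissions)
    assert loaded.mode == model.mode


def test_parameter_recovery_from_long_simulation():
    """Fitting 10k labeled steps from a known model recovers T and emissions."""
    from castress.simulate import SimConfig, simulate_context, simulate_tension

    cfg = SimConfig(n_days=35, step_minutes=5.0, seed=77)  # ~10k steps
    truth = simulate_tension(cfg)
    events = simulate_context(truth, cfg)
    by_time = {}
    for e in events:
        by_time.setdefault(e.timestamp, []).append(e)
    from castress.features import build_observation

    observations = [
        build_observation(by_time[t], t, lookback=60.0) for t in sorted(by_time)
    ]
    seq = LabeledSequence(observations=observations, labels=list(truth.true_states))
    model = supervised_fit([seq], alpha=1.0)
    assert len(seq.labels) >= 10000
    assert np.abs(model.T - cfg.true_T).max() < 0.05
    tv = 0.5 * np.abs(model.emissions - cfg.true_emissions).sum(axis=-1)
    assert tv.max() < 0.05
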