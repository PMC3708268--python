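"""Discrete HMM: forward/backward, Baum–Welch, sampling, classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import (hmm_likelihood_enumeration,
                     hmm_state_posterior_enumeration,
                     hmm_transition_posterior_enumeration)
from lungcad.hmm import (HMMParams, backward, baum_welch, classify, forward,
                         init_params, sample)

WELL_SEPARATED = dict(pi=[0.6, 0.4], A=[[0.9, 0.1], [0.2, 0.8]],
                      B=[[0.95, 0.05], [0.1, 0.9]])


def random_params(rng, N, M):
    def rows(shape):
        w = rng.uniform(0.1, 1.0, size=shape)
        return w / w.sum(axis=-1, keepdims=True)
    return HMMParams(pi=rows(N), A=rows((N, N)), B=rows((N, M)))


def permuted_error(est: HMMParams, true: HMMParams) -> float:
    """Max entrywise |Δ| over A and B after best state permutation."""
    import itertools
    N = true.n_states
    best = np.inf
    for perm in itertools.permutations(range(N)):
        perm = list(perm)
        e = max(np.abs(est.A[np.ix_(perm, perm)] - true.A).max(),
                np.abs(est.B[perm] - true.B).max())
        best = min(best, e)
    return best


class TestParams:
    def test_row_stochasticity_enforced(self):
        with pytest.raises(ValueError):
            HMMParams(pi=[0.5, 0.5], A=[[0.9, 0.2], [0.5, 0.5]],
                      B=[[1.0], [1.0]])

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            HMMParams(pi=[1.5, -0.5], A=np.eye(2), B=np.eye(2))

    def test_json_roundtrip(self):
        p = HMMParams(**WELL_SEPARATED)
        q, label = HMMParams.from_json(p.to_json(label="nodule"))
        assert label == "nodule"
        assert np.allclose(p.A, q.A) and np.allclose(p.B, q.B)


class TestForward:
    def test_single_state_closed_form(self):
        p = HMMParams(pi=[1.0], A=[[1.0]], B=[[0.3, 0.7]])
        obs = [0, 1, 1, 0]
        _, _, ll = forward(p, obs)
        assert ll == pytest.approx(sum(np.log(p.B[0, o]) for o in obs))

    def test_deterministic_chain(self):
        p = HMMParams(pi=[1.0, 0.0], A=[[0.0, 1.0], [1.0, 0.0]],
                      B=[[1.0, 0.0], [0.0, 1.0]])
        assert forward(p, [0, 1, 0])[2] == pytest.approx(0.0)  # P = 1
        assert forward(p, [0, 0, 1])[2] == -np.inf             # P = 0

    def test_matches_enumeration(self, rng):
        p = random_params(rng, 2, 3)
        obs = rng.integers(0, 3, 4)
        _, _, ll = forward(p, obs)
        assert ll == pytest.approx(np.log(hmm_likelihood_enumeration(
            p.pi, p.A, p.B, obs)), rel=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(1, 3), st.integers(1, 6), st.integers(0, 10 ** 6))
    def test_property_equals_path_enumeration(self, N, T, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(2, 4))
        p = random_params(rng, N, M)
        obs = rng.integers(0, M, T)
        _, _, ll = forward(p, obs)
        expected = np.log(hmm_likelihood_enumeration(p.pi, p.A, p.B, obs))
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_agrees_with_hmmlearn(self, rng):
        # independent cross-check against an external implementation
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        p = random_params(rng, 3, 4)
        obs = rng.integers(0, 4, 50)
        model = hmmlearn.CategoricalHMM(n_components=3)
        model.startprob_, model.transmat_, model.emissionprob_ = p.pi, p.A, p.B
        expected = model.score(obs.reshape(-1, 1))
        assert forward(p, obs)[2] == pytest.approx(expected, rel=1e-10)

    def test_symbol_out_of_range_rejected(self):
        p = HMMParams(**WELL_SEPARATED)
        with pytest.raises(ValueError):
            forward(p, [0, 2])


class TestBackward:
    def test_alpha_beta_identity(self, rng):
        p = random_params(rng, 3, 3)
        obs = rng.integers(0, 3, 12)
        alpha, scales, _ = forward(p, obs)
        beta = backward(p, obs, scales)
        assert np.allclose((alpha * beta).sum(axis=1), 1.0, atol=1e-12)

    def test_base_case_is_one(self, rng):
        p = random_params(rng, 2, 2)
        obs = rng.integers(0, 2, 5)
        _, scales, _ = forward(p, obs)
        assert np.allclose(backward(p, obs, scales)[-1], 1.0)

    def test_posterior_matches_enumeration(self, rng):
        p = random_params(rng, 2, 3)
        obs = rng.integers(0, 3, 4)
        alpha, scales, _ = forward(p, obs)
        gamma = alpha * backward(p, obs, scales)
        expected = hmm_state_posterior_enumeration(p.pi, p.A, p.B, obs)
        assert np.allclose(gamma, expected, atol=1e-12)


class TestBaumWelch:
    def test_fixed_point_unchanged(self):
        p = HMMParams(pi=[1.0, 0.0], A=[[0.0, 1.0], [1.0, 0.0]],
                      B=[[1.0, 0.0], [0.0, 1.0]])
        obs = np.array([0, 1] * 10)
        res = baum_welch(p, obs, max_iter=5)
        assert np.allclose(res.params.A, p.A, atol=1e-9)
        assert np.allclose(res.params.B, p.B, atol=1e-9)

    def test_one_iteration_matches_enumeration_oracle(self, rng):
        # E-step posteriors by exhaustive path enumeration, M-step by the
        # expected-frequency re-estimates, computed independently
        p = random_params(rng, 2, 2)
        obs = np.array([0, 0, 1, 1])
        res = baum_welch(p, obs, max_iter=1, tol=0.0)
        gamma = hmm_state_posterior_enumeration(p.pi, p.A, p.B, obs)
        xi = hmm_transition_posterior_enumeration(p.pi, p.A, p.B, obs)
        exp_pi = gamma[0]
        exp_A = xi / gamma[:-1].sum(axis=0)[:, None]
        exp_B = np.stack([gamma[obs == k].sum(axis=0) for k in (0, 1)], axis=1)
        exp_B /= gamma.sum(axis=0)[:, None]
        assert np.allclose(res.params.pi, exp_pi, atol=1e-9)
        assert np.allclose(res.params.A, exp_A, atol=1e-9)
        assert np.allclose(res.params.B, exp_B, atol=1e-9)

    def test_loglik_monotone_and_stochastic(self, rng):
        for _ in range(3):
            p_true = random_params(rng, 2, 4)
            obs, _ = sample(p_true, 300, seed=int(rng.integers(10 ** 6)))
            res = baum_welch(random_params(rng, 2, 4), obs, max_iter=50)
            trace = np.array(res.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-8)
            res.params.validate()  # raises if any row drifted

    def test_parameter_recovery_well_separated(self):
        true = HMMParams(**WELL_SEPARATED)
        obs, _ = sample(true, 2000, seed=7)
        blend = 0.5
        init = HMMParams(pi=(1 - blend) * true.pi + blend * 0.5,
                         A=(1 - blend) * true.A + blend * 0.5,
                         B=(1 - blend) * true.B + blend * 0.5)
        res = baum_welch(init, obs, max_iter=200)
        assert permuted_error(res.params, true) < 0.05

    def test_concat_equals_separate_on_single_sequence(self, rng):
        p = random_params(rng, 2, 3)
        obs = rng.integers(0, 3, 40)
        r1 = baum_welch(p, [obs], max_iter=5, mode="concat")
        r2 = baum_welch(p, [obs], max_iter=5, mode="separate")
        assert np.allclose(r1.params.A, r2.params.A)
        assert np.allclose(r1.params.B, r2.params.B)
        assert np.allclose(r1.loglik_trace, r2.loglik_trace)

    def test_degenerate_constant_sequence_no_nan(self):
        init = init_params(2, 3, seed=0)
        res = baum_welch(init, np.zeros(30, dtype=int), max_iter=20)
        assert np.isfinite(res.params.A).all()
        assert np.isfinite(res.params.B).all()
        res.params.validate()


class TestSample:
    def test_deterministic_model_unique_sequence(self):
        p = HMMParams(pi=[1.0, 0.0], A=[[0.0, 1.0], [1.0, 0.0]],
                      B=[[1.0, 0.0], [0.0, 1.0]])
        obs, states = sample(p, 6, seed=0)
        assert list(obs) == [0, 1, 0, 1, 0, 1]
        assert list(states) == [0, 1, 0, 1, 0, 1]

    def test_empirical_frequencies_match_stationary(self):
        # stationary distribution by power iteration (independent route)
        p = HMMParams(**WELL_SEPARATED)
        v = np.array([0.5, 0.5])
        for _ in range(500):
            v = v @ p.A
        expected = v @ p.B
        obs, _ = sample(p, 100_000, seed=3)
        freq = np.bincount(obs, minlength=2) / len(obs)
        assert np.max(np.abs(freq - expected)) < 0.02

    def test_same_seed_reproducible(self):
        p = HMMParams(**WELL_SEPARATED)
        assert np.array_equal(sample(p, 50, seed=5)[0], sample(p, 50, seed=5)[0])

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            sample(HMMParams(**WELL_SEPARATED), 0)


class TestClassify:
    def _two_models(self):
        nodule = HMMParams(**WELL_SEPARATED)
        normal = HMMParams(pi=[0.5, 0.5], A=[[0.5, 0.5], [0.5, 0.5]],
                           B=[[0.3, 0.7], [0.6, 0.4]])
        return {"nodule": nodule, "normal": normal}

    def test_monte_carlo_accuracy(self):
        models = self._two_models()
        hits = 0
        for seed in range(200):
            obs, _ = sample(models["nodule"], 50, seed=seed)
            call, _ = classify(models, obs)
            hits += call == "nodule"
        assert hits >= 190  # >= 95%

    def test_identical_models_tie_to_first_sorted_label(self):
        p = HMMParams(**WELL_SEPARATED)
        models = {"b_model": p, "a_model": p}
        call, lls = classify(models, [0, 1, 0])
        assert call == "a_model"
        assert lls["a_model"] == lls["b_model"]

    def test_impossible_sequence_excluded(self):
        x = HMMParams(pi=[1.0], A=[[1.0]], B=[[1.0, 0.0]])
        y = HMMParams(pi=[1.0], A=[[1.0]], B=[[0.5, 0.5]])
        call, lls = classify({"x": x, "y": y}, [1, 0])
        assert call == "y"
        assert lls["x"] == -np.inf

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            classify(self._two_models(), [])
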