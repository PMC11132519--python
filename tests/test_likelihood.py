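"""Step likelihood, analytic gradients, and the four feedback mechanisms."""

import numpy as np
import pytest

from toh_feedback.likelihood import (
    fit_choice_model,
    loglik,
    loglik_from_logits,
    model_logits,
    next_state_features,
    param_count,
    step_counts,
)
from toh_feedback.planning import TaskMdp, feedback_array, solve
from toh_feedback.softq import graph_arrays, masked_logsumexp


@pytest.fixture(scope="module")
def setup3(graph3):
    arrays = graph_arrays(graph3)
    vt = solve(TaskMdp(graph=graph3, target="012"))
    H = feedback_array(vt)
    rng = np.random.default_rng(5)
    F = np.zeros((arrays.n_states, 4))
    for j, s in enumerate(rng.choice(arrays.n_states, size=4, replace=False)):
        F[s, j] = 1.0
    C = np.where(arrays.mask, rng.integers(0, 4, arrays.mask.shape), 0).astype(float)
    return arrays, F, H, C


class TestParameterCounts:
    def test_all_state_features_match_published_counts(self):
        assert [param_count(m, 81) for m in (1, 2, 3, 4)] == [81, 82, 82, 1]

    def test_sparse_features_match_published_counts(self):
        assert [param_count(m, 8) for m in (1, 2, 3, 4)] == [8, 9, 9, 1]

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            param_count(5, 8)


class TestLoglik:
    def test_uniform_myopic_loglik_counts_action_sets(self, graph3):
        arrays = graph_arrays(graph3)
        paths = [["000", "100", "120"], ["000", "200"]]
        C, n = step_counts(arrays, paths)
        assert n == 3
        val = loglik(1, arrays, np.zeros((27, 1)), None, C, np.zeros(1), gamma=0.0)
        expected = -sum(
            np.log(arrays.mask[arrays.index[s]].sum()) for s in ["000", "100", "000"]
        )
        assert val == pytest.approx(expected)

    def test_empty_dataset_gives_zero(self, graph3):
        arrays = graph_arrays(graph3)
        C, n = step_counts(arrays, [])
        assert n == 0
        assert loglik(1, arrays, np.zeros((27, 1)), None, C, np.zeros(1)) == 0.0

    def test_loglik_is_linear_in_counts(self, setup3):
        # doubling every trajectory doubles the log-likelihood, so the
        # unpenalized maximizer is unchanged under duplication
        arrays, F, H, C = setup3
        theta = np.array([0.3, -0.2, 0.8, 0.1])
        one = loglik(1, arrays, F, H, C, theta)
        two = loglik(1, arrays, F, H, 2 * C, theta)
        assert two == pytest.approx(2 * one)

    @pytest.mark.parametrize("model_id", [1, 2, 3, 4])
    def test_gradients_match_central_finite_differences(self, setup3, model_id):
        arrays, F, H, C = setup3
        rng = np.random.default_rng(17)
        theta = rng.normal(size=4)
        k = 0.6
        phi = next_state_features(arrays, F)
        L, dL, _ = model_logits(model_id, arrays, phi, H, theta, k, 0.9)
        _, grad = loglik_from_logits(L, arrays.mask, C, dL)
        P = dL.shape[2]
        eps = 1e-6
        for j in range(P):
            th, kk = theta.copy(), k

            def at(d):
                t2, k2 = theta.copy(), k
                if model_id == 4 or (model_id in (2, 3) and j == P - 1):
                    k2 = k + d
                else:
                    t2[j] += d
                L2, _, _ = model_logits(
                    model_id, arrays, phi, H, t2, k2, 0.9, want_grad=False
                )
                return loglik_from_logits(L2, arrays.mask, C)[0]

            fd = (at(eps) - at(-eps)) / (2 * eps)
            assert abs(grad[j] - fd) / max(abs(fd), 1e-8) < 1e-5


class TestModelMechanisms:
    def _policy(self, L, mask):
        V = masked_logsumexp(L, mask)
        return np.where(mask, np.exp(L - V[:, None]), 0.0)

    def test_zero_gain_collapses_models_2_and_3_to_model_1(self, setup3):
        arrays, F, H, _ = setup3
        theta = np.array([0.5, -0.3, 0.2, 0.9])
        phi = next_state_features(arrays, F)
        L1, _, _ = model_logits(1, arrays, phi, H, theta, 0.0, 0.9, want_grad=False)
        for mid in (2, 3):
            Lm, _, _ = model_logits(mid, arrays, phi, H, theta, 0.0, 0.9, want_grad=False)
            assert np.allclose(
                self._policy(Lm, arrays.mask), self._policy(L1, arrays.mask), atol=1e-8
            )

    def test_zero_gain_model_4_is_uniform(self, setup3):
        arrays, F, H, _ = setup3
        L4, _, _ = model_logits(4, arrays, None, H, np.zeros(4), 0.0, 0.9, want_grad=False)
        pol = self._policy(L4, arrays.mask)
        deg = arrays.mask.sum(axis=1)
        for i in range(arrays.n_states):
            assert pol[i, arrays.mask[i]] == pytest.approx(1.0 / deg[i])

    def test_large_gain_model_2_prefers_value_improving_moves(self, graph4, arrays4):
        vt = solve(TaskMdp(graph=graph4, target="0012"))
        H = feedback_array(vt)
        rng = np.random.default_rng(2)
        F = np.eye(81)[:, rng.choice(81, size=6, replace=False)]
        phi = next_state_features(arrays4, F)
        L, _, _ = model_logits(2, arrays4, phi, H, rng.normal(size=6), 10.0, 0.95,
                               want_grad=False)
        pol = self._policy(L, arrays4.mask)
        for i in range(81):
            if (H[i, arrays4.mask[i]] > 0).any():
                best = np.argmax(pol[i])
                assert H[i, best] > 0

    def test_missing_feedback_signal_rejected(self, setup3):
        arrays, F, _, _ = setup3
        phi = next_state_features(arrays, F)
        with pytest.raises(ValueError):
            model_logits(2, arrays, phi, None, np.zeros(4), 1.0, 0.9)


class TestFitting:
    def test_huge_penalty_drives_weights_to_zero(self, setup3):
        arrays, F, H, C = setup3
        res = fit_choice_model(1, arrays, F, H, C, int(C.sum()), lam=1e6, gamma=0.9)
        assert np.allclose(res.theta, 0.0)
        uniform = loglik(1, arrays, F, None, C, np.zeros(4), gamma=0.9)
        assert res.logL == pytest.approx(uniform)

    def test_fit_is_deterministic(self, setup3):
        arrays, F, H, C = setup3
        r1 = fit_choice_model(2, arrays, F, H, C, int(C.sum()), lam=0.2, gamma=0.9)
        r2 = fit_choice_model(2, arrays, F, H, C, int(C.sum()), lam=0.2, gamma=0.9)
        assert np.array_equal(r1.theta, r2.theta) and r1.k == r2.k
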