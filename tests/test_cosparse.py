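import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cosreg import (
    ADMMConfig,
    AnalysisOperator,
    DimensionError,
    PatchEnsemblePair,
    SparsityConfig,
    ValidationError,
    coherence_penalty_r,
    cosupport,
    joint_sparsity_g,
    learn_operators,
    learning_objective,
    mean_joint_sparsity,
    rank_penalty_h,
    sparsity_g,
)
from cosreg.cosparse import _joint_prox, _normalize_rows


def _random_operator(rng, k, n):
    return AnalysisOperator(_normalize_rows(rng.standard_normal((k, n))))


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation's vectorized paths)
# ---------------------------------------------------------------------------


def brute_g(alpha, nu):
    return sum(math.log(1.0 + nu * float(a) ** 2) for a in alpha)


def brute_joint_g(a, b, nu):
    return sum(math.log(1.0 + nu * (float(x) + float(y)) ** 2) for x, y in zip(a, b))


def brute_h(W, m):
    n = W.shape[1]
    eig = np.linalg.eigvalsh(W.T @ W / m)
    return -sum(math.log(e) for e in eig) / (n * math.log(n))


def brute_r(W):
    k = W.shape[0]
    total = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            total -= math.log(1.0 - float(W[i] @ W[j]) ** 2)
    return total


class TestSparsityG:
    def test_zero_vector_gives_zero(self):
        assert sparsity_g(np.zeros(5), nu=100.0) == 0.0

    def test_closed_form_log_two(self):
        assert np.isclose(sparsity_g(np.array([1.0]), nu=1.0), math.log(2.0))

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            a = rng.normal(size=8)
            assert np.isclose(sparsity_g(a, 100.0), brute_g(a, 100.0), atol=1e-9)

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=8))
    @settings(deadline=None, max_examples=50)
    def test_nonnegative_and_zero_iff_zero(self, vals):
        a = np.asarray(vals)
        g = sparsity_g(a, 10.0)
        assert g >= 0
        if np.all(a == 0):
            assert g == 0
        if g == 0:  # underflow-tolerant converse
            assert np.all(np.abs(a) < 1e-100)


class TestJointSparsityG:
    def test_zero_pair_gives_zero(self):
        assert joint_sparsity_g(np.zeros(4), np.zeros(4), 1e3) == 0.0

    def test_reduces_to_single_argument_form(self, rng):
        a = rng.normal(size=6)
        assert np.isclose(joint_sparsity_g(a, np.zeros(6), 50.0), sparsity_g(a, 50.0))

    def test_symmetric(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=6)
        assert np.isclose(joint_sparsity_g(a, b, 1e3), joint_sparsity_g(b, a, 1e3))

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=8), rng.normal(size=8)
            assert np.isclose(joint_sparsity_g(a, b, 1e3), brute_joint_g(a, b, 1e3), atol=1e-9)

    def test_length_mismatch_raises(self):
        with pytest.raises(DimensionError):
            joint_sparsity_g(np.zeros(3), np.zeros(4), 1.0)


class TestCosupport:
    def test_listed_example(self):
        # responses (0, 0.5, 0) -> co-support {0, 2}
        omega = AnalysisOperator(np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]]))
        x = np.array([0.0, 0.5])
        assert set(cosupport(omega, x, 1e-8)) == {0, 2}

    def test_zero_signal_has_full_cosupport(self, rng):
        op = _random_operator(rng, 10, 5)
        assert len(cosupport(op, np.zeros(5))) == 10

    def test_matches_naive_scan(self, rng):
        op = _random_operator(rng, 12, 6)
        x = rng.normal(size=6)
        tol = 0.5
        naive = {j for j in range(12) if abs(op.omega[j] @ x) <= tol}
        assert set(cosupport(op, x, tol)) == naive


class TestRankPenalty:
    def test_identity_closed_form_is_one(self):
        n = 6
        h = rank_penalty_h(AnalysisOperator(np.eye(n)), m_norm=n)
        assert np.isclose(h, 1.0, atol=1e-12)

    def test_rank_deficient_gives_inf_with_warning(self):
        W = _normalize_rows(np.array([[1.0, 1.0], [1.0, 1.0], [-1.0, -1.0]]))
        with pytest.warns(UserWarning):
            assert rank_penalty_h(AnalysisOperator(W)) == np.inf

    def test_matches_eigenvalue_oracle(self, rng):
        for _ in range(5):
            op = _random_operator(rng, 16, 8)
            assert np.isclose(rank_penalty_h(op), brute_h(op.omega, 16), atol=1e-9)


class TestCoherencePenalty:
    def test_orthogonal_rows_give_zero(self):
        assert coherence_penalty_r(AnalysisOperator(np.eye(5))) == 0.0

    def test_duplicate_rows_give_inf(self):
        W = _normalize_rows(np.vstack([np.ones((1, 4)), np.ones((1, 4)), np.eye(4)[:1]]))
        assert coherence_penalty_r(AnalysisOperator(W)) == np.inf

    def test_matches_pairwise_double_loop(self, rng):
        for _ in range(5):
            op = _random_operator(rng, 16, 8)
            assert np.isclose(coherence_penalty_r(op), brute_r(op.omega), atol=1e-9)


class TestLearningObjective:
    def _ensemble(self, rng, n=25, N=40, zero=False):
        X = np.zeros((n, N)) if zero else rng.normal(size=(n, N))
        return PatchEnsemblePair(X, X.copy(), int(np.sqrt(n)), np.zeros((N, 2), int), "NONE")

    def test_zero_ensemble_orthonormal_square_ops_leave_only_h(self, rng):
        n = 25
        cfg = SparsityConfig(k_rows=n + 1, m_norm=n)
        op = AnalysisOperator(np.eye(n))
        ens = self._ensemble(rng, n=n, zero=True)
        # g vanishes on zero data, r vanishes for orthogonal rows: kappa * 2h
        want = cfg.kappa * 2.0 * rank_penalty_h(op, cfg.m_norm)
        assert np.isclose(learning_objective((op, op), ens, cfg), want, atol=1e-12)

    def test_compositional_oracle(self, rng):
        n = 16
        cfg = SparsityConfig(k_rows=24)
        ens = self._ensemble(rng, n=n)
        op_a, op_b = _random_operator(rng, 24, n), _random_operator(rng, 24, n)
        want = (
            np.mean(
                [
                    joint_sparsity_g(op_a.omega @ ens.X_a[:, i], op_b.omega @ ens.X_b[:, i], cfg.nu)
                    for i in range(ens.count)
                ]
            )
            + cfg.kappa * (rank_penalty_h(op_a, cfg.m_norm) + rank_penalty_h(op_b, cfg.m_norm))
            + cfg.mu * (coherence_penalty_r(op_a) + coherence_penalty_r(op_b))
        )
        assert np.isclose(learning_objective((op_a, op_b), ens, cfg), want, atol=1e-9)

    def test_zero_scaling_leaves_penalties(self, rng):
        n = 16
        cfg = SparsityConfig(k_rows=24)
        ens = self._ensemble(rng, n=n)
        zero_ens = PatchEnsemblePair(0 * ens.X_a, 0 * ens.X_b, 4, ens.centers, "NONE")
        op_a, op_b = _random_operator(rng, 24, n), _random_operator(rng, 24, n)
        pen = cfg.kappa * (
            rank_penalty_h(op_a, cfg.m_norm) + rank_penalty_h(op_b, cfg.m_norm)
        ) + cfg.mu * (coherence_penalty_r(op_a) + coherence_penalty_r(op_b))
        assert np.isclose(learning_objective((op_a, op_b), zero_ens, cfg), pen)


class TestJointProx:
    def test_stationarity_of_solution(self, rng):
        S = np.abs(rng.normal(size=(50,))) * 2
        nu, rho, a_w = 1e3, 0.3, 1e-3
        t = _joint_prox(S, nu, rho, a_w)
        grad = 2 * a_w * nu * t / (1 + nu * t**2) + rho * (t - S)
        assert np.max(np.abs(grad)) < 1e-8
        assert np.all(t >= 0) and np.all(t <= S + 1e-12)


class TestLearnOperators:
    def test_same_seed_identical_operators(self, small_scene):
        from cosreg import extract_patch_pairs

        ens = extract_patch_pairs(small_scene.pa, small_scene.mr, 5, 300, seed=1)
        cfg = SparsityConfig(k_rows=30)
        a1, b1, _ = learn_operators(ens, cfg, ADMMConfig(max_iter=8), seed=2)
        a2, b2, _ = learn_operators(ens, cfg, ADMMConfig(max_iter=8), seed=2)
        assert np.array_equal(a1.omega, a2.omega)
        assert np.array_equal(b1.omega, b2.omega)

    def test_unit_rows_after_every_iteration(self, small_operators):
        _, _, state = small_operators
        assert max(state.row_norm_deviation) <= 1e-8

    def test_objective_eventually_non_increasing(self, small_operators):
        _, _, state = small_operators
        obj = np.asarray(state.objective_trace)
        tol = 1e-6 * np.abs(obj).max()
        assert np.all(obj[6:] - obj[5:-1] <= tol)

    def test_degenerate_identical_ensembles_are_symmetric(self, small_scene):
        from cosreg import extract_patch_pairs

        ens = extract_patch_pairs(small_scene.mr, small_scene.mr, 5, 300, seed=3)
        cfg = SparsityConfig(k_rows=30)
        op_a, op_b, _ = learn_operators(ens, cfg, ADMMConfig(max_iter=10), seed=4)
        # antisymmetric pair: per-operator penalty contributions match exactly
        assert abs(rank_penalty_h(op_a, cfg.m_norm) - rank_penalty_h(op_b, cfg.m_norm)) < 1e-6
        assert abs(coherence_penalty_r(op_a) - coherence_penalty_r(op_b)) < 1e-6
        # and the joint data term is exactly cancelled at alignment
        assert mean_joint_sparsity(op_a, op_b, ens.X_a, ens.X_b, cfg.nu) < 1e-20

    def test_learned_beats_random_on_held_out(self, small_scene):
        from cosreg import extract_patch_pairs

        ens = extract_patch_pairs(small_scene.pa, small_scene.mr, 5, 900, seed=5)
        train = PatchEnsemblePair(
            ens.X_a[:, :700], ens.X_b[:, :700], 5, ens.centers[:700]
        )
        cfg = SparsityConfig(k_rows=40)
        op_a, op_b, _ = learn_operators(train, cfg, ADMMConfig(max_iter=25), seed=6)
        i_a, i_b, _ = learn_operators(train, cfg, ADMMConfig(max_iter=0), seed=6)
        ho_a, ho_b = ens.X_a[:, 700:], ens.X_b[:, 700:]
        g_learned = mean_joint_sparsity(op_a, op_b, ho_a, ho_b, cfg.nu)
        g_init = mean_joint_sparsity(i_a, i_b, ho_a, ho_b, cfg.nu)
        assert g_learned < g_init

    def test_k_rows_must_exceed_patch_dim(self, small_scene):
        from cosreg import extract_patch_pairs

        ens = extract_patch_pairs(small_scene.pa, small_scene.mr, 5, 50, seed=1)
        with pytest.raises(ValidationError):
            learn_operators(ens, SparsityConfig(k_rows=25), ADMMConfig(max_iter=1), seed=0)


class TestAnalysisOperator:
    def test_unit_row_invariant_enforced(self, rng):
        with pytest.raises(ValidationError):
            AnalysisOperator(rng.normal(size=(8, 4)) * 3)
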