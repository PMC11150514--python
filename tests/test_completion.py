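import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mircomplete.completion import (
    SolverConfig,
    SolverState,
    admm_inner,
    build_target_matrix,
    compute_weights,
    project,
    solve,
    truncation_factors,
    update_E,
    update_T,
    update_X,
    weighted_svt,
)
from mircomplete.io import AssociationMatrix, LabeledMatrix, Role
from mircomplete.similarity import build_fused_similarities
from mircomplete.synthetic import hold_out_ones


def similarity(ids, values):
    return LabeledMatrix(ids, ids, np.asarray(values, dtype=float), Role.MM)


def toy_system():
    mm = similarity(["m1", "m2"], [[1.0, 0.5], [0.5, 1.0]])
    dd = similarity(["d1"], [[1.0]])
    assoc = AssociationMatrix(["m1", "m2"], ["d1"], np.array([[1.0], [0.0]]))
    return build_target_matrix(mm, assoc, dd)


class TestBuildTargetMatrix:
    def test_block_placement(self):
        system = toy_system()
        assert system.H.shape == (3, 3)
        assert system.H[0, 2] == 1.0  # association block entry
        assert system.H[2, 0] == 1.0  # transposed block
        assert system.H[0, 1] == 0.5

    def test_zero_association_omega_is_similarity_blocks_only(self):
        mm = similarity(["m1", "m2"], [[1.0, 0.5], [0.5, 1.0]])
        dd = similarity(["d1"], [[1.0]])
        assoc = AssociationMatrix(["m1", "m2"], ["d1"], np.zeros((2, 1)))
        system = build_target_matrix(mm, assoc, dd)
        assert system.mask[:2, :2].all() and system.mask[2, 2]
        assert not system.mask[:2, 2].any() and not system.mask[2, :2].any()

    def test_symmetry_of_h_and_mask(self, planted_small):
        mm, dd = build_fused_similarities(planted_small.assoc, planted_small.MM, planted_small.DD)
        system = build_target_matrix(mm, planted_small.assoc, dd)
        np.testing.assert_allclose(system.H, system.H.T)
        assert (system.mask == system.mask.T).all()


class TestProject:
    def test_empty_and_full_masks(self, rng):
        M = rng.normal(size=(4, 4))
        assert project(M, np.zeros((4, 4), bool)).sum() == 0
        np.testing.assert_array_equal(project(M, np.ones((4, 4), bool)), M)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 9999))
    def test_idempotent_and_linear(self, seed):
        rng = np.random.default_rng(seed)
        M, N = rng.normal(size=(2, 4, 4))
        mask = rng.random((4, 4)) < 0.5
        np.testing.assert_array_equal(project(project(M, mask), mask), project(M, mask))
        np.testing.assert_allclose(
            project(2 * M + 3 * N, mask), 2 * project(M, mask) + 3 * project(N, mask)
        )

    def test_index_list_and_bounds(self):
        M = np.arange(4.0).reshape(2, 2)
        out = project(M, [(0, 1)])
        assert out[0, 1] == 1.0 and out.sum() == 1.0
        with pytest.raises(IndexError):
            project(M, [(5, 0)])


class TestTruncationFactors:
    def test_orthonormality(self, rng):
        X = rng.normal(size=(6, 6))
        for r in (1, 3, 6):
            A, B = truncation_factors(X, r)
            np.testing.assert_allclose(A @ A.T, np.eye(r), atol=1e-10)
            np.testing.assert_allclose(B @ B.T, np.eye(r), atol=1e-10)

    def test_identity_matrix_gives_unit_overlap(self):
        A, B = truncation_factors(np.eye(4), 2)
        s = np.linalg.svd(B.T @ A, compute_uv=False)
        np.testing.assert_allclose(s[:2], [1.0, 1.0], atol=1e-12)

    def test_r_zero_empty_factors(self):
        A, B = truncation_factors(np.eye(3), 0)
        assert A.shape == (0, 3) and B.shape == (0, 3)
        assert (B.T @ A == 0).all()


class TestComputeWeights:
    def test_nuclear_norm_limit(self):
        A, B = truncation_factors(np.eye(3), 0)
        w = compute_weights(np.array([3.0, 2.0, 1.0]), A, B, p=1.0)
        np.testing.assert_allclose(w, np.ones(3))

    def test_truncation_zeroes_head(self, rng):
        X = rng.normal(size=(5, 5)) + 5 * np.eye(5)
        sigma = np.linalg.svd(X, compute_uv=False)
        A, B = truncation_factors(X, 2)
        w = compute_weights(sigma, A, B, p=1.0)
        np.testing.assert_allclose(w, [0, 0, 1, 1, 1], atol=1e-10)

    def test_p_half_hand_value(self):
        A, B = truncation_factors(np.eye(2), 0)
        w = compute_weights(np.array([4.0, 1.0]), A, B, p=0.5)
        np.testing.assert_allclose(w, [0.25, 0.5])

    def test_invalid_p(self):
        A, B = truncation_factors(np.eye(2), 0)
        with pytest.raises(ValueError):
            compute_weights(np.array([1.0, 1.0]), A, B, p=1.5)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 9999), p=st.floats(0.2, 1.0), r=st.integers(0, 4))
    def test_weights_non_decreasing(self, seed, p, r):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 6))
        sigma = np.linalg.svd(X, compute_uv=False)
        A, B = truncation_factors(X, r)
        w = compute_weights(sigma, A, B, p=p)
        assert np.all(np.diff(w) >= -1e-12)


class TestWeightedSvt:
    def test_zero_threshold_is_identity(self, rng):
        Q = rng.normal(size=(3, 3))
        np.testing.assert_array_equal(weighted_svt(Q, np.ones(3), 0.0), Q)

    def test_hand_example(self, example):
        out = weighted_svt(example.prox_q, example.prox_w, example.prox_tau)
        np.testing.assert_allclose(np.diag(out), example.expected["prox_result_diag"], atol=1e-12)
        np.testing.assert_allclose(out, np.diag(np.diag(out)), atol=1e-12)

    def test_unit_weights_match_classical_svt(self, rng):
        Q = rng.normal(size=(5, 5))
        tau = 0.3
        U, s, Vt = np.linalg.svd(Q, full_matrices=False)
        classical = (U * np.maximum(s - tau, 0.0)) @ Vt
        np.testing.assert_allclose(weighted_svt(Q, np.ones(5), tau), classical, atol=1e-12)

    def test_decreasing_weights_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            weighted_svt(np.eye(2), np.array([1.0, 0.5]), 0.1)


class TestAdmmUpdates:
    def test_update_t_empty_omega(self, rng):
        system = toy_system()
        system.mask[:] = False
        X = rng.uniform(0.2, 0.8, (3, 3))
        E = rng.normal(0, 0.1, (3, 3))
        out = update_T(X, E, system, alpha=20.0, beta=5.0)
        np.testing.assert_allclose(out, np.clip(X + E / 5.0, 0, 1))

    def test_update_t_clips_to_unit_box(self):
        system = toy_system()
        X = np.full((3, 3), 1.2)
        out = update_T(X, np.zeros((3, 3)), system, alpha=20.0, beta=5.0)
        assert out.max() <= 1.0 and out.min() >= 0.0

    def test_update_t_matches_elementwise_stationarity(self, rng):
        # independent solution of the quadratic subproblem: on omega
        # T = (alpha H + E + beta X)/(alpha+beta), off omega T = X + E/beta
        system = toy_system()
        system.H[:] = rng.uniform(0.3, 0.7, (3, 3))
        alpha, beta = 4.0, 3.0
        X = rng.uniform(0.3, 0.7, (3, 3))
        E = rng.uniform(-0.1, 0.1, (3, 3))
        expected = np.where(
            system.mask,
            (alpha * system.H + E + beta * X) / (alpha + beta),
            X + E / beta,
        )
        out = update_T(X, E, system, alpha, beta)
        np.testing.assert_allclose(out, expected, atol=1e-8)

    def test_update_x_no_shrinkage_with_zero_weights(self, rng):
        T = rng.normal(size=(4, 4))
        E = rng.normal(size=(4, 4))
        np.testing.assert_allclose(update_X(T, E, np.zeros(4), beta=2.0), T - E / 2.0, atol=1e-10)

    def test_update_x_approaches_t_for_large_beta(self, rng):
        T = rng.normal(size=(4, 4))
        out = update_X(T, np.zeros((4, 4)), np.ones(4), beta=1e8)
        np.testing.assert_allclose(out, T, atol=1e-6)

    def test_update_e_linear_in_gap(self, rng):
        E = rng.normal(size=(3, 3))
        X, T = rng.normal(size=(2, 3, 3))
        np.testing.assert_array_equal(update_E(E, X, X, 5.0), E)
        np.testing.assert_allclose(update_E(E, X, T, 1.0), E + (X - T))


class TestAdmmInner:
    def test_zero_budget_returns_initial_state(self):
        system = toy_system()
        cfg = SolverConfig(max_inner=0)
        state = SolverState(X=system.H.copy(), T=system.H.copy(), E=np.zeros_like(system.H))
        out = admm_inner(system, np.ones(3), cfg, state)
        assert not out.converged and out.inner_iter == 0
        np.testing.assert_array_equal(out.X, system.H)

    def test_fully_observed_fit_dominates(self, rng):
        n = 8
        L = rng.uniform(0.1, 0.6, size=(n, 3))
        H = np.clip(L @ L.T, 0, 1)
        np.fill_diagonal(H, 1.0)
        from mircomplete.completion import HeterogeneousSystem

        system = HeterogeneousSystem(H, np.ones((n, n), bool), (4, 4))
        cfg = SolverConfig(alpha=1e4, beta=1.0, r=0, p=1.0, max_inner=500, eps1=1e-6, eps2=1e-8)
        state = SolverState(X=H.copy(), T=H.copy(), E=np.zeros_like(H))
        out = admm_inner(system, np.ones(n), cfg, state)
        assert np.abs(out.X - H).max() < 1e-3

    def test_trace_is_recorded(self):
        system = toy_system()
        cfg = SolverConfig(max_inner=5)
        state = SolverState(X=system.H.copy(), T=system.H.copy(), E=np.zeros_like(system.H))
        out = admm_inner(system, np.ones(3), cfg, state)
        assert len(out.trace) == out.inner_iter
        assert all(np.isfinite(out.trace))


class TestSolve:
    def test_low_rank_fully_observed_fixed_point(self, rng):
        L = rng.uniform(0.1, 0.5, size=(10, 2))
        H = L @ L.T  # entries < 1, exactly rank 2
        from mircomplete.completion import HeterogeneousSystem

        system = HeterogeneousSystem(H, np.ones((10, 10), bool), (6, 4))
        cfg = SolverConfig(alpha=1e4, beta=1.0, r=5, max_inner=500, eps1=1e-6, eps2=1e-8)
        result = solve(system, cfg)
        assert np.abs(result.H_star - H).max() < 1e-3

    def test_masked_positives_score_above_unknowns(self, planted_small):
        rng = np.random.default_rng(0)
        train, held = hold_out_ones(planted_small.assoc, 0.4, rng)
        mm, dd = build_fused_similarities(train, planted_small.MM, planted_small.DD)
        result = solve(build_target_matrix(mm, train, dd))
        scores = result.A_star.values
        masked = scores[held[:, 0], held[:, 1]]
        never = scores[planted_small.assoc.values == 0]
        assert masked.mean() > never.mean()

    def test_known_positives_score_at_least_median(self, planted_small):
        mm, dd = build_fused_similarities(
            planted_small.assoc, planted_small.MM, planted_small.DD
        )
        result = solve(build_target_matrix(mm, planted_small.assoc, dd))
        scores = result.A_star.values
        known = scores[planted_small.assoc.values == 1]
        assert known.mean() >= np.median(scores)

    def test_output_in_unit_box_and_symmetric(self, planted_small):
        mm, dd = build_fused_similarities(planted_small.assoc, planted_small.MM, planted_small.DD)
        result = solve(build_target_matrix(mm, planted_small.assoc, dd))
        assert result.H_star.min() >= 0.0 and result.H_star.max() <= 1.0
        assert np.abs(result.H_star - result.H_star.T).max() <= 1e-8

    def test_default_config_accepted(self):
        cfg = SolverConfig()
        assert (cfg.alpha, cfg.beta, cfg.p, cfg.r) == (20.0, 5.0, 1.0, 5)
        cfg.validate(n=100)

    def test_invalid_rank_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(r=10).validate(n=10)

    def test_score_extraction_averages_twin_blocks(self, planted_small):
        mm, dd = build_fused_similarities(planted_small.assoc, planted_small.MM, planted_small.DD)
        system = build_target_matrix(mm, planted_small.assoc, dd)
        result = solve(system)
        nm, nd = system.block_layout
        expected = (result.H_star[:nm, nm:] + result.H_star[nm:, :nm].T) / 2
        np.testing.assert_allclose(result.A_star.values, expected)
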