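import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from oracles import qp_minnorm_kkt, smoothed_l21_constrained

from nmfl21 import (
    ExpressionMatrix,
    SolverConfig,
    build_reweighting,
    init_basis,
    l21_norm,
    nmf_l21_fit,
    smoothed_l21,
    weighted_minnorm_solve,
    woodbury_minnorm_solve,
)

# ---------------------------------------------------------------------------
# l21_norm
# ---------------------------------------------------------------------------


class TestL21Norm:
    def test_three_four_five_row(self):
        assert l21_norm(np.array([[3.0, 4.0], [0.0, 0.0]])) == pytest.approx(5.0)

    def test_zero_matrix(self):
        assert l21_norm(np.zeros((4, 7))) == 0.0

    def test_identity(self):
        assert l21_norm(np.eye(2)) == pytest.approx(2.0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            l21_norm(np.array([[1.0, np.nan]]))

    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(1, 6), st.integers(1, 6)),
            elements=st.floats(-100, 100),
        )
    )
    def test_matches_row_norm_sum(self, M):
        expected = sum(np.sqrt((row**2).sum()) for row in M)
        assert l21_norm(M) == pytest.approx(expected, abs=1e-9)

    @given(
        arrays(np.float64, (4, 3), elements=st.floats(-50, 50)),
        st.floats(0.01, 10.0),
    )
    def test_absolute_homogeneity(self, M, alpha):
        assert l21_norm(alpha * M) == pytest.approx(alpha * l21_norm(M), rel=1e-9, abs=1e-9)

    def test_zero_iff_zero_matrix(self):
        assert l21_norm(np.zeros((3, 3))) == 0.0
        assert l21_norm(np.array([[0.0, 1e-12], [0.0, 0.0]])) > 0.0


# ---------------------------------------------------------------------------
# build_reweighting
# ---------------------------------------------------------------------------


class TestBuildReweighting:
    def test_unit_and_zero_rows(self):
        U = np.array([[1.0, 0.0], [0.0, 0.0]])
        q = build_reweighting(U, 1e-8)
        assert q[0] == pytest.approx(0.5, rel=1e-6)
        assert q[1] == pytest.approx(1.0 / (2.0 * 1e-4))

    def test_all_zero_rows(self):
        q = build_reweighting(np.zeros((5, 3)), 0.25)
        np.testing.assert_allclose(q, np.ones(5))

    def test_row_norms_three_four(self):
        U = np.array([[3.0, 0.0], [0.0, 4.0]])
        q = build_reweighting(U, 1e-16)
        np.testing.assert_allclose(q, [1 / 6, 1 / 8], rtol=1e-9)

    @pytest.mark.parametrize("eps", [0.0, -1.0])
    def test_rejects_nonpositive_epsilon(self, eps):
        with pytest.raises(ValueError, match="epsilon"):
            build_reweighting(np.ones((2, 2)), eps)

    @given(
        arrays(np.float64, (5, 3), elements=st.floats(-1e3, 1e3)),
        st.floats(1e-12, 1.0),
    )
    def test_always_finite_positive(self, U, eps):
        q = build_reweighting(U, eps)
        assert np.all(np.isfinite(q)) and np.all(q > 0)


# ---------------------------------------------------------------------------
# weighted_minnorm_solve
# ---------------------------------------------------------------------------


class TestWeightedMinnormSolve:
    def test_identity_B_returns_X(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 3))
        q = rng.uniform(0.5, 2.0, size=4)
        np.testing.assert_allclose(weighted_minnorm_solve(np.eye(4), q, X), X, atol=1e-12)

    def test_orthonormal_rows_unit_weights(self):
        # B with orthonormal rows, q = 1: min-norm solution is B^T X
        B = np.array([[1.0, 0.0, 0.0], [0.0, 0.6, 0.8]])
        X = np.array([[1.0], [2.0]])
        U = weighted_minnorm_solve(B, np.ones(3), X)
        np.testing.assert_allclose(U, B.T @ X, atol=1e-12)

    def test_matches_kkt_oracle(self):
        rng = np.random.default_rng(7)
        B = rng.normal(size=(5, 9))
        q = rng.uniform(0.2, 3.0, size=9)
        X = rng.normal(size=(5, 2))
        np.testing.assert_allclose(
            weighted_minnorm_solve(B, q, X), qp_minnorm_kkt(B, q, X), rtol=1e-6, atol=1e-9
        )

    def test_feasibility(self):
        rng = np.random.default_rng(3)
        B = rng.normal(size=(6, 10))
        q = rng.uniform(0.1, 5.0, size=10)
        X = rng.normal(size=(6, 4))
        U = weighted_minnorm_solve(B, q, X)
        assert np.linalg.norm(B @ U - X) / np.linalg.norm(X) < 1e-10

    def test_rejects_nonpositive_weights(self):
        with pytest.raises(ValueError, match="positive"):
            weighted_minnorm_solve(np.eye(2), np.array([1.0, 0.0]), np.eye(2))

    def test_singular_system_raises(self):
        B = np.zeros((2, 3))  # rank deficient
        with pytest.raises(np.linalg.LinAlgError, match="row rank"):
            weighted_minnorm_solve(B, np.ones(3), np.ones((2, 1)))


# ---------------------------------------------------------------------------
# woodbury_minnorm_solve
# ---------------------------------------------------------------------------


class TestWoodburyMinnormSolve:
    def test_toy_matches_dense_path(self):
        rng = np.random.default_rng(1)
        n, d, c = 3, 1, 2
        A = rng.uniform(0.1, 1.0, size=(n, d))
        lam = 0.7
        qY = rng.uniform(0.5, 2.0, size=d)
        qE = rng.uniform(0.5, 2.0, size=n)
        X = rng.normal(size=(n, c))
        B = np.hstack([A, lam * np.eye(n)])
        dense = weighted_minnorm_solve(B, np.concatenate([qY, qE]), X)
        fast = woodbury_minnorm_solve(A, lam, qY, qE, X)
        np.testing.assert_allclose(fast, dense, rtol=1e-10, atol=1e-12)

    def test_zero_basis_puts_all_mass_in_E(self):
        X = np.arange(6, dtype=float).reshape(3, 2) + 1.0
        U = woodbury_minnorm_solve(np.zeros((3, 2)), 1.0, np.ones(2), np.ones(3), X)
        np.testing.assert_allclose(U[:2], 0.0, atol=1e-12)
        np.testing.assert_allclose(U[2:], X, atol=1e-12)

    def test_large_instance_matches_dense_path(self):
        rng = np.random.default_rng(5)
        n, d, c = 2000, 3, 8
        A = rng.uniform(0.0, 1.0, size=(n, d))
        lam = 0.3
        qY = rng.uniform(0.2, 2.0, size=d)
        qE = rng.uniform(0.2, 2.0, size=n)
        X = rng.uniform(0.0, 1.0, size=(n, c))
        B = np.hstack([A, lam * np.eye(n)])
        dense = weighted_minnorm_solve(B, np.concatenate([qY, qE]), X)
        fast = woodbury_minnorm_solve(A, lam, qY, qE, X)
        np.testing.assert_allclose(fast, dense, rtol=1e-8, atol=1e-10)

    def test_rejects_nonpositive_lambda(self):
        with pytest.raises(ValueError, match="lam"):
            woodbury_minnorm_solve(np.ones((2, 1)), 0.0, np.ones(1), np.ones(2), np.ones((2, 1)))


# ---------------------------------------------------------------------------
# nmf_l21_fit
# ---------------------------------------------------------------------------


def _expr(values: np.ndarray) -> ExpressionMatrix:
    n, c = values.shape
    return ExpressionMatrix(
        values, tuple(f"g{i}" for i in range(n)), tuple(f"s{j}" for j in range(c))
    )


class TestFit:
    def test_zero_input(self):
        cfg = SolverConfig(lam=0.3, d=1, seed=0, epsilon=1e-8)
        result = nmf_l21_fit(_expr(np.zeros((10, 4))), cfg)
        np.testing.assert_allclose(result.Y, 0.0)
        np.testing.assert_allclose(result.E, 0.0)
        assert result.converged and result.n_iter <= 2
        # for U = 0 the smoothed objective is b * sqrt(epsilon), a pure epsilon constant
        assert result.objective_trace[-1] == pytest.approx(result.b * np.sqrt(1e-8))

    def test_u_stacks_y_then_e(self, planted_instance, default_config):
        X, _ = planted_instance
        result = nmf_l21_fit(X, default_config)
        d = default_config.d
        np.testing.assert_array_equal(result.U[:d], result.Y)
        np.testing.assert_array_equal(result.U[d:], result.E)
        assert result.b == d + X.n_genes

    def test_basis_fixed_and_nonnegative(self, planted_instance, default_config):
        X, _ = planted_instance
        result = nmf_l21_fit(X, default_config)
        np.testing.assert_array_equal(
            result.A, init_basis(X.n_genes, default_config.d, default_config.seed)
        )
        assert np.all(result.A >= 0)

    def test_clamp_makes_u_nonnegative(self, planted_instance, default_config):
        X, _ = planted_instance
        result = nmf_l21_fit(X, default_config)
        assert np.all(result.U >= 0)

    def test_matches_generic_convex_solver_4x2(self):
        rng = np.random.default_rng(11)
        X = _expr(rng.uniform(0.5, 2.0, size=(4, 2)))
        eps = 1e-8
        cfg = SolverConfig(lam=0.3, d=1, seed=0, epsilon=eps, clamp=False, max_iter=500, tol=1e-12)
        result = nmf_l21_fit(X, cfg)
        B = np.hstack([result.A, cfg.lam * np.eye(4)])
        assert np.linalg.norm(B @ result.U - X.values) < 1e-6
        oracle = smoothed_l21_constrained(B, X.values, eps)
        # compare objective values: both should sit at the shared optimum
        assert smoothed_l21(result.U, eps) == pytest.approx(smoothed_l21(oracle, eps), rel=1e-3)
        np.testing.assert_allclose(result.U, oracle, rtol=1e-3, atol=1e-4)

    def test_recovers_planted_rows(self, planted_instance, default_config):
        X, truth = planted_instance
        result = nmf_l21_fit(X, default_config)
        row_norms = np.linalg.norm(result.E, axis=1)
        top10 = set(np.argsort(-row_norms)[:10])
        assert top10 == set(truth.outlier_rows)

    def test_rejects_negative_input(self, default_config):
        with pytest.raises(ValueError, match="negative"):
            nmf_l21_fit(np.array([[1.0, -1.0]]), default_config)

    def test_rank_warning(self):
        X = _expr(np.random.default_rng(0).uniform(size=(5, 3)))
        with pytest.warns(UserWarning, match="min\\(n, c\\)"):
            nmf_l21_fit(X, SolverConfig(lam=0.3, d=3, seed=0))

    def test_rejects_nonpositive_lambda(self):
        with pytest.raises(ValueError, match="lam must be > 0"):
            SolverConfig(lam=0.0)


class TestFitProperties:
    @pytest.mark.parametrize("seed", range(20))
    def test_monotone_descent_without_clamp(self, seed):
        rng = np.random.default_rng(seed)
        X = _expr(rng.uniform(0.0, 2.0, size=(30, 6)))
        cfg = SolverConfig(lam=0.4, d=2, seed=seed, clamp=False, max_iter=60)
        trace = nmf_l21_fit(X, cfg).objective_trace
        diffs = np.diff(trace)
        assert np.all(diffs <= 1e-10), f"objective increased by {diffs.max()}"

    def test_feasible_before_clamp(self):
        # one sweep with clamping off ends exactly at the solve output
        rng = np.random.default_rng(2)
        X = _expr(rng.uniform(0.1, 1.0, size=(25, 5)))
        cfg = SolverConfig(lam=0.5, d=2, seed=2, clamp=False, max_iter=1)
        result = nmf_l21_fit(X, cfg)
        B = np.hstack([result.A, cfg.lam * np.eye(25)])
        assert np.linalg.norm(B @ result.U - X.values) / np.linalg.norm(X.values) < 1e-8

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fast_and_dense_paths_agree(self, seed):
        rng = np.random.default_rng(seed)
        X = _expr(rng.uniform(0.0, 1.0, size=(40, 6)))
        base = dict(lam=0.5, d=2, seed=seed, max_iter=30)
        fast = nmf_l21_fit(X, SolverConfig(fast_path=True, **base))
        dense = nmf_l21_fit(X, SolverConfig(fast_path=False, **base))
        np.testing.assert_allclose(fast.U, dense.U, rtol=1e-8, atol=1e-10)

    def test_larger_lambda_shrinks_coefficients(self):
        rng = np.random.default_rng(9)
        X = _expr(rng.uniform(0.0, 2.0, size=(50, 6)))
        small = nmf_l21_fit(X, SolverConfig(lam=0.1, d=2, seed=9))
        large = nmf_l21_fit(X, SolverConfig(lam=1.0, d=2, seed=9))
        assert l21_norm(large.Y) <= l21_norm(small.Y) + 1e-9
        # mass the basis no longer explains shifts into the residual term
        resid_small = l21_norm(X.values - small.A @ small.Y)
        resid_large = l21_norm(X.values - large.A @ large.Y)
        assert resid_large >= resid_small - 1e-9

    def test_zero_gene_rows_score_near_bottom(self):
        # an all-zero gene row carries (almost) no sparse-component mass:
        # its E row norm is tiny relative to every expressed gene's
        rng = np.random.default_rng(4)
        values = rng.uniform(0.5, 1.5, size=(20, 4))
        values[[3, 7]] = 0.0
        result = nmf_l21_fit(_expr(values), SolverConfig(lam=0.3, d=2, seed=4))
        norms = np.linalg.norm(result.E, axis=1)
        expressed = np.delete(norms, [3, 7])
        assert norms[3] < 0.05 * expressed.min()
        assert norms[7] < 0.05 * expressed.min()


class TestExpressionMatrix:
    def test_rejects_negative(self):
        with pytest.raises(ValueError, match="negative"):
            ExpressionMatrix(np.array([[1.0, -0.5]]), ("g0",), ("s0", "s1"))

    def test_rejects_duplicate_gene_ids(self):
        with pytest.raises(ValueError, match="duplicate gene id"):
            ExpressionMatrix(np.ones((2, 1)), ("g0", "g0"), ("s0",))

    def test_rejects_nan(self):
        with pytest.raises(ValueError, match="non-finite"):
            ExpressionMatrix(np.array([[np.nan]]), ("g0",), ("s0",))

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(np.ones((0, 3)), (), ("a", "b", "c"))


class TestSolverConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lam": -0.1},
            {"epsilon": 0.0},
            {"tol": 0.0},
            {"max_iter": 0},
            {"d": 0},
        ],
    )
    def test_invalid_settings(self, kwargs):
        with pytest.raises(ValueError):
            SolverConfig(**kwargs)

    @settings(max_examples=25, deadline=None)
    @given(st.floats(1e-3, 10.0), st.integers(1, 4))
    def test_valid_settings_roundtrip(self, lam, d):
        cfg = SolverConfig(lam=lam, d=d)
        assert cfg.lam == lam and cfg.d == d
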