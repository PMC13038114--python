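"""Penalized-regression solvers against closed forms, KKT conditions and
a quadratic-programming oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import optimize

from netrl.graphs import WeightedGraph, normalized_laplacian
from netrl.solvers import (
    DesignData,
    PenaltyGrid,
    bic,
    estimate_sigma2,
    fit_adaptive_lasso,
    fit_elastic_net,
    fit_lasso,
    fit_network_lasso,
    select_by_bic,
)


def make_design(rng, n=30, q=5, standardize=True):
    X = rng.standard_normal((n, q))
    beta = np.zeros(q)
    beta[: min(2, q)] = [2.0, -1.5][: min(2, q)]
    y = X @ beta + 0.3 * rng.standard_normal(n)
    return DesignData.build(X, y, standardize=standardize)


def qp_solve(X, y, lambda1, M=None, lambda2=0.0):
    """Split-variable bound-constrained oracle for
    1/2||y-Xb||^2 + l1||b||_1 + l2 b'Mb."""
    q = X.shape[1]

    def objective(z):
        b = z[:q] - z[q:]
        r = y - X @ b
        val = 0.5 * r @ r + lambda1 * z.sum()
        if M is not None and lambda2 > 0:
            val += lambda2 * b @ M @ b
        return val

    def grad(z):
        b = z[:q] - z[q:]
        g = -(X.T @ (y - X @ b))
        if M is not None and lambda2 > 0:
            g = g + 2.0 * lambda2 * (M @ b)
        return np.concatenate([g + lambda1, -g + lambda1])

    res = optimize.minimize(
        objective, np.zeros(2 * q), jac=grad, method="L-BFGS-B",
        bounds=[(0, None)] * 2 * q,
        options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-12},
    )
    return res.x[:q] - res.x[q:], res.fun


def lasso_objective(d, beta, lambda1):
    r = d.y - d.X @ beta
    return 0.5 * r @ r + lambda1 * np.abs(beta).sum()


class TestLasso:
    def test_zero_penalty_gives_ols(self, rng):
        d = make_design(rng, n=40, q=4)
        fit = fit_lasso(d, 0.0)
        ols = np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        assert np.allclose(fit.coefficients, ols, atol=1e-8)

    def test_penalty_above_critical_value_zeroes_everything(self, rng):
        d = make_design(rng)
        lam_max = np.max(np.abs(d.X.T @ d.y))
        fit = fit_lasso(d, lam_max * 1.0001)
        assert np.all(fit.coefficients == 0)
        assert fit.df_hat == 0

    def test_orthonormal_design_soft_threshold(self, rng):
        A = rng.standard_normal((30, 4))
        Q, _ = np.linalg.qr(A)
        y = rng.standard_normal(30)
        y -= y.mean()
        d = DesignData(X=Q, y=y, column_ids=list("abcd"), standardized=False)
        lam = 0.1
        fit = fit_lasso(d, lam)
        z = Q.T @ y
        expect = np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)
        assert np.allclose(fit.coefficients, expect, atol=1e-8)

    def test_kkt_conditions_hold(self, rng):
        for _ in range(5):
            d = make_design(rng, n=25, q=6)
            lam = 0.3 * np.max(np.abs(d.X.T @ d.y))
            fit = fit_lasso(d, lam)
            r = d.y - d.X @ fit.coefficients
            g = d.X.T @ r
            active = fit.coefficients != 0
            assert np.all(np.abs(g[~active]) <= lam + 1e-6)
            assert np.allclose(
                g[active], lam * np.sign(fit.coefficients[active]), atol=1e-6
            )

    def test_nan_rejected(self, rng):
        d = make_design(rng)
        d.X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_lasso(d, 0.1)


class TestAdaptiveLasso:
    def test_unit_weights_reduce_to_lasso(self, rng):
        d = make_design(rng)
        lam = 0.2 * np.max(np.abs(d.X.T @ d.y))
        a = fit_adaptive_lasso(d, lam, init_coef=np.ones(d.q))
        b = fit_lasso(d, lam)
        assert np.allclose(a.coefficients, b.coefficients, atol=1e-8)

    def test_zero_penalty_gives_ols(self, rng):
        d = make_design(rng, n=40, q=4)
        fit = fit_adaptive_lasso(d, 0.0, init_coef=np.ones(4))
        ols = np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        assert np.allclose(fit.coefficients, ols, atol=1e-8)

    def test_zero_initial_coefficient_excludes_predictor(self, rng):
        d = make_design(rng, q=4)
        init = np.array([1.0, 0.0, 1.0, 1.0])
        fit = fit_adaptive_lasso(d, 0.05, init_coef=init)
        assert fit.coefficients[1] == 0.0

    def test_large_initial_coefficient_enters_path_first(self, rng):
        # three equally informative predictors; the one with a huge
        # initial estimate is penalized least and activates first
        X = rng.standard_normal((50, 3))
        y = X @ np.array([1.0, 1.0, 1.0]) + 0.01 * rng.standard_normal(50)
        d = DesignData.build(X, y)
        init = np.array([0.5, 50.0, 0.5])
        lam_hi = 0.9 * np.max(np.abs(d.X.T @ d.y) * np.abs(init)) / np.max(np.abs(init))
        # at a penalty where cheap predictors are still excluded
        w = 1.0 / np.abs(init)
        lam_entry = np.abs(d.X.T @ d.y) / w
        lam = 0.5 * (np.sort(lam_entry)[-1] + np.sort(lam_entry)[-2])
        fit = fit_adaptive_lasso(d, lam, init_coef=init)
        assert fit.coefficients[1] != 0.0
        del lam_hi

    def test_ols_weights_require_low_dimension(self, rng):
        X = rng.standard_normal((5, 8))
        y = rng.standard_normal(5)
        d = DesignData.build(X, y)
        with pytest.raises(ValueError, match="ridge"):
            fit_adaptive_lasso(d, 0.1, weight_source="ols")


class TestElasticNet:
    def test_delta_one_equals_lasso(self, rng):
        d = make_design(rng)
        lam = 0.2 * np.max(np.abs(d.X.T @ d.y))
        assert np.allclose(
            fit_elastic_net(d, lam, 1.0).coefficients,
            fit_lasso(d, lam).coefficients,
        )

    def test_delta_zero_is_ridge_closed_form(self, rng):
        d = make_design(rng, n=25, q=5)
        lam = 2.0
        fit = fit_elastic_net(d, lam, 0.0)
        expect = np.linalg.solve(d.X.T @ d.X + lam * np.eye(5), d.X.T @ d.y)
        assert np.allclose(fit.coefficients, expect, atol=1e-10)

    def test_identical_columns_share_the_coefficient(self, rng):
        x = rng.standard_normal(40)
        z = rng.standard_normal(40)
        X = np.column_stack([x, x, z])
        y = 2 * x + z + 0.1 * rng.standard_normal(40)
        d = DesignData(X=X - X.mean(0), y=y - y.mean(), column_ids=list("abc"),
                       standardized=False)
        fit = fit_elastic_net(d, 1.0, 0.5)
        assert fit.coefficients[0] == pytest.approx(fit.coefficients[1], abs=1e-6)

    def test_delta_out_of_range_rejected(self, rng):
        d = make_design(rng)
        with pytest.raises(ValueError):
            fit_elastic_net(d, 1.0, 1.2)

    def test_matches_qp_oracle(self, rng):
        d = make_design(rng, n=20, q=3)
        lam, delta = 1.5, 0.6
        fit = fit_elastic_net(d, lam, delta)
        beta_qp, _ = qp_solve(
            d.X, d.y, lam * delta, M=0.5 * np.eye(3), lambda2=lam * (1 - delta) / 2 * 2
        )
        # QP M-term: lambda2 b'Mb with M=I/2 and lambda2=lam*(1-delta)
        beta_qp2, _ = qp_solve(d.X, d.y, lam * delta, M=np.eye(3),
                               lambda2=lam * (1 - delta) / 2)
        assert np.allclose(fit.coefficients, beta_qp2, atol=1e-5)
        del beta_qp


class TestNetworkLasso:
    def make_laplacian(self, rng, q):
        W = np.abs(rng.standard_normal((q, q)))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0)
        return normalized_laplacian(
            WeightedGraph(tuple(f"g{i}" for i in range(q)), W)
        )

    def test_zero_lambda2_reduces_to_lasso(self, rng):
        d = make_design(rng, q=4)
        L = self.make_laplacian(rng, 4)
        lam = 0.5
        a = fit_network_lasso(d, lam, 0.0, L, np.ones(4))
        b = fit_lasso(d, lam)
        assert np.allclose(a.coefficients, b.coefficients)

    def test_empty_graph_reduces_to_lasso_for_any_lambda2(self, rng):
        d = make_design(rng, q=3)
        L = normalized_laplacian(WeightedGraph(("a", "b", "c"), np.zeros((3, 3))))
        a = fit_network_lasso(d, 0.4, 5.0, L, np.ones(3))
        b = fit_lasso(d, 0.4)
        assert np.allclose(a.coefficients, b.coefficients)

    def test_strong_laplacian_penalty_fuses_connected_duplicates(self, rng):
        x = rng.standard_normal(60)
        X = np.column_stack([x, x])
        y = 3 * x + 0.05 * rng.standard_normal(60)
        d = DesignData(X=X - X.mean(0), y=y - y.mean(), column_ids=("a", "b"),
                       standardized=False)
        L = normalized_laplacian(
            WeightedGraph(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        )
        fit = fit_network_lasso(d, 0.01, 500.0, L, np.array([1.0, 1.0]))
        assert abs(fit.coefficients[0] - fit.coefficients[1]) < 1e-3

    def test_matches_qp_oracle_on_small_problems(self, rng):
        for _ in range(20):
            q = int(rng.integers(2, 5))
            d = make_design(rng, n=15, q=q)
            L = self.make_laplacian(rng, q)
            s = rng.choice([-1.0, 1.0], q)
            lam1 = float(0.2 * np.max(np.abs(d.X.T @ d.y)))
            lam2 = float(rng.choice([0.1, 1.0, 5.0]))
            fit = fit_network_lasso(d, lam1, lam2, L, s)
            M = (s[:, None] * L.matrix) * s[None, :]
            beta_qp, f_qp = qp_solve(d.X, d.y, lam1, M=M, lambda2=lam2)
            r = d.y - d.X @ fit.coefficients
            f_fit = (0.5 * r @ r + lam1 * np.abs(fit.coefficients).sum()
                     + lam2 * fit.coefficients @ M @ fit.coefficients)
            assert f_fit <= f_qp + 1e-6 * (1 + abs(f_qp))
            assert np.allclose(fit.coefficients, beta_qp, atol=1e-4)

    def test_non_psd_matrix_rejected(self, rng):
        d = make_design(rng, q=2)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalue -1
        with pytest.raises(ValueError, match="semidefinite"):
            fit_network_lasso(d, 0.1, 1.0, bad, np.ones(2))

    def test_dimension_mismatch_rejected(self, rng):
        d = make_design(rng, q=3)
        with pytest.raises(ValueError, match="match"):
            fit_network_lasso(d, 0.1, 1.0, np.eye(4), np.ones(4))


class TestBic:
    def test_perfect_fit_counts_only_df(self, rng):
        X = np.eye(10)[:, :3]
        beta = np.array([1.0, 2.0, 3.0])
        d = DesignData(X=X, y=X @ beta, column_ids=list("abc"), standardized=False)
        from netrl.solvers import FitResult

        fit = FitResult(coefficients=beta, lambda1=0.0, rss=0.0)
        assert bic(fit, d, 1.0) == pytest.approx(3 * math.log(10) / 10)

    def test_null_model_is_scaled_response_energy(self, rng):
        y = rng.standard_normal(12)
        y -= y.mean()
        d = DesignData(X=rng.standard_normal((12, 3)), y=y,
                       column_ids=list("abc"), standardized=False)
        from netrl.solvers import FitResult

        fit = FitResult(coefficients=np.zeros(3), lambda1=1.0, rss=float(y @ y))
        assert bic(fit, d, 2.0) == pytest.approx(float(y @ y) / (12 * 2.0))

    def test_matches_direct_formula(self, rng):
        d = make_design(rng)
        fit = fit_lasso(d, 0.5)
        s2 = 1.3
        expect = fit.rss / (d.n * s2) + math.log(d.n) / d.n * fit.df_hat
        assert bic(fit, d, s2) == pytest.approx(expect)

    def test_invalid_inputs(self, rng):
        d = make_design(rng)
        fit = fit_lasso(d, 0.5)
        with pytest.raises(ValueError):
            bic(fit, d, 0.0)


class TestSigma2:
    def test_ols_branch_is_exact_residual_variance(self, rng):
        d = make_design(rng, n=30, q=4)
        beta = np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        rss = float(np.sum((d.y - d.X @ beta) ** 2))
        assert estimate_sigma2(d) == pytest.approx(rss / 26)

    def test_override_wins(self, rng):
        d = make_design(rng)
        assert estimate_sigma2(d, value=4.2) == 4.2

    def test_high_dimensional_pure_noise_tracks_response_variance(self):
        ratios = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.standard_normal((40, 60))
            y = r.standard_normal(40)
            d = DesignData.build(X, y)
            ratios.append(estimate_sigma2(d) / np.var(y, ddof=1))
        assert 0.5 < float(np.median(ratios)) < 1.5


class TestSelectByBic:
    def test_single_point_grid_returns_that_fit(self, rng):
        d = make_design(rng)
        grid = PenaltyGrid(lambda1_values=np.array([0.7]))
        fit = select_by_bic(d, grid, method="lasso", sigma2=1.0)
        direct = fit_lasso(d, 0.7)
        assert np.allclose(fit.coefficients, direct.coefficients)

    def test_tie_goes_to_larger_lambda1(self, rng):
        d = make_design(rng)
        lam_max = float(np.max(np.abs(d.X.T @ d.y)))
        # both penalties exceed the critical value: identical null fits
        grid = PenaltyGrid(lambda1_values=np.array([2 * lam_max, 3 * lam_max]))
        fit = select_by_bic(d, grid, method="lasso", sigma2=1.0)
        assert fit.lambda1 == 3 * lam_max

    def test_prefers_sparse_model_on_pure_noise(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        d = DesignData.build(X, y)
        lam_max = float(np.max(np.abs(d.X.T @ d.y)))
        grid = PenaltyGrid(lambda1_values=np.array([lam_max * 1.01, 0.0]))
        fit = select_by_bic(d, grid, method="lasso")
        assert fit.df_hat == 0

    def test_network_method_requires_laplacian(self, rng):
        d = make_design(rng)
        with pytest.raises(ValueError, match="Laplacian"):
            select_by_bic(d, PenaltyGrid(), method="network-lasso")

    def test_agrees_with_gram_path_selection(self, rng):
        """The reference grid search and the ensemble fast path must pick
        fits with matching support on a clear-cut problem."""
        from netrl._cd import lambda_grid
        from netrl.pipeline import _bic_best

        d = make_design(rng, n=40, q=6)
        s2 = 1.0
        lam_max = float(np.max(np.abs(d.X.T @ d.y)))
        lams = lambda_grid(lam_max, 25, 0.01)
        grid = PenaltyGrid(lambda1_values=lams)
        ref = select_by_bic(d, grid, method="lasso", sigma2=s2)
        G = d.X.T @ d.X
        beta, _, lam1 = _bic_best(G, G, d.X.T @ d.y, float(d.y @ d.y), lams,
                                  d.n, s2, 1e-9, 100_000)
        assert lam1 == pytest.approx(ref.lambda1)
        assert np.allclose(beta, ref.coefficients, atol=1e-4)


class TestOptimalityAndPaths:
    def test_solution_beats_random_feasible_points(self, rng):
        d = make_design(rng, n=25, q=5)
        lam = 0.4 * np.max(np.abs(d.X.T @ d.y))
        fit = fit_lasso(d, lam)
        f_star = lasso_objective(d, fit.coefficients, lam)
        for _ in range(500):
            trial = fit.coefficients + 0.5 * rng.standard_normal(5)
            assert f_star <= lasso_objective(d, trial, lam) + 1e-8

    def test_df_monotone_along_path(self, rng):
        d = make_design(rng, n=30, q=8)
        lam_max = float(np.max(np.abs(d.X.T @ d.y)))
        lams = np.geomspace(lam_max, 0.01 * lam_max, 15)
        dfs = [fit_lasso(d, lam).df_hat for lam in lams]
        assert all(a <= b + 1 for a, b in zip(dfs, dfs[1:]))  # ties allowed,
        # strict decreases should not happen going denser
        assert dfs[0] <= dfs[-1]


class TestDesignData:
    def test_standardization_invariants(self, rng):
        X = rng.standard_normal((20, 4)) * 3 + 1
        y = rng.standard_normal(20) + 5
        d = DesignData.build(X, y)
        assert np.max(np.abs(d.X.mean(axis=0))) < 1e-8
        assert np.max(np.abs(d.X.std(axis=0, ddof=1) - 1)) < 1e-6
        assert abs(d.y.mean()) < 1e-8

    def test_constant_column_rejected(self, rng):
        X = np.column_stack([np.ones(10), rng.standard_normal(10)])
        with pytest.raises(ValueError, match="constant"):
            DesignData.build(X, rng.standard_normal(10))
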