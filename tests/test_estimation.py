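"""Node-wise penalized regression, lambda selection, and network assembly."""

import numpy as np
import pandas as pd
import pytest

from clpnkit import (ConfigurationError, DegenerateFitError, EdgeMatrix,
                     FitConfig, estimate_network, fit_node, fit_node_at_lambda,
                     kkt_violation, select_lambda, summarize_edges)
from clpnkit.estimation import default_lambda_grid


def make_instance(n=50, p=5, seed=0, noise=0.1):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"x{i}" for i in range(p)])
    beta = np.array([1.0, -0.5, 0.0, 2.0, 0.3])[:p]
    y = X.to_numpy() @ beta + noise * rng.normal(size=n)
    return X, y, beta


class TestSelectLambda:
    def test_monotone_decreasing_curve_selects_smallest(self):
        lam = np.geomspace(1, 0.01, 20)
        assert select_lambda((lam, np.linspace(5, 1, 20))) == lam[-1]

    def test_u_shaped_curve_selects_minimum(self):
        lam = np.geomspace(1, 0.01, 21)
        loss = (np.arange(21) - 10.0) ** 2 + 1
        assert select_lambda((lam, loss)) == lam[10]

    def test_tie_broken_toward_larger_lambda(self):
        lam = np.array([1.0, 0.5, 0.1])
        loss = np.array([2.0, 1.0, 1.0])
        assert select_lambda((lam, loss)) == 0.5

    def test_non_finite_losses_rejected(self):
        with pytest.raises(Exception, match="non-finite"):
            select_lambda((np.array([1.0, 0.5]), np.array([1.0, np.nan])))


class TestFitNode:
    def test_full_shrinkage_above_lambda_max(self):
        X, y, _ = make_instance()
        cfg = FitConfig(lambda_grid=(100.0, 50.0), n_folds=5, covariates=())
        fit = fit_node(y, X, None, cfg)
        assert (fit.symptom_coefficients == 0).all()

    def test_lambda_zero_matches_least_squares(self):
        X, y, _ = make_instance()
        cfg = FitConfig(lambda_grid=(1.0, 0.0), n_folds=5, covariates=(),
                        standardize=False)
        fit = fit_node(y, X, None, cfg)
        assert fit.selected_lambda == 0.0
        Xc = X.to_numpy() - X.to_numpy().mean(0)
        ols, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        np.testing.assert_allclose(fit.symptom_coefficients.to_numpy(), ols,
                                   atol=1e-6)

    def test_noiseless_autoregressive_recovery(self):
        # outcome = 0.5 * own T1 score exactly; tiny lambda recovers it
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(200, 6)),
                         columns=[f"s{i}" for i in range(6)])
        y = 0.5 * X["s0"].to_numpy()
        cfg = FitConfig(lambda_grid=(0.1, 1e-5), n_folds=5, covariates=(),
                        standardize=False)
        fit = fit_node(y, X, None, cfg)
        assert fit.coefficients["s0"] == pytest.approx(0.5, abs=1e-3)
        assert np.abs(fit.coefficients.drop("s0")).max() < 1e-3

    def test_constant_outcome_is_degenerate(self):
        X, _, _ = make_instance()
        with pytest.raises(DegenerateFitError):
            fit_node(np.ones(len(X)), X, None, FitConfig(n_folds=5, covariates=()))

    def test_n_smaller_than_folds_rejected(self):
        X, y, _ = make_instance(n=6)
        with pytest.raises(ConfigurationError):
            fit_node(y, X, None, FitConfig(n_folds=10, covariates=()))

    def test_kkt_residuals_within_tolerance(self):
        X, y, _ = make_instance(n=120, seed=4, noise=0.5)
        cov = pd.DataFrame({"age": np.random.default_rng(5).normal(40, 10, 120)})
        cfg = FitConfig(n_folds=5, n_lambda=50)
        fit = fit_node(y, X, cov, cfg)
        assert kkt_violation(fit, X, cov, y, cfg) <= cfg.tolerance

    def test_row_order_invariance_at_fixed_lambda(self):
        X, y, _ = make_instance(n=80, seed=6, noise=0.3)
        cfg = FitConfig(covariates=())
        fit = fit_node_at_lambda(y, X, None, cfg, 0.05)
        perm = np.random.default_rng(7).permutation(80)
        fit_p = fit_node_at_lambda(y[perm], X.iloc[perm].reset_index(drop=True),
                                   None, cfg, 0.05)
        np.testing.assert_allclose(fit.coefficients.to_numpy(),
                                   fit_p.coefficients.to_numpy(), atol=1e-10)

    def test_predictor_order_invariance_up_to_relabeling(self):
        X, y, _ = make_instance(n=80, seed=8, noise=0.3)
        cfg = FitConfig(covariates=())
        fit = fit_node_at_lambda(y, X, None, cfg, 0.02)
        shuffled = X[["x3", "x0", "x4", "x1", "x2"]]
        fit_s = fit_node_at_lambda(y, shuffled, None, cfg, 0.02)
        # equality up to the coordinate-descent solver tolerance
        for name in X.columns:
            assert fit_s.coefficients[name] == pytest.approx(
                fit.coefficients[name], abs=1e-6)

    def test_binomial_family_recovers_signs(self):
        rng = np.random.default_rng(9)
        n = 500
        X = pd.DataFrame(rng.normal(size=(n, 5)),
                         columns=[f"s{i}" for i in range(5)])
        eta = 1.5 * X["s0"].to_numpy() - 1.0 * X["s2"].to_numpy()
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        cfg = FitConfig(family="binomial", n_lambda=25, n_folds=5,
                        covariates=(), tolerance=1e-6)
        fit = fit_node(y, X, None, cfg)
        assert fit.coefficients["s0"] > 0.3
        assert fit.coefficients["s2"] < -0.2
        assert kkt_violation(fit, X, None, y, cfg) <= 10 * cfg.tolerance


class TestPathProperties:
    def test_sparsity_non_decreasing_in_lambda_on_orthogonal_design(self):
        # orthogonal predictors make the path exact soft-thresholding,
        # where support growth along decreasing lambda is strictly monotone
        rng = np.random.default_rng(10)
        Q, _ = np.linalg.qr(rng.normal(size=(60, 8)))
        X = Q * np.sqrt(60)
        beta = np.array([0.9, -0.6, 0.4, 0.25, 0.15, 0.1, 0.05, 0.0])
        y = X @ beta
        from clpnkit.estimation import _gaussian_coef_path
        grid = default_lambda_grid(np.max(np.abs(X.T @ y)) / 60, 30)
        coefs = _gaussian_coef_path(X, y - y.mean(), grid)
        nnz = (coefs != 0).sum(axis=0)
        assert (np.diff(nnz) >= 0).all()

    def test_default_grid_descending_and_spanning(self):
        grid = default_lambda_grid(2.0, 50, 1e-3)
        assert len(grid) == 50
        assert grid[0] == pytest.approx(2.0)
        assert grid[-1] == pytest.approx(2e-3)
        assert (np.diff(grid) < 0).all()


class TestEstimateNetwork:
    def test_summary_of_published_matrix(self, fixture_matrix):
        s = summarize_edges(fixture_matrix)
        assert round(s.mean_autoregressive_or, 2) == 1.16
        assert round(s.mean_cross_lagged_or, 2) == 1.01

    def test_summary_of_identity_network(self, codebook):
        m = EdgeMatrix(codebook.codes, codebook.codes, np.eye(32) * 0.2 + 1)
        s = summarize_edges(m)
        assert s.mean_cross_lagged_or == 1
        assert s.n_positive == 0 and s.n_negative == 0

    def test_directional_recovery(self):
        # truth has a strong COGS5 -> COGS4 edge and no reverse edge
        from clpnkit import SimulationConfig, make_true_network, simulate_panel
        truth = make_true_network(cross_density=0.0, seed=30)
        i, j = truth.nodes.index("COGS5"), truth.nodes.index("COGS4")
        truth.B[i, j] = 0.35
        panel = simulate_panel(truth, SimulationConfig(), seed=31)
        net = estimate_network(panel, FitConfig(n_lambda=40))
        assert net.weight("COGS5", "COGS4") > net.weight("COGS4", "COGS5")
        assert net.weight("COGS5", "COGS4") > 1.05

    def test_gaussian_null_effects_bracket_one(self):
        # standardized-shrunken coefficients exponentiate close to 1,
        # mirroring the published edge magnitude range
        from clpnkit import SimulationConfig, make_true_network, simulate_panel
        truth = make_true_network(seed=32)
        panel = simulate_panel(truth, SimulationConfig(n_enrolled=500), seed=33)
        net = estimate_network(panel, FitConfig(n_lambda=40))
        assert net.weights.min() > 0.8 and net.weights.max() < 1.6
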