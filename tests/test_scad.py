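"""SCAD penalty, solver, and cross-validated penalty selection."""

import numpy as np
import pytest

from beidc import ScadConfig, ScadRegressor, ScadRegressorCV, cv_select_lambda, fit_scad, scad_penalty
from beidc.scad import scad_objective


def orthonormal_design(rng, n, k):
    """Mean-zero columns with X^T X = n I (so internal standardization is a no-op)."""
    A = rng.standard_normal((n, k))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    return np.sqrt(n) * Q[:, :k]


def grid_search_scad_univariate(z, lam, alpha, n):
    """Independent per-coordinate oracle: dense grid minimization of
    0.5*n*(z - b)^2 + n*p_lambda(|b|), refined around the coarse minimum."""
    def obj(b):
        pen = np.array([scad_penalty(abs(v), lam, alpha) for v in np.atleast_1d(b)])
        return 0.5 * n * (z - b) ** 2 + n * pen

    span = abs(z) * 1.5 + 1.0
    coarse = np.linspace(-span, span, 4001)
    b0 = coarse[int(np.argmin(obj(coarse)))]
    step = coarse[1] - coarse[0]
    fine = np.linspace(b0 - 2 * step, b0 + 2 * step, 4001)
    return fine[int(np.argmin(obj(fine)))]


class TestPenalty:
    def test_branch_values(self):
        assert scad_penalty(0.5, 1.0, 3.7) == pytest.approx(0.5)
        assert scad_penalty(10.0, 1.0, 3.7) == pytest.approx(2.35)

    def test_continuity_at_knots(self):
        lam, alpha, eps = 0.7, 3.7, 1e-9
        assert scad_penalty(lam - eps, lam, alpha) == pytest.approx(
            scad_penalty(lam + eps, lam, alpha), abs=1e-7)
        assert scad_penalty(alpha * lam - eps, lam, alpha) == pytest.approx(
            scad_penalty(alpha * lam + eps, lam, alpha), abs=1e-7)

    def test_monotone_nondecreasing(self):
        vals = [scad_penalty(b, 0.5, 3.7) for b in np.linspace(0, 5, 200)]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            scad_penalty(1.0, 1.0, alpha=2.0)
        with pytest.raises(ValueError):
            ScadConfig(alpha=1.5)


class TestSolver:
    def test_tiny_lambda_matches_ols(self, rng):
        X = rng.standard_normal((100, 8))
        beta = np.array([3.0, -2.0, 0.0, 0.0, 1.5, 0.0, 0.0, 0.0])
        y = X @ beta + rng.standard_normal(100)
        fit = fit_scad(X, y, ScadConfig(), lam=1e-8)
        Xi = np.column_stack([np.ones(100), X])
        ols = np.linalg.lstsq(Xi, y, rcond=None)[0]
        assert np.allclose(fit.beta, ols[1:], atol=1e-6)
        assert fit.intercept == pytest.approx(ols[0], abs=1e-6)

    def test_large_lambda_zeroes_everything(self, rng):
        X = rng.standard_normal((50, 6))
        y = X[:, 0] + rng.standard_normal(50)
        Xs = (X - X.mean(0)) / X.std(0)
        lam_max = np.abs(Xs.T @ (y - y.mean())).max() / 50
        fit = fit_scad(X, y, ScadConfig(), lam=lam_max * 1.01)
        assert np.all(fit.beta == 0.0)
        assert fit.intercept == pytest.approx(y.mean())

    def test_orthonormal_design_matches_grid_search_oracle(self, rng):
        n, k, lam, alpha = 80, 10, 0.8, 3.7
        X = orthonormal_design(rng, n, k)
        # spread true effects across all three penalty branches
        beta = np.array([0.3, 0.9, 1.6, 2.5, 4.0, -0.3, -1.2, -3.0, 0.0, 6.0])
        y = X @ beta + 0.5 * rng.standard_normal(n)
        fit = fit_scad(X, y, ScadConfig(), lam=lam)
        z = X.T @ (y - y.mean()) / n  # OLS estimates under orthonormality
        for j in range(k):
            expected = grid_search_scad_univariate(z[j], lam, alpha, n)
            assert fit.beta[j] == pytest.approx(expected, abs=1e-4)

    def test_objective_non_increasing_across_lla_iterations(self, rng):
        X = rng.standard_normal((60, 30))
        y = X[:, 0] - 2.0 * X[:, 1] + rng.standard_normal(60)
        fit = fit_scad(X, y, ScadConfig(), lam=0.2)
        diffs = np.diff(fit.objective_path)
        assert np.all(diffs <= 1e-9 * (1.0 + np.abs(fit.objective_path[:-1])))

    def test_returned_objective_matches_recomputation(self, rng):
        X = rng.standard_normal((40, 5))
        y = X[:, 1] + rng.standard_normal(40)
        fit = fit_scad(X, y, ScadConfig(), lam=0.3)
        # objective_path is on the standardized scale; recompute there
        Xs = (X - X.mean(0)) / X.std(0)
        beta_std = fit.beta * X.std(0)
        obj = scad_objective(Xs, y - y.mean(), 0.0, beta_std, 0.3)
        assert fit.objective_path[-1] == pytest.approx(obj, rel=1e-6)

    def test_zero_variance_column_gets_zero_coefficient(self, rng):
        X = rng.standard_normal((50, 4))
        X[:, 2] = 1.0
        y = X[:, 0] + rng.standard_normal(50)
        fit = fit_scad(X, y, ScadConfig(), lam=0.05)
        assert fit.beta[2] == 0.0

    def test_nearly_unbiased_for_large_coefficients(self):
        """Orthonormal design, beta = 10, lambda = 1: penalty is flat there,
        so the SCAD estimate should track OLS with negligible bias."""
        biases = []
        for rep in range(50):
            rng = np.random.default_rng(300 + rep)
            X = orthonormal_design(rng, 60, 3)
            y = 10.0 * X[:, 0] + rng.standard_normal(60)
            fit = fit_scad(X, y, ScadConfig(), lam=1.0)
            z = X[:, 0] @ (y - y.mean()) / 60
            biases.append(fit.beta[0] - z)
        assert abs(np.mean(biases)) < 0.05


class TestCrossValidation:
    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((60, 10))
        y = X[:, 0] + rng.standard_normal(60)
        lam1, fit1 = cv_select_lambda(X, y, ScadConfig(), seed=9)
        lam2, fit2 = cv_select_lambda(X, y, ScadConfig(), seed=9)
        assert lam1 == lam2
        assert np.array_equal(fit1.beta, fit2.beta)

    def test_pure_noise_gives_intercept_dominated_model(self, rng):
        X = rng.standard_normal((120, 15))
        y = rng.standard_normal(120)
        _, fit = cv_select_lambda(X, y, ScadConfig(), seed=1)
        held_out = float(np.min(fit.cv_mse))
        assert len(fit.nonzero_index_set) <= 3
        assert held_out == pytest.approx(np.var(y), rel=0.35)

    def test_parameter_recovery(self):
        good = 0
        for rep in range(20):
            rng = np.random.default_rng(400 + rep)
            X = rng.standard_normal((200, 20))
            y = 3.0 * X[:, 0] + rng.standard_normal(200)
            _, fit = cv_select_lambda(X, y, ScadConfig(), seed=rep)
            good += (0 in fit.nonzero_index_set) and abs(fit.beta[0] - 3.0) < 0.3
        assert good >= 18

    def test_sparsity_with_many_noise_features(self):
        small_support = 0
        for rep in range(10):
            rng = np.random.default_rng(500 + rep)
            X = rng.standard_normal((100, 500))
            y = 4.0 * X[:, 0] + 4.0 * X[:, 1] - 3.0 * X[:, 2] + rng.standard_normal(100)
            _, fit = cv_select_lambda(X, y, ScadConfig(), seed=rep)
            small_support += len(fit.nonzero_index_set) <= 25
        assert small_support >= 9


class TestEstimators:
    def test_regressor_roundtrip(self, rng):
        X = rng.standard_normal((80, 6))
        y = 2.0 * X[:, 3] + rng.standard_normal(80)
        model = ScadRegressor(lam=0.1).fit(X, y)
        assert model.predict(X).shape == (80,)
        assert abs(model.coef_[3] - 2.0) < 0.4

    def test_cv_regressor_sets_lambda(self, rng):
        X = rng.standard_normal((70, 8))
        y = X[:, 0] + rng.standard_normal(70)
        model = ScadRegressorCV(random_state=3).fit(X, y)
        assert model.lambda_ in model.lambda_grid_
        assert model.cv_mse_path_.shape == model.lambda_grid_.shape

    def test_works_with_sklearn_model_selection(self, rng):
        from sklearn.model_selection import cross_val_score
        X = rng.standard_normal((60, 5))
        y = 2.0 * X[:, 0] + 0.5 * rng.standard_normal(60)
        scores = cross_val_score(ScadRegressor(lam=0.05), X, y, cv=3)
        assert np.all(scores > 0.7)
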