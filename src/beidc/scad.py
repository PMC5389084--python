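"""SCAD-penalized least-squares regression.

The smoothly clipped absolute deviation (SCAD) penalty behaves like the
lasso near zero (sparsity), tapers linearly between its two knots at
``lambda`` and ``alpha*lambda``, and is flat beyond, so large coefficients
are left nearly unbiased.  The objective is

    0.5 * ||y - X beta||^2 + n * sum_j p_lambda(|beta_j|).

Fitting is by cyclic coordinate descent in which every coordinate update is
the exact univariate SCAD minimizer (firm thresholding), with warm starts
down a decreasing lambda path, active-set cycling, and full KKT checks;
outer refinement cycles repeat until the coefficients are stationary, and
the recorded penalized objective is non-increasing across them.  Predictors
are standardized internally and the (unpenalized) intercept handled by
centering; returned coefficients are on the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from ._kernels import scad_path, scad_penalty_scalar

__all__ = [
    "ScadConfig",
    "ScadFit",
    "scad_penalty",
    "scad_objective",
    "fit_scad",
    "cv_select_lambda",
    "ScadRegressor",
    "ScadRegressorCV",
]


@dataclass
class ScadConfig:
    """Tuning knobs for the SCAD solver.

    alpha > 2 is required for the middle branch of the penalty to be well
    defined; 3.7 is the conventional default.  ``lambda_grid`` overrides the
    auto-generated grid of ``n_lambdas`` log-spaced values from lambda_max
    (smallest lambda zeroing every coefficient) down to
    ``lambda_min_ratio * lambda_max``.
    """

    alpha: float = 3.7
    lambda_grid: Optional[np.ndarray] = None
    n_lambdas: int = 50
    lambda_min_ratio: float = 0.05
    cv_folds: int = 5
    max_iter: int = 200
    tol: float = 1e-5
    max_outer: int = 5
    saturation_stop: bool = True

    def __post_init__(self):
        if self.alpha <= 2:
            raise ValueError("SCAD requires alpha > 2")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if np.any(g <= 0) or np.any(np.diff(g) >= 0):
                raise ValueError("lambda_grid must be strictly positive and decreasing")
            self.lambda_grid = g


@dataclass
class ScadFit:
    """A fitted SCAD model on the original feature scale."""

    intercept: float
    beta: np.ndarray
    lambda_selected: float
    nonzero_index_set: np.ndarray
    converged: bool = True
    objective_path: Optional[np.ndarray] = None  # per-outer-cycle objective at final lambda
    cv_mse: Optional[np.ndarray] = None
    lambda_grid: Optional[np.ndarray] = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.beta


def scad_penalty(beta_abs: float, lam: float, alpha: float = 3.7) -> float:
    """Three-branch SCAD penalty p_lambda(|beta|); continuous at both knots."""
    if alpha <= 2:
        raise ValueError("SCAD requires alpha > 2")
    if beta_abs < 0:
        raise ValueError("beta_abs must be non-negative")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return float(scad_penalty_scalar(float(beta_abs), float(lam), float(alpha)))


def scad_objective(X, y, intercept, beta, lam, alpha=3.7) -> float:
    """Penalized least-squares objective evaluated at (intercept, beta)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    r = y - intercept - X @ beta
    pen = sum(scad_penalty(abs(b), lam, alpha) for b in np.atleast_1d(beta))
    return 0.5 * float(r @ r) + len(y) * pen


def _standardize(X: np.ndarray, y: np.ndarray):
    n = X.shape[0]
    xm = X.mean(axis=0)
    xs = X.std(axis=0)
    ok = xs > 0
    Xs = (X - xm) / np.where(ok, xs, 1.0)
    Xs[:, ~ok] = 0.0
    colnorm2 = np.where(ok, float(n), 0.0)
    ym = float(y.mean())
    return Xs, colnorm2, xm, xs, ok, y - ym, ym


def _lambda_grid(Xs, colnorm2, yc, config: ScadConfig) -> np.ndarray:
    if config.lambda_grid is not None:
        return config.lambda_grid
    n = Xs.shape[0]
    g = np.abs(Xs.T @ yc) / n
    lam_max = float(g.max(initial=0.0))
    if lam_max <= 0:  # constant response: any positive grid gives the null model
        lam_max = 1.0
    return np.geomspace(lam_max, config.lambda_min_ratio * lam_max, config.n_lambdas)


def _run_path(Xs, colnorm2, yc, lambdas, config: ScadConfig):
    XT = np.ascontiguousarray(Xs.T)
    # beyond-saturation fits (active set larger than the sample count) are
    # never competitive on held-out error; stopping there bounds the cost of
    # the small-lambda tail of the path
    dfmax = Xs.shape[0] if config.saturation_stop else 0
    return scad_path(
        XT, yc, colnorm2, np.asarray(lambdas, dtype=float),
        config.alpha, config.tol, config.max_outer, config.max_iter, dfmax,
    )


def _to_original_scale(beta_std, xm, xs, ok, ym):
    beta = np.where(ok, beta_std / np.where(ok, xs, 1.0), 0.0)
    return float(ym - xm @ beta), beta


def fit_scad(X, y, config: Optional[ScadConfig] = None, lam: float = None) -> ScadFit:
    """Fit SCAD at a single lambda (warm-started down the path from lambda_max)."""
    if config is None:
        config = ScadConfig()
    if lam is None or lam <= 0:
        raise ValueError("lam must be a positive penalty level")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be n x k with matching y")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    Xs, colnorm2, xm, xs, ok, yc, ym = _standardize(X, y)
    grid = _lambda_grid(Xs, colnorm2, yc, config)
    lambdas = np.append(grid[grid > lam], lam)
    betas, objs, conv, _ = _run_path(Xs, colnorm2, yc, lambdas, config)
    beta_std = betas[-1]
    intercept, beta = _to_original_scale(beta_std, xm, xs, ok, ym)
    converged = bool(conv[-1])
    if not converged:
        warnings.warn("SCAD coordinate descent did not fully converge; returning best iterate")
    final_objs = objs[-1]
    return ScadFit(
        intercept=intercept,
        beta=beta,
        lambda_selected=float(lam),
        nonzero_index_set=np.flatnonzero(beta),
        converged=converged,
        objective_path=final_objs[np.isfinite(final_objs)],
    )


def cv_select_lambda(X, y, config: Optional[ScadConfig] = None, seed: int = 0) -> Tuple[float, ScadFit]:
    """Select lambda by K-fold cross validation (squared-error loss), refit on all data.

    Folds are a deterministic function of ``seed``.  Returns the selected
    lambda and the refitted model, which also carries the CV curve.
    """
    if config is None:
        config = ScadConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < config.cv_folds:
        raise ValueError("need at least cv_folds observations")
    Xs_all, colnorm2_all, xm, xs, ok, yc_all, ym = _standardize(X, y)
    grid = _lambda_grid(Xs_all, colnorm2_all, yc_all, config)
    L = grid.size

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, config.cv_folds)
    sse = np.zeros(L)
    n_valid = L
    for val_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[val_idx] = False
        Xtr, ytr = X[mask], y[mask]
        Xst, cn, xmt, xst, okt, yct, ymt = _standardize(Xtr, ytr)
        betas, _, _, nv = _run_path(Xst, cn, yct, grid, config)
        n_valid = min(n_valid, nv)
        Xv = (X[val_idx] - xmt) / np.where(okt, xst, 1.0)
        Xv[:, ~okt] = 0.0
        pred = Xv @ betas.T + ymt  # (n_val, L)
        sse += ((y[val_idx][:, None] - pred) ** 2).sum(axis=0)
    cv_mse = sse / n
    # restrict the choice to lambdas solved in every fold (saturation stop)
    best = int(np.argmin(cv_mse[:max(n_valid, 1)]))  # ties -> largest (first) lambda
    lam = float(grid[best])

    betas, objs, conv, nv = _run_path(Xs_all, colnorm2_all, yc_all, grid[: best + 1], config)
    last = min(best, nv - 1)
    intercept, beta = _to_original_scale(betas[last], xm, xs, ok, ym)
    final_objs = objs[last][np.isfinite(objs[last])]
    fit = ScadFit(
        intercept=intercept,
        beta=beta,
        lambda_selected=lam,
        nonzero_index_set=np.flatnonzero(beta),
        converged=bool(conv[best]),
        objective_path=final_objs,
        cv_mse=cv_mse,
        lambda_grid=grid,
    )
    return lam, fit


class ScadRegressor(RegressorMixin, BaseEstimator):
    """SCAD-penalized linear regression at a fixed penalty level.

    Parameters mirror :class:`ScadConfig`; ``lam`` is the penalty level.
    Fitted attributes follow scikit-learn conventions (``coef_``,
    ``intercept_``, ``n_features_in_``).
    """

    def __init__(self, lam: float = 0.1, alpha: float = 3.7, max_iter: int = 200,
                 tol: float = 1e-5, max_outer: int = 5):
        self.lam = lam
        self.alpha = alpha
        self.max_iter = max_iter
        self.tol = tol
        self.max_outer = max_outer

    def _config(self) -> ScadConfig:
        return ScadConfig(alpha=self.alpha, max_iter=self.max_iter, tol=self.tol,
                          max_outer=self.max_outer)

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        fit = fit_scad(X, y, self._config(), lam=self.lam)
        self.coef_ = fit.beta
        self.intercept_ = fit.intercept
        self.converged_ = fit.converged
        self.fit_ = fit
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = validate_data(self, X, reset=False)
        return self.intercept_ + X @ self.coef_


class ScadRegressorCV(ScadRegressor):
    """SCAD regression with the penalty level chosen by K-fold cross validation."""

    def __init__(self, alpha: float = 3.7, n_lambdas: int = 50, lambda_min_ratio: float = 0.01,
                 cv: int = 5, max_iter: int = 200, tol: float = 1e-5, max_outer: int = 5,
                 random_state: int = 0):
        super().__init__(lam=None, alpha=alpha, max_iter=max_iter, tol=tol, max_outer=max_outer)
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.random_state = random_state

    def _config(self) -> ScadConfig:
        return ScadConfig(alpha=self.alpha, n_lambdas=self.n_lambdas,
                          lambda_min_ratio=self.lambda_min_ratio, cv_folds=self.cv,
                          max_iter=self.max_iter, tol=self.tol, max_outer=self.max_outer)

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        lam, fit = cv_select_lambda(X, y, self._config(), seed=self.random_state)
        self.lambda_ = lam
        self.coef_ = fit.beta
        self.intercept_ = fit.intercept
        self.converged_ = fit.converged
        self.cv_mse_path_ = fit.cv_mse
        self.lambda_grid_ = fit.lambda_grid
        self.fit_ = fit
        return self
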