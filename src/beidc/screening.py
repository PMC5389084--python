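"""Distance-correlation estimation and single-pass DC-SIS ranking.

DC-SIS ranks every SNP by the distance correlation of its dosage column with
the phenotype.  Distance correlation is zero iff the two variables are
independent, captures nonlinear association, and needs no model assumptions,
which makes it the screening statistic of choice for mixed genotype /
continuous features.  The V-statistic estimator used here is

    dcov2_hat = S1 + S2 - 2*S3

built from pairwise absolute differences (all variables univariate), and the
reported score is Dcorr = (dcov2_xy / sqrt(dcov2_xx * dcov2_yy))^(1/2).
"""

from __future__ import annotations

from typing import Union

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from . import _kernels
from .datatypes import ScreenRanking, as_feature_array, as_phenotype_array

__all__ = [
    "dcov2_hat",
    "dcorr_hat",
    "dcsis_rank",
    "fixed_threshold",
    "DistanceCorrelationScreener",
]


def _check_pair(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


def _y_summaries(y: np.ndarray):
    """Pairwise-distance matrix of y with row sums, grand sum and dcov2(y,y)."""
    B = _kernels.pairwise_absdiff(y)
    brow = B.sum(axis=1)
    bsum = brow.sum()
    d_yy, _ = _kernels.dcov_stats(y, B, brow, bsum)
    return B, brow, bsum, max(d_yy, 0.0)


def dcov2_hat(x, y) -> float:
    """Squared distance covariance (V-statistic) of two univariate samples.

    Non-negative up to rounding; symmetric; invariant under adding constants.
    """
    x, y = _check_pair(x, y)
    B, brow, bsum, _ = _y_summaries(y)
    d_xy, _ = _kernels.dcov_stats(x, B, brow, bsum)
    return max(d_xy, 0.0)


def dcorr_hat(x, y) -> float:
    """Distance correlation in [0, 1]; 0 when either input is constant."""
    x, y = _check_pair(x, y)
    B, brow, bsum, d_yy = _y_summaries(y)
    d_xy, d_xx = _kernels.dcov_stats(x, B, brow, bsum)
    denom = d_xx * d_yy
    if denom <= 0.0:
        return 0.0
    r2 = max(d_xy / np.sqrt(denom), 0.0)
    return float(min(np.sqrt(r2), 1.0))


def dcsis_scores(X: np.ndarray, y: np.ndarray, block_size: int = 512) -> np.ndarray:
    """Distance correlation of every column of X with y (Eq.-(2) scale).

    The phenotype distance matrix and its row/grand sums are computed once;
    features are processed in memory-bounded blocks.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("phenotype length mismatch")
    B, brow, bsum, d_yy = _y_summaries(y)
    scores = np.empty(p)
    for lo in range(0, p, block_size):
        hi = min(lo + block_size, p)
        XT = np.ascontiguousarray(X[:, lo:hi].T)
        scores[lo:hi] = _kernels.dcorr_batch(XT, B, brow, bsum, d_yy)
    return scores


def rank_order(scores: np.ndarray) -> np.ndarray:
    """Descending-score order; ties broken by ascending original index."""
    return np.argsort(-scores, kind="stable")


def dcsis_rank(X, y) -> ScreenRanking:
    """Single-pass DC-SIS: rank all features by marginal distance correlation."""
    Xv = as_feature_array(X)
    yv = as_phenotype_array(y, Xv.shape[0])
    scores = dcsis_scores(Xv, yv)
    order = rank_order(scores)
    return ScreenRanking(order=order, scores=scores, stage=np.zeros(Xv.shape[1], dtype=int))


def fixed_threshold(n: int, multiplier: int = 2) -> int:
    """Conventional fixed screening threshold d = multiplier * [n / log(n)].

    Natural log with truncation toward zero, matching the usage that turns
    n = 200 into d1 = 37 and d2 = 74.
    """
    return multiplier * int(n / np.log(n))


class DistanceCorrelationScreener(SelectorMixin, BaseEstimator):
    """Marginal DC-SIS feature screener (scikit-learn selector interface).

    Parameters
    ----------
    d : int or "auto", default="auto"
        Number of top-ranked features kept by :meth:`transform`.  "auto"
        uses the conventional 2*[n/log(n)].

    Attributes
    ----------
    scores_ : ndarray of shape (p,)
        Distance correlation per feature (original order).
    ranking_ : ScreenRanking
        Full ordering with per-feature scores and stages.
    d_ : int
        Resolved selection size.
    """

    def __init__(self, d: Union[int, str] = "auto"):
        self.d = d

    def _rank(self, X: np.ndarray, y: np.ndarray) -> ScreenRanking:
        return dcsis_rank(X, y)

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        self.ranking_ = self._rank(X, y)
        self.scores_ = self.ranking_.scores
        n, p = X.shape
        d = fixed_threshold(n) if self.d == "auto" else int(self.d)
        self.d_ = max(1, min(d, p))
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_")
        mask = np.zeros(self.ranking_.p, dtype=bool)
        mask[self.ranking_.top(self.d_)] = True
        return mask
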