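"""Core in-memory containers shared across the package.

The containers are deliberately thin: estimators accept plain numpy arrays
(the scikit-learn convention), while :class:`FeatureMatrix` carries the
metadata (feature identifiers, optional genomic coordinates) needed by file
I/O and the command line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FeatureMatrix",
    "ScreenRanking",
    "IterationSchedule",
    "EliminationTrace",
    "ThresholdResult",
]


def as_feature_array(X) -> np.ndarray:
    """Return the n x p float array behind ``X`` (FeatureMatrix or array-like)."""
    if isinstance(X, FeatureMatrix):
        return X.values
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"feature matrix must be 2-D, got shape {arr.shape}")
    return arr


def as_phenotype_array(y, n: Optional[int] = None) -> np.ndarray:
    """Validate and return the length-n phenotype vector."""
    arr = np.asarray(y, dtype=float).ravel()
    if n is not None and arr.size != n:
        raise ValueError(f"phenotype length {arr.size} != sample count {n}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("phenotype contains non-finite values")
    return arr


@dataclass
class FeatureMatrix:
    """n x p matrix of SNP dosage codes (0/1/2) or continuous covariates.

    Parameters
    ----------
    values : ndarray of shape (n, p)
        Feature values; missing data must already be imputed (I/O layer).
    feature_ids : sequence of str
        Unique identifier per feature (column).
    coords : optional sequence of (str, int)
        Per-feature (chromosome, 1-based bp position), e.g. from VCF.
    """

    values: np.ndarray
    feature_ids: Sequence[str]
    coords: Optional[Sequence[tuple]] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if p < 1:
            raise ValueError("need at least 1 feature")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries; impute first")
        self.feature_ids = list(self.feature_ids)
        if len(self.feature_ids) != p:
            raise ValueError("feature_ids length mismatch")
        if len(set(self.feature_ids)) != p:
            raise ValueError("feature_ids must be unique")
        if self.coords is not None and len(self.coords) != p:
            raise ValueError("coords length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class ScreenRanking:
    """Output of a screening pass: features ordered most- to least-important.

    Attributes
    ----------
    order : ndarray of int
        Permutation of 0..p-1, most important first.
    scores : ndarray of float
        Distance correlation per feature, aligned to the *original* feature
        index (Eq.-(2) scale, in [0, 1]).  For iterative screening the score
        is the residual distance correlation at the stage where the feature
        was ranked.
    stage : ndarray of int
        Stage that ranked each feature (aligned to original index); 0 for a
        single-pass ranking.
    """

    order: np.ndarray
    scores: np.ndarray
    stage: np.ndarray

    def __post_init__(self):
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        self.stage = np.asarray(self.stage, dtype=int)
        p = self.order.size
        if sorted(self.order.tolist()) != list(range(p)):
            raise ValueError("order must be a permutation of 0..p-1")
        if self.scores.size != p or self.stage.size != p:
            raise ValueError("scores/stage must align with order length")

    @property
    def p(self) -> int:
        return self.order.size

    def top(self, d: int) -> np.ndarray:
        """Original indices of the ``d`` highest-ranked features."""
        return self.order[:d]


@dataclass
class IterationSchedule:
    """Block schedule for iterative screening.

    ``block_sizes`` gives the first explicit block sizes (p1, p2, ...); after
    they are exhausted the last size repeats until ``iterative_cap`` features
    have been ranked iteratively, after which all remaining features are
    ranked in one final pass on their residuals.
    """

    block_sizes: Sequence[int] = (3, 3)
    iterative_cap: int = 100

    def __post_init__(self):
        self.block_sizes = tuple(int(b) for b in self.block_sizes)
        if not self.block_sizes or any(b < 1 for b in self.block_sizes):
            raise ValueError("block_sizes must be positive integers")
        self.iterative_cap = int(self.iterative_cap)
        if len(self.block_sizes) >= 2:
            head = self.block_sizes[0] + self.block_sizes[1]
        else:
            head = self.block_sizes[0]
        if self.iterative_cap < head:
            raise ValueError("iterative_cap must cover the first two blocks")

    def blocks(self):
        """Yield block sizes until the cap is reached (generator)."""
        taken = 0
        i = 0
        while taken < self.iterative_cap:
            b = self.block_sizes[i] if i < len(self.block_sizes) else self.block_sizes[-1]
            b = min(b, self.iterative_cap - taken)
            yield b
            taken += b
            i += 1


@dataclass
class EliminationTrace:
    """Pool sizes visited by backward elimination with their bootstrap MSPE."""

    pool_sizes: np.ndarray
    mspe_mean: np.ndarray
    mspe_se: np.ndarray
    pools: list = field(default_factory=list)
    # per-bootstrap OOB errors, shape (n_pools, n_bootstrap); present when the
    # pools were scored on a shared resample plan (enables paired comparisons)
    mspe_samples: Optional[np.ndarray] = None

    def __post_init__(self):
        self.pool_sizes = np.asarray(self.pool_sizes, dtype=int)
        self.mspe_mean = np.asarray(self.mspe_mean, dtype=float)
        self.mspe_se = np.asarray(self.mspe_se, dtype=float)
        if self.pool_sizes.size == 0:
            raise ValueError("trace is empty")
        if np.any(np.diff(self.pool_sizes) >= 0):
            raise ValueError("pool_sizes must be strictly decreasing")
        if not np.all(np.isfinite(self.mspe_mean)):
            raise ValueError("mspe_mean must be finite")


@dataclass
class ThresholdResult:
    """Adaptive threshold d-hat with the selected / discarded feature split."""

    d_hat: int
    selected: np.ndarray
    discarded: np.ndarray
    d_one_se: int
    mspe_at_d_hat: float

    def __post_init__(self):
        self.selected = np.asarray(self.selected, dtype=int)
        self.discarded = np.asarray(self.discarded, dtype=int)
        if self.selected.size != self.d_hat:
            raise ValueError("selected size must equal d_hat")
        if self.d_one_se > self.d_hat:
            raise ValueError("d_one_se cannot exceed d_hat")
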