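"""BE-IDC: backward elimination with bootstrap-OOB prediction error.

The driver ranks all features once by iterative distance-correlation
screening, then walks a nested sequence of candidate pools (each the top-k
prefix of the ranking), shrinking the pool by a fixed drop rate per step.
Every pool is scored by the mean out-of-bag squared prediction error of a
cross-validated SCAD regression over bootstrap resamples, and the adaptive
threshold d-hat is the visited pool size minimizing that error, with
statistical ties (pools within one paired-difference SE of the minimum)
resolved toward the smallest pool.  A 1-standard-error alternative — the
smallest pool whose error is within one marginal SE of the minimum — is
reported alongside.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .datatypes import (
    EliminationTrace,
    IterationSchedule,
    ScreenRanking,
    ThresholdResult,
    as_feature_array,
    as_phenotype_array,
)
from .iterative import idcsis_rank
from .scad import ScadConfig, cv_select_lambda

__all__ = [
    "BeConfig",
    "bootstrap_mspe",
    "eliminate",
    "select_threshold",
    "run_be_idc",
    "BackwardEliminationSelector",
]


@dataclass
class BeConfig:
    """Backward-elimination settings: drop rate, bootstrap count, seed, SCAD knobs."""

    drop_rate: float = 0.5
    n_bootstrap: int = 1000
    min_pool: int = 1
    seed: int = 0
    scad: ScadConfig = field(default_factory=ScadConfig)
    n_jobs: int = 1

    def __post_init__(self):
        if not 0 < self.drop_rate < 1:
            raise ValueError("drop_rate must lie in (0, 1)")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.min_pool < 1:
            raise ValueError("min_pool must be >= 1")


def eliminate(pool_size: int, drop_rate: float, min_pool: int = 1) -> int:
    """Next pool size after removing ``drop_rate`` of the lowest-ranked features."""
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if pool_size <= min_pool:
        return min_pool
    nxt = pool_size - math.ceil(drop_rate * pool_size)
    if nxt >= pool_size:  # guarantee progress
        nxt = pool_size - 1
    return max(min_pool, nxt)


def _one_bootstrap(X_pool, y, idx, oob, cfg: ScadConfig, fold_seed: int) -> float:
    train = np.unique(idx)
    try:
        _, fit = cv_select_lambda(X_pool[train], y[train], cfg, seed=fold_seed)
        pred = fit.predict(X_pool[oob])
    except Exception:  # degenerate resample: intercept-only fallback
        pred = np.full(oob.size, y[train].mean())
    err = y[oob] - pred
    return float(err @ err / oob.size)


def draw_bootstrap_resamples(n: int, n_bootstrap: int, seed) -> list:
    """Resample plan: (in-bag indices, OOB indices, CV fold seed) triples.

    Resamples with an empty OOB set are redrawn.
    """
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_bootstrap):
        while True:
            idx = rng.integers(0, n, n)
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size:
                break
        draws.append((idx, oob, int(rng.integers(2**31))))
    return draws


def bootstrap_mspe(X_pool, y, config: Optional[BeConfig] = None,
                   draws: Optional[list] = None, return_samples: bool = False):
    """Mean and standard error of OOB squared prediction error over bootstraps.

    Each bootstrap resample is split into its unique in-bag rows (training)
    and the out-of-bag rows (test); a cross-validated SCAD model is fit on
    the training rows and scored on the OOB rows.  Deterministic given
    ``config.seed``: when ``draws`` is not supplied the resample stream is
    keyed by (seed, pool size).  The backward-elimination driver passes one
    shared resample plan for all pool sizes so that pools are compared on
    identical splits (a paired comparison — between-pool differences are not
    polluted by independent resampling noise).
    """
    if config is None:
        config = BeConfig()
    X_pool = np.asarray(X_pool, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X_pool.shape
    if k < 1:
        raise ValueError("pool must contain at least one feature")
    if n < 10:
        raise ValueError("need at least 10 observations for bootstrap OOB scoring")

    cfg = config.scad
    if k > n and cfg.n_lambdas > 25:
        # beyond-saturation pools: a coarser penalty grid loses no useful CV
        # resolution (the competitive lambdas keep far fewer than n features)
        # and bounds the cost of the largest pools
        cfg = dataclasses.replace(cfg, n_lambdas=25)

    if draws is None:
        draws = draw_bootstrap_resamples(n, config.n_bootstrap, [config.seed, k])

    if config.n_jobs != 1:
        mspes = Parallel(n_jobs=config.n_jobs, prefer="threads")(
            delayed(_one_bootstrap)(X_pool, y, idx, oob, cfg, fs) for idx, oob, fs in draws
        )
    else:
        mspes = [_one_bootstrap(X_pool, y, idx, oob, cfg, fs) for idx, oob, fs in draws]
    mspes = np.asarray(mspes)
    mean = float(mspes.mean())
    se = float(mspes.std(ddof=1) / math.sqrt(mspes.size)) if mspes.size > 1 else 0.0
    if return_samples:
        return mean, se, mspes
    return mean, se


def select_threshold(trace: EliminationTrace) -> ThresholdResult:
    """Locate the MSPE-minimizing pool size (ties: smallest) and the 1-SE size.

    When the trace carries per-bootstrap errors from a shared resample plan,
    "ties" with the minimum are resolved by the paired comparison: any pool
    whose mean exceeds the minimum by no more than one standard error of the
    *per-bootstrap difference* is statistically indistinguishable from it,
    and the smallest such pool is selected.  Nested penalized fits are near
    identical over a wide size range, so the raw argmin of the flat stretch
    is noise; the paired rule returns the knee of the curve.  Pools that
    genuinely predict worse (e.g. ones that cut into the true model) exceed
    the band by orders of magnitude and are never chosen.
    """
    sizes = trace.pool_sizes
    means = trace.mspe_mean
    if sizes.size == 0:
        raise ValueError("empty trace")
    min_mean = means.min()
    at_min = np.flatnonzero(means == min_mean)
    i_best = at_min[np.argmin(sizes[at_min])]
    if trace.mspe_samples is not None:
        smp_min = trace.mspe_samples[i_best]
        order_small_first = np.argsort(sizes)
        for i in order_small_first:
            diff = trace.mspe_samples[i] - smp_min
            se_d = diff.std(ddof=1) / math.sqrt(diff.size) if diff.size > 1 else 0.0
            if means[i] - min_mean <= se_d + 1e-12:
                i_best = i
                break
    d_hat = int(sizes[i_best])
    se_min = float(trace.mspe_se[i_best])
    within = np.flatnonzero(means <= min_mean + se_min)
    d_one_se = int(sizes[within].min())
    full_rank = np.asarray(trace.pools[0], dtype=int)
    return ThresholdResult(
        d_hat=d_hat,
        selected=full_rank[:d_hat],
        discarded=full_rank[d_hat:],
        d_one_se=min(d_one_se, d_hat),
        mspe_at_d_hat=float(means[i_best]),
    )


def run_be_idc(
    X,
    y,
    config: Optional[BeConfig] = None,
    schedule: Optional[IterationSchedule] = None,
    center: bool = True,
) -> Tuple[ScreenRanking, EliminationTrace, ThresholdResult]:
    """Full BE-IDC: rank once, walk shrinking pools, pick the MSPE minimizer."""
    if config is None:
        config = BeConfig()
    Xv = as_feature_array(X)
    yv = as_phenotype_array(y, Xv.shape[0])
    ranking = idcsis_rank(Xv, yv, schedule=schedule, center=center)
    p = Xv.shape[1]

    sizes = [p]
    while sizes[-1] > config.min_pool:
        sizes.append(eliminate(sizes[-1], config.drop_rate, config.min_pool))
    draws = draw_bootstrap_resamples(Xv.shape[0], config.n_bootstrap, [config.seed])
    means, ses, pools, samples = [], [], [], []
    for k in sizes:
        pool = ranking.order[:k]
        m, s, smp = bootstrap_mspe(Xv[:, pool], yv, config, draws=draws,
                                   return_samples=True)
        means.append(m)
        ses.append(s)
        pools.append(pool)
        samples.append(smp)
    trace = EliminationTrace(pool_sizes=np.array(sizes), mspe_mean=np.array(means),
                             mspe_se=np.array(ses), pools=pools,
                             mspe_samples=np.asarray(samples))
    return ranking, trace, select_threshold(trace)


class BackwardEliminationSelector(SelectorMixin, BaseEstimator):
    """BE-IDC feature selector with an adaptively estimated threshold.

    Parameters
    ----------
    drop_rate : float in (0, 1), default 0.5
        Fraction of the pool (lowest-ranked features) discarded per step.
    n_bootstrap : int, default 1000
        Bootstrap resamples per pool for the OOB prediction error.
    min_pool : int, default 1
        Smallest pool visited.
    block_sizes, iterative_cap, center :
        Iterative-screening schedule (see :class:`IterativeDCScreener`).
    use_one_se : bool, default False
        Select with the 1-standard-error rule instead of the MSPE minimum.
    scad_config : ScadConfig, optional
        SCAD solver settings for the bootstrap fits.
    random_state : int, default 0
        Seed for the bootstrap and CV streams.

    Attributes
    ----------
    ranking_ : ScreenRanking
    trace_ : EliminationTrace
    result_ : ThresholdResult
    d_hat_, d_one_se_ : int
    """

    def __init__(self, drop_rate: float = 0.5, n_bootstrap: int = 1000, min_pool: int = 1,
                 block_sizes: Sequence[int] = (3, 3), iterative_cap: int = 100,
                 center: bool = True, use_one_se: bool = False,
                 scad_config: Optional[ScadConfig] = None, n_jobs: int = 1,
                 random_state: int = 0):
        self.drop_rate = drop_rate
        self.n_bootstrap = n_bootstrap
        self.min_pool = min_pool
        self.block_sizes = block_sizes
        self.iterative_cap = iterative_cap
        self.center = center
        self.use_one_se = use_one_se
        self.scad_config = scad_config
        self.n_jobs = n_jobs
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        config = BeConfig(
            drop_rate=self.drop_rate,
            n_bootstrap=self.n_bootstrap,
            min_pool=self.min_pool,
            seed=self.random_state,
            scad=self.scad_config if self.scad_config is not None else ScadConfig(),
            n_jobs=self.n_jobs,
        )
        schedule = IterationSchedule(block_sizes=tuple(self.block_sizes),
                                     iterative_cap=self.iterative_cap)
        self.ranking_, self.trace_, self.result_ = run_be_idc(X, y, config, schedule,
                                                              center=self.center)
        self.d_hat_ = self.result_.d_hat
        self.d_one_se_ = self.result_.d_one_se
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "result_")
        d = self.d_one_se_ if self.use_one_se else self.d_hat_
        mask = np.zeros(self.ranking_.p, dtype=bool)
        mask[self.ranking_.order[:d]] = True
        return mask
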