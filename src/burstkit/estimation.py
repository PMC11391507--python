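"""Estimation statistics: mean differences with BCa bootstrap confidence
intervals and permutation p-values.

The effect size is the unpaired mean difference test − control.  Confidence
intervals use the bias-corrected and accelerated (BCa) bootstrap: the bias
correction z0 comes from the fraction of bootstrap statistics strictly
below the observed statistic, the acceleration from the jackknife skewness
of the statistic under the concatenated leave-one-out scheme (omit one
observation from whichever group it belongs to).  Two-sided p-values come
from reshuffling the group labels, with the +1/(n+1) finite-sample
correction so p is never exactly zero.  All routines are deterministic
given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "EstimationResult",
    "mean_difference",
    "bca_interval",
    "permutation_p",
    "estimate_difference",
]


@dataclass
class EstimationResult:
    mean_difference: float
    ci_low: float
    ci_high: float
    confidence_level: float
    n_bootstrap: int
    n_permutation: int
    p_value: float
    seed: int
    degenerate: bool = False


def _as_groups(test, control):
    x = np.asarray(test, dtype=float).ravel()
    y = np.asarray(control, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be nonempty")
    return x, y


def mean_difference(test, control) -> float:
    """Unpaired effect size: mean(test) − mean(control)."""
    x, y = _as_groups(test, control)
    return float(x.mean() - y.mean())


def _bootstrap_diffs(x, y, n_boot, rng) -> np.ndarray:
    bx = x[rng.integers(0, x.size, size=(n_boot, x.size))].mean(axis=1)
    by = y[rng.integers(0, y.size, size=(n_boot, y.size))].mean(axis=1)
    return bx - by


def _adjusted_levels(z0: float, a: float, confidence_level: float) -> tuple[float, float]:
    """BCa-adjusted quantile levels; reduces to plain percentile levels when
    z0 = 0 and a = 0."""
    alpha = (1.0 - confidence_level) / 2.0
    lo, hi = ndtri(alpha), ndtri(1.0 - alpha)
    adj = lambda z: float(ndtr(z0 + (z0 + z) / (1.0 - a * (z0 + z))))
    return adj(lo), adj(hi)


def bca_interval(
    test,
    control,
    n_bootstrap: int = 5000,
    confidence_level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """BCa bootstrap confidence interval for the mean difference."""
    x, y = _as_groups(test, control)
    if x.size + y.size < 4:
        raise ValueError("combined sample size must be at least 4")
    if n_bootstrap < 1000:
        raise ValueError("n_bootstrap must be at least 1000")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = float(x.mean() - y.mean())
    boot = _bootstrap_diffs(x, y, n_bootstrap, rng)
    if np.ptp(boot) == 0:
        warnings.warn("degenerate zero-variance samples: point interval", stacklevel=2)
        return obs, obs
    # bias correction: strictly-less convention for ties
    prop = np.count_nonzero(boot < obs) / n_bootstrap
    prop = min(max(prop, 1.0 / (n_bootstrap + 1)), n_bootstrap / (n_bootstrap + 1.0))
    z0 = float(ndtri(prop))
    # jackknife acceleration over the concatenated leave-one-out scheme
    nx, ny = x.size, y.size
    loo_x = (x.sum() - x) / (nx - 1) - y.mean() if nx > 1 else np.array([obs])
    loo_y = x.mean() - (y.sum() - y) / (ny - 1) if ny > 1 else np.array([obs])
    theta = np.concatenate((loo_x, loo_y))
    d = theta.mean() - theta
    denom = 6.0 * (d @ d) ** 1.5
    a = float((d**3).sum() / denom) if denom > 0 else 0.0
    lo_lv, hi_lv = _adjusted_levels(z0, a, confidence_level)
    lo, hi = np.quantile(boot, [lo_lv, hi_lv])
    return float(lo), float(hi)


def permutation_p(
    test,
    control,
    n_permutation: int = 5000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Two-sided Monte-Carlo permutation p-value for the mean difference.

    Group labels are reshuffled ``n_permutation`` times; p is the corrected
    fraction of reshuffles whose |mean difference| is at least the observed
    |mean difference|: (1 + hits) / (n_permutation + 1).
    """
    x, y = _as_groups(test, control)
    if x.size + y.size < 4:
        raise ValueError("combined sample size must be at least 4")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = abs(x.mean() - y.mean())
    pool = np.concatenate((x, y))
    perms = rng.permuted(np.broadcast_to(pool, (n_permutation, pool.size)).copy(), axis=1)
    dx = perms[:, : x.size].mean(axis=1) - perms[:, x.size :].mean(axis=1)
    hits = int(np.count_nonzero(np.abs(dx) >= obs - 1e-12))
    return (1 + hits) / (n_permutation + 1)


def estimate_difference(
    test,
    control,
    n_bootstrap: int = 5000,
    n_permutation: int = 5000,
    confidence_level: float = 0.95,
    seed: int = 0,
) -> EstimationResult:
    """Full estimation-statistics result for one two-group comparison."""
    x, y = _as_groups(test, control)
    md = mean_difference(x, y)
    rng = np.random.default_rng(seed)
    ci_low, ci_high = bca_interval(
        x, y, n_bootstrap=n_bootstrap, confidence_level=confidence_level, seed=rng
    )
    p = permutation_p(x, y, n_permutation=n_permutation, seed=rng)
    degenerate = not (ci_low <= md <= ci_high)
    if degenerate:
        warnings.warn("observed mean difference outside the BCa interval", stacklevel=2)
    return EstimationResult(
        mean_difference=md,
        ci_low=ci_low,
        ci_high=ci_high,
        confidence_level=confidence_level,
        n_bootstrap=n_bootstrap,
        n_permutation=n_permutation,
        p_value=p,
        seed=seed,
        degenerate=degenerate,
    )
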