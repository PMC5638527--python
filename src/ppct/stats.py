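"""Nonparametric and regression statistics implemented from their definitions.

This module provides the analysis battery used throughout the pipeline:

* Spearman rank correlation (mid-ranks for ties, large-sample t p-value),
* standardized multiple regression (OLS on z-scored variables),
* the Steel-Dwass all-pairs comparison (pairwise rank-sum z statistics with
  tie correction, adjusted through the studentized-range distribution),
* the Mann-Whitney U test (normal approximation with tie and continuity
  correction; exact enumeration for small samples),
* Fisher-z comparison of two independent correlation coefficients.

Each procedure is written out from its defining formulas rather than wrapped
from a statistics library, so the behaviour is fully specified here; library
implementations serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.special import ndtr
from scipy.stats import rankdata, t as t_dist

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "AllPairsResult",
    "CollinearityError",
    "spearman",
    "regress_standardized",
    "steel_dwass",
    "mann_whitney",
    "compare_correlations",
    "studentized_range_sf",
]


class CollinearityError(ValueError):
    """Raised when a regression design matrix is rank deficient."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str = "spearman"


@dataclass(frozen=True)
class RegressionResult:
    """Standardized OLS coefficients with two-sided t p-values."""

    coefficients: Dict[str, float]
    p_values: Dict[str, float]
    n: int
    outcome: str = "y"


@dataclass(frozen=True)
class AllPairsResult:
    """Steel-Dwass all-pairs comparison: pair -> (z statistic, adjusted p)."""

    statistics: Dict[Tuple[int, int], float]
    p_values: Dict[Tuple[int, int], float]
    k: int

    def statistic(self, i: int, j: int) -> float:
        return self.statistics[(min(i, j), max(i, j))]

    def p_value(self, i: int, j: int) -> float:
        return self.p_values[(min(i, j), max(i, j))]


# ---------------------------------------------------------------------------
# Spearman correlation


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    r is the Pearson correlation of the mid-ranks; the two-sided p-value uses
    the large-sample t approximation ``t = r sqrt((n-2)/(1-r^2))`` on n-2
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = math.sqrt(float(np.dot(sx, sx)) * float(np.dot(sy, sy)))
    if denom == 0.0:
        raise ValueError("undefined correlation: zero variance in ranks")
    r = float(np.dot(sx, sy) / denom)
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        p = 0.0
    else:
        t_stat = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * t_dist.sf(abs(t_stat), df=n - 2))
    return CorrelationResult(r=r, p=p, n=n)


# ---------------------------------------------------------------------------
# Standardized multiple regression


def regress_standardized(
    y: Sequence[float],
    X: np.ndarray,
    predictor_names: Sequence[str] | None = None,
    outcome: str = "y",
) -> RegressionResult:
    """OLS on z-scored outcome and predictors: coefficients are standardized betas.

    The design is augmented with an intercept (numerically ~0 after
    z-scoring); p-values come from two-sided t statistics on n - p - 1
    degrees of freedom. Raises :class:`CollinearityError` on rank-deficient
    designs (e.g. duplicated predictors).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match number of rows of X")
    if n <= p + 1:
        raise ValueError("need n > number of predictors + 1")
    names = list(predictor_names) if predictor_names is not None else [f"x{i}" for i in range(p)]
    if len(names) != p:
        raise ValueError("predictor_names length must match columns of X")

    def zscore(a: np.ndarray) -> np.ndarray:
        sd = a.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant column: cannot standardize")
        return (a - a.mean(axis=0)) / sd

    yz = zscore(y)
    Xz = zscore(X)
    design = np.column_stack([np.ones(n), Xz])
    if np.linalg.matrix_rank(design) < p + 1:
        raise CollinearityError("design matrix is rank deficient")
    gram_inv = np.linalg.inv(design.T @ design)
    beta = gram_inv @ design.T @ yz
    resid = yz - design @ beta
    dof = n - p - 1
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(gram_inv) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = beta / se
    pvals = 2.0 * t_dist.sf(np.abs(t_stats), df=dof)
    return RegressionResult(
        coefficients={nm: float(b) for nm, b in zip(names, beta[1:])},
        p_values={nm: float(pv) for nm, pv in zip(names, pvals[1:])},
        n=n,
        outcome=outcome,
    )


# ---------------------------------------------------------------------------
# Rank-sum machinery shared by Mann-Whitney and Steel-Dwass


def _rank_sum_z(a: np.ndarray, b: np.ndarray, continuity: bool = True) -> float:
    """Standardized Wilcoxon rank-sum statistic for the first sample.

    Pooled mid-ranks; the tie-corrected variance is the exact finite-population
    variance of the rank sum, ``Var(W) = m n / (N (N-1)) * sum (r_k - rbar)^2``.
    A 0.5 continuity correction shrinks the deviation toward zero.
    """
    m, n = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    big_n = m + n
    w = float(ranks[:m].sum())
    expect = m * (big_n + 1) / 2.0
    centered = ranks - ranks.mean()
    var = m * n / (big_n * (big_n - 1.0)) * float(np.dot(centered, centered))
    if var == 0.0:
        return 0.0
    dev = w - expect
    if continuity:
        dev = math.copysign(max(abs(dev) - 0.5, 0.0), dev)
    return dev / math.sqrt(var)


def mann_whitney(a: Sequence[float], b: Sequence[float], method: str = "normal") -> float:
    """Two-sided Mann-Whitney p-value.

    ``method="normal"`` (default): normal approximation on the standardized
    rank sum with tie and continuity correction — the large-sample form used
    throughout the pipeline. ``method="exact"``: full enumeration over all
    C(m+n, m) group assignments of the pooled values (tie-safe), rejecting on
    the absolute deviation of the rank sum from its null mean; intended for
    small samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "normal":
        z = _rank_sum_z(a, b, continuity=True)
        return float(2.0 * (1.0 - ndtr(abs(z))))
    if method == "exact":
        return _mann_whitney_exact(a, b)
    raise ValueError(f"unknown method {method!r}")


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided p by enumeration of all pooled-rank assignments."""
    m = a.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    expect = m * (pooled.size + 1) / 2.0
    observed = abs(float(ranks[:m].sum()) - expect)
    total = 0
    hits = 0
    for combo in itertools.combinations(range(pooled.size), m):
        total += 1
        w = float(ranks[list(combo)].sum())
        if abs(w - expect) >= observed - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# Studentized range (df = infinity) and Steel-Dwass


def studentized_range_sf(q, k: int) -> np.ndarray | float:
    """Upper tail P(Q >= q) of the range of k iid standard normals.

    This is the studentized-range distribution with infinite degrees of
    freedom; the CDF is ``k * Int phi(z) [Phi(z) - Phi(z-q)]^(k-1) dz``,
    evaluated here by trapezoidal quadrature on a fine grid. Vectorized in q.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    out = np.ones_like(q_arr)
    pos = q_arr > 0
    if np.any(pos):
        z = np.linspace(-8.5, 8.5, 3401)
        phi = np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
        big_phi = ndtr(z)
        qp = q_arr[pos][:, None]
        inner = big_phi[None, :] - ndtr(z[None, :] - qp)
        cdf = k * np.trapezoid(phi[None, :] * inner ** (k - 1), z, axis=1)
        out[pos] = np.clip(1.0 - cdf, 0.0, 1.0)
    return out if np.ndim(q) else float(out[0])


def steel_dwass(groups: Sequence[Sequence[float]], continuity: bool = True) -> AllPairsResult:
    """Steel-Dwass all-pairs nonparametric comparison.

    For each unordered pair of groups the Wilcoxon rank-sum z statistic is
    computed on that pair's pooled mid-ranks with tie correction; the
    adjusted two-sided p-value refers ``sqrt(2) |z|`` to the studentized
    range of k groups (infinite degrees of freedom), which for k = 2 reduces
    to the ordinary two-sided normal Mann-Whitney p.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least 2 groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs at least 2 observations")
    pairs = list(itertools.combinations(range(k), 2))
    zs = np.array([_rank_sum_z(arrays[i], arrays[j], continuity=continuity) for i, j in pairs])
    padj = studentized_range_sf(math.sqrt(2.0) * np.abs(zs), k)
    return AllPairsResult(
        statistics={pair: float(z) for pair, z in zip(pairs, zs)},
        p_values={pair: float(p) for pair, p in zip(pairs, np.atleast_1d(padj))},
        k=k,
    )


# ---------------------------------------------------------------------------
# Comparison of two correlation coefficients


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-sided p for the difference of two independent correlations.

    Fisher z transform: ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))``.
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("correlations must satisfy |r| < 1")
    for n in (n1, n2):
        if n < 4:
            raise ValueError("need at least 4 observations per sample")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * (1.0 - ndtr(abs(z))))
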