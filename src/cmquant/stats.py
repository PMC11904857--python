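"""Two-group nonparametric comparison and summary statistics.

The Mann-Whitney U is computed from midrank sums with U = min(U1, U2).  The
two-sided p-value is exact (full enumeration of labelings) for combined
sample sizes up to ``EXACT_LIMIT`` with no ties, and otherwise uses the
normal approximation with tie and continuity corrections.  Tests are
two-sided throughout; no multiple-testing correction is applied by default
(a Holm adjustment is available but off by default).
"""

from __future__ import annotations

from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd

from .errors import DegenerateDataError
from .records import GroupComparison

__all__ = ["mann_whitney", "summarize", "star_annotation", "compare_groups",
           "holm_adjust"]

EXACT_LIMIT = 12
ALPHA = 0.05

_STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*"))


def _rank_u1(pooled: np.ndarray, n1: int) -> float:
    """U1 from midrank sums of the first n1 elements of ``pooled``."""
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def _exact_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p by enumeration of all C(n, n1) group labelings."""
    n = pooled.size
    n2 = n - n1
    order = np.argsort(pooled, kind="mergesort")
    sorted_vals = pooled[order]
    # midranks of the sorted pooled sample
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[i:j + 1] = (i + j) / 2.0 + 1.0
        i = j + 1
    u_hi = n1 * n2 - u_obs
    count = 0
    for subset in combinations(range(n), n1):
        u1 = ranks[list(subset)].sum() - n1 * (n1 + 1) / 2.0
        if u1 <= u_obs + 1e-9 or u1 >= u_hi - 1e-9:
            count += 1
    return min(1.0, count / comb(n, n1))


def _normal_p(pooled: np.ndarray, n1: int, u1: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = pooled.size
    n2 = n - n1
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(u1 - mu) - 0.5) / sqrt(var)
    z = max(z, 0.0)
    # two-sided: 2 * (1 - Phi(z)) == erfc(z / sqrt(2))
    return min(1.0, 1.0 - erf(z / sqrt(2.0)))


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U, p) with U = min(U1, U2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise DegenerateDataError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    u1 = _rank_u1(pooled, n1)
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    has_ties = np.unique(pooled).size < pooled.size
    if n1 + n2 <= EXACT_LIMIT and not has_ties:
        p = _exact_p(pooled, n1, u)
    else:
        p = _normal_p(pooled, n1, u1)
    return float(u), float(p)


def summarize(values) -> tuple[int, float, float, float]:
    """(n, mean, sd, sem); sd uses the n-1 denominator; NaN-dropped input."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise DegenerateDataError("empty sample")
    n = int(v.size)
    mean = float(v.mean())
    if n == 1:
        return n, mean, float("nan"), float("nan")
    sd = float(v.std(ddof=1))
    return n, mean, sd, sd / sqrt(n)


def star_annotation(p: float) -> str:
    """Map a p-value to the star category; half-open bins, p >= 0.05 -> ns."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    for threshold, stars in _STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment (optional; off by default in pipelines)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def compare_groups(table: pd.DataFrame, parameters: list[str] | None = None,
                   groups: tuple[str, str] | None = None,
                   group_col: str = "group", value_col: str = "value",
                   parameter_col: str = "parameter",
                   holm: bool = False) -> list[GroupComparison]:
    """Per-parameter two-group comparison of a long-format results table.

    ``table`` columns: group, parameter, value (names configurable).
    Missing values are dropped per parameter; reported n values are
    post-drop.
    """
    labels = list(pd.unique(table[group_col]))
    if groups is None:
        if len(labels) != 2:
            raise DegenerateDataError(
                f"expected exactly two groups, found {labels}")
        groups = (labels[0], labels[1])
    g1, g2 = groups
    for g in groups:
        if g not in labels:
            raise DegenerateDataError(f"group {g!r} absent from table")
    if parameters is None:
        parameters = list(pd.unique(table[parameter_col]))

    results = []
    for param in parameters:
        sub = table[table[parameter_col] == param]
        a = sub.loc[sub[group_col] == g1, value_col].dropna().to_numpy(float)
        b = sub.loc[sub[group_col] == g2, value_col].dropna().to_numpy(float)
        u, p = mann_whitney(a, b)
        n1, mean1, sd1, sem1 = summarize(a)
        n2, mean2, sd2, sem2 = summarize(b)
        results.append(GroupComparison(
            parameter=str(param), group1=g1, group2=g2, n1=n1, n2=n2,
            mean1=mean1, mean2=mean2, sd1=sd1, sd2=sd2, sem1=sem1, sem2=sem2,
            u_statistic=u, p_value=p, stars=star_annotation(p)))
    if holm:
        adj = holm_adjust([r.p_value for r in results])
        for r, pa in zip(results, adj):
            r.p_value = float(pa)
            r.stars = star_annotation(float(pa))
    return results
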