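"""Exact small-sample nonparametric tests and group summaries.

At the group sizes typical of mouse cohorts (n = 4-5 per group) the
asymptotic approximations behind rank tests are unreliable, and published
p-values from packages such as GraphPad Prism come from full enumeration of
the permutation distribution.  This module reproduces that arithmetic:

* :func:`mann_whitney_exact` enumerates all ``C(n1+n2, n1)`` rank
  assignments (midranks for ties) and reports the two-sided exact p-value
  as ``min(1, 2 * min(lower tail, upper tail))``.
* :func:`wilcoxon_signed_rank_exact` enumerates the ``2**n`` sign patterns
  of the ranked absolute differences via a generating-function convolution.
* :func:`kruskal_wallis` computes the tie-corrected H statistic with a
  chi-square reference, optionally exact by label enumeration for small n.
* :func:`spearman` computes the midrank correlation with an exact
  permutation p-value for n <= 9 and a t approximation otherwise.

Under complete separation the two-sided exact Mann-Whitney p-value is
``2 / C(n1+n2, n1)`` -- e.g. 2/252 = .0079 for 5 v 5, 2/70 = .0286 for
4 v 4, 2/126 = .0159 for 5 v 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "CorrelationResult",
    "GroupSummary",
    "mann_whitney_exact",
    "kruskal_wallis",
    "wilcoxon_signed_rank_exact",
    "spearman",
    "summarize",
    "fold_change",
]

#: largest total sample size for which the Mann-Whitney / Wilcoxon
#: permutation distributions are fully enumerated
EXACT_N_MAX = 20

#: largest pooled n for which Kruskal-Wallis enumerates all label assignments
KRUSKAL_EXACT_N_MAX = 10

#: largest n for which Spearman's p comes from all n! rank permutations
SPEARMAN_EXACT_N_MAX = 9


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample or k-sample rank test."""

    method: str
    statistic: float
    p_two_sided: float
    exact: bool
    n_per_group: tuple[int, ...]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_two_sided <= 1.0):
            raise ValueError(f"p-value out of (0, 1]: {self.p_two_sided}")


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank-order correlation with its two-sided p-value."""

    rho: float
    p_two_sided: float
    n: int
    exact: bool
    undefined: bool = False


@dataclass(frozen=True)
class GroupSummary:
    """Median and range, the reporting convention for small cohorts."""

    median: float
    min: float
    max: float
    n: int

    def __post_init__(self) -> None:
        if not (self.min <= self.median <= self.max):
            raise ValueError("median outside [min, max]")


def _as_1d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def mann_whitney_exact(x, y, exact_n_max: int = EXACT_N_MAX) -> TestResult:
    """Two-sample Mann-Whitney U test with exact enumeration p-value.

    For pooled ``n1 + n2 <= exact_n_max`` the p-value is computed by
    enumerating every assignment of the pooled midranks to the first group,
    conditioning on the observed tie pattern.  Larger samples fall back to
    the normal approximation with tie correction and continuity correction.

    Parameters
    ----------
    x, y : array-like
        The two groups of measurements.

    Returns
    -------
    TestResult
        ``statistic`` is ``U = min(U1, U2)``; ``p_two_sided`` is
        ``min(1, 2 * min tail)``.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:
        # no information: all observations identical across both groups
        return TestResult("mann_whitney", n1 * n2 / 2.0, 1.0, True, (n1, n2),
                          degenerate=True)
    ranks = _sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u = min(u1, n1 * n2 - u1)
    n = n1 + n2
    if n <= exact_n_max:
        idx = np.fromiter(
            (i for comb in combinations(range(n), n1) for i in comb),
            dtype=np.intp,
        ).reshape(-1, n1)
        u1_all = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
        total = u1_all.size
        eps = 1e-9
        p_low = np.count_nonzero(u1_all <= u1 + eps) / total
        p_high = np.count_nonzero(u1_all >= u1 - eps) / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return TestResult("mann_whitney", u, p, True, (n1, n2))
    # normal approximation with tie correction + continuity correction
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return TestResult("mann_whitney", u, 1.0, False, (n1, n2),
                          degenerate=True)
    z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * _sps.norm.sf(max(z, 0.0)))
    return TestResult("mann_whitney", u, p, False, (n1, n2))


def _kruskal_h(ranks: np.ndarray, sizes: np.ndarray, tie_factor: float) -> float:
    n = ranks.size
    h = 0.0
    start = 0
    for sz in sizes:
        rbar = ranks[start:start + sz].mean()
        h += sz * (rbar - (n + 1) / 2.0) ** 2
        start += sz
    h *= 12.0 / (n * (n + 1))
    return h / tie_factor


def kruskal_wallis(groups, exact: bool | None = None) -> TestResult:
    """Kruskal-Wallis H test across k groups with tie correction.

    ``p`` comes from the chi-square distribution with ``k - 1`` degrees of
    freedom; for pooled ``n <= 10`` (or ``exact=True``) the p-value is
    instead computed by enumerating every assignment of the pooled values
    to groups of the observed sizes.
    """
    arrays = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    sizes = np.array([a.size for a in arrays])
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = _sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_factor = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    if tie_factor == 0.0:  # every value identical
        return TestResult("kruskal_wallis", 0.0, 1.0, False,
                          tuple(sizes), degenerate=True)
    h = _kruskal_h(ranks, sizes, tie_factor)
    do_exact = exact if exact is not None else n <= KRUSKAL_EXACT_N_MAX
    if do_exact:
        p = _kruskal_exact_p(ranks, sizes, tie_factor, h)
        return TestResult("kruskal_wallis", h, p, True, tuple(sizes))
    p = float(_sps.chi2.sf(h, df=len(arrays) - 1))
    return TestResult("kruskal_wallis", h, max(p, np.finfo(float).tiny),
                      False, tuple(sizes))


def _kruskal_exact_p(ranks: np.ndarray, sizes: np.ndarray,
                     tie_factor: float, h_obs: float) -> float:
    """P(H >= h_obs) over all assignments of the observed ranks to groups."""
    n = ranks.size
    count = 0
    total = 0
    eps = 1e-9

    def recurse(remaining: tuple[int, ...], gi: int, chosen: list[np.ndarray]):
        nonlocal count, total
        if gi == len(sizes) - 1:
            perm = np.concatenate(chosen + [np.array(remaining, dtype=np.intp)])
            h = _kruskal_h(ranks[perm], sizes, tie_factor)
            total += 1
            if h >= h_obs - eps:
                count += 1
            return
        for comb in combinations(remaining, int(sizes[gi])):
            rest = tuple(i for i in remaining if i not in comb)
            recurse(rest, gi + 1, chosen + [np.array(comb, dtype=np.intp)])

    recurse(tuple(range(n)), 0, [])
    return count / total


def wilcoxon_signed_rank_exact(paired_diffs,
                               exact_n_max: int = EXACT_N_MAX) -> TestResult:
    """Wilcoxon signed-rank test on paired differences, exact for n <= 20.

    Zero differences are dropped before ranking (the standard Wilcoxon
    convention).  The exact two-sided p-value enumerates all ``2**n`` sign
    patterns of the observed absolute-difference midranks via a
    generating-function convolution, so ties in magnitudes are handled by
    conditioning on the observed midrank multiset.
    """
    d = np.asarray(paired_diffs, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("no paired differences supplied")
    d = d[d != 0.0]
    if d.size == 0:
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, True, (0,),
                          degenerate=True)
    n = d.size
    ranks = _sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks.sum() - w_plus)
    w = min(w_plus, w_minus)
    if n <= exact_n_max:
        # work in doubled-rank integers so midranks (x.5) stay exact
        r2 = np.rint(2 * ranks).astype(np.int64)
        max_sum = int(r2.sum())
        counts = np.zeros(max_sum + 1, dtype=np.float64)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: max_sum + 1 - r]
            counts = counts + shifted
        total = counts.sum()  # == 2**n
        w2 = int(round(2 * w_plus))
        p_low = counts[: w2 + 1].sum() / total
        p_high = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return TestResult("wilcoxon_signed_rank", w, p, True, (n,))
    mu = n * (n + 1) / 4.0
    _, tcounts = np.unique(ranks, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        np.sum(tcounts**3 - tcounts)) / 48.0
    z = (abs(w_plus - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * _sps.norm.sf(max(z, 0.0)))
    return TestResult("wilcoxon_signed_rank", w, p, False, (n,))


def spearman(x, y) -> CorrelationResult:
    """Spearman rank-order correlation with exact permutation p for n <= 9.

    ``rho`` is the Pearson correlation of the midranks.  For n <= 9 the
    two-sided p-value is the fraction of all n! permutations of the y-ranks
    whose |rho| reaches the observed |rho|; beyond that the Student-t
    approximation ``t = rho * sqrt((n-2)/(1-rho^2))`` is used.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    rx = _sps.rankdata(x)
    ry = _sps.rankdata(y)
    if np.ptp(rx) == 0.0 or np.ptp(ry) == 0.0:
        return CorrelationResult(float("nan"), 1.0, n, False, undefined=True)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= SPEARMAN_EXACT_N_MAX:
        from itertools import permutations

        perms = np.array(list(permutations(range(n))), dtype=np.intp)
        ry_perm = ry[perms]  # (n!, n)
        rx_c = rx - rx.mean()
        ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        num = ry_c @ rx_c
        den = math.sqrt(float(rx_c @ rx_c)) * np.sqrt(
            np.einsum("ij,ij->i", ry_c, ry_c))
        rho_all = num / den
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
        return CorrelationResult(rho, p, n, True)
    if abs(rho) >= 1.0:
        # t approximation degenerates; fall back to the no-tie exact value
        return CorrelationResult(rho, min(1.0, 2.0 / math.factorial(n)), n,
                                 False)
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = min(1.0, 2.0 * float(_sps.t.sf(abs(t), df=n - 2)))
    return CorrelationResult(rho, p, n, False)


def summarize(values) -> GroupSummary:
    """Median and range (min-max) of one group of measurements."""
    v = _as_1d(values, "values")
    return GroupSummary(float(np.median(v)), float(v.min()), float(v.max()),
                        int(v.size))


def fold_change(a_median: float, b_median: float) -> float:
    """Ratio of two group medians, ``a / b``.

    Raises if the reference median ``b`` is zero.  Rounding to printed
    precision is left to the caller.
    """
    if b_median == 0:
        raise ValueError("reference median is zero")
    return float(a_median) / float(b_median)
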