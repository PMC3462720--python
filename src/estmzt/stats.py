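"""Nonparametric and normality statistics used throughout the analysis.

Self-contained implementations of the Kruskal-Wallis rank test with tie
correction, Dunn's multiple-comparison post test with a compact letter
display, and the D'Agostino-Pearson omnibus K2 normality test.  Group
differences in stage-resolved expression and in 3'UTR length are assessed
with these tests; normality is reported first but the nonparametric path is
always taken, since neither qPCR replicates (n = 3) nor UTR lengths are
Gaussian.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, norm

from estmzt.core import ValidationError, require

__all__ = [
    "TestResult",
    "PairwiseResult",
    "DunnResult",
    "kruskal_wallis",
    "dunns_test",
    "dagostino_pearson",
]


@dataclass
class TestResult:
    method: str
    statistic: float | None
    p_value: float | None
    df: int | None = None
    group_sizes: tuple[int, ...] | None = None
    tie_correction_applied: bool = False
    note: str | None = None

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value out of [0,1]: {self.p_value}")


@dataclass
class PairwiseResult:
    group_i: int
    group_j: int
    z: float
    p_raw: float
    p_adjusted: float


@dataclass
class DunnResult:
    pairs: list[PairwiseResult]
    letters: list[str]
    alpha: float
    adjustment: str
    mean_ranks: list[float] = field(default_factory=list)

    def significant(self, i: int, j: int) -> bool:
        a, b = min(i, j), max(i, j)
        for pr in self.pairs:
            if (pr.group_i, pr.group_j) == (a, b):
                return pr.p_adjusted <= self.alpha
        raise KeyError((i, j))


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Mid-ranks (ties share the average rank), 1-based."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        ranks[order[i : j + 1]] = avg
        i = j + 1
    return ranks


def _tie_counts(pooled: np.ndarray) -> np.ndarray:
    _, counts = np.unique(pooled, return_counts=True)
    return counts


def kruskal_wallis(groups: list[list[float]] | list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis H test across two or more groups.

    H = [12 / (N(N+1))] * sum_i R_i^2 / n_i - 3(N+1) on mid-ranks, divided by
    the tie-correction factor 1 - sum(t^3 - t)/(N^3 - N).  The p-value is
    asymptotic chi-square with k-1 degrees of freedom.  When every pooled
    value is identical the test is degenerate and reported as H = 0, p = 1.
    """
    require(len(groups) >= 2, "kruskal_wallis requires at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for k, a in enumerate(arrays):
        require(a.size >= 1, f"group {k} is empty")
    sizes = tuple(a.size for a in arrays)
    n_total = int(sum(sizes))
    require(n_total >= 3, "kruskal_wallis requires at least 3 observations in total")
    pooled = np.concatenate(arrays)

    ties = _tie_counts(pooled)
    tie_factor = 1.0 - float(np.sum(ties**3 - ties)) / (n_total**3 - n_total)
    if tie_factor == 0.0:  # all values identical
        return TestResult(
            method="kruskal_wallis",
            statistic=0.0,
            p_value=1.0,
            df=len(groups) - 1,
            group_sizes=sizes,
            tie_correction_applied=True,
            note="all pooled values identical",
        )

    ranks = _midranks(pooled)
    h = 0.0
    offset = 0
    for a in arrays:
        r = ranks[offset : offset + a.size]
        h += r.sum() ** 2 / a.size
        offset += a.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    h /= tie_factor
    h = max(h, 0.0)
    dof = len(groups) - 1
    p = float(chi2.sf(h, dof))
    return TestResult(
        method="kruskal_wallis",
        statistic=float(h),
        p_value=p,
        df=dof,
        group_sizes=sizes,
        tie_correction_applied=bool(np.any(ties > 1)),
    )


def _compact_letters(k: int, significant: set[tuple[int, int]]) -> list[str]:
    """Compact letter display: groups share a letter iff not significantly different.

    Insert-and-absorb: start from one set holding all groups; each significant
    pair splits every set containing both; redundant subsets are absorbed.
    """
    sets: list[set[int]] = [set(range(k))]
    for i, j in sorted(significant):
        new_sets: list[set[int]] = []
        for s in sets:
            if i in s and j in s:
                new_sets.append(s - {i})
                new_sets.append(s - {j})
            else:
                new_sets.append(s)
        # absorb subsets
        kept: list[set[int]] = []
        for s in new_sets:
            if not s:
                continue
            if any(s < t for t in new_sets if t is not s):
                continue
            if s not in kept:
                kept.append(s)
        sets = kept
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for idx, s in enumerate(sets):
        for g in sorted(s):
            letters[g] += alphabet[idx % len(alphabet)]
    return letters


def dunns_test(
    groups: list[list[float]] | list[np.ndarray],
    alpha: float = 0.05,
    adjustment: str = "bonferroni",
) -> DunnResult:
    """Dunn's rank-based multiple comparisons following a Kruskal-Wallis test.

    z_ij = (meanrank_i - meanrank_j) / sqrt[(N(N+1)/12 - tie_term)(1/n_i + 1/n_j)]
    with tie_term = sum(t^3 - t) / (12(N-1)); two-sided normal p-values,
    adjusted over all k(k-1)/2 pairs (``bonferroni`` default, ``holm`` or
    ``none`` available).  Groups sharing a letter in the compact letter
    display are not significantly different at ``alpha``.
    """
    require(len(groups) >= 2, "dunns_test requires at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for k, a in enumerate(arrays):
        require(a.size >= 1, f"group {k} is empty")
    if adjustment not in ("bonferroni", "holm", "none"):
        raise ValidationError(f"unknown adjustment: {adjustment}")
    sizes = [a.size for a in arrays]
    n_total = int(sum(sizes))
    pooled = np.concatenate(arrays)
    ranks = _midranks(pooled)
    mean_ranks = []
    offset = 0
    for a in arrays:
        mean_ranks.append(float(ranks[offset : offset + a.size].mean()))
        offset += a.size
    ties = _tie_counts(pooled)
    tie_term = float(np.sum(ties**3 - ties)) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    variance = n_total * (n_total + 1) / 12.0 - tie_term

    k = len(arrays)
    pairs: list[PairwiseResult] = []
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(variance * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0.0:  # all pooled values identical
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = float(2.0 * norm.sf(abs(z)))
        pairs.append(PairwiseResult(i, j, float(z), p_raw, p_raw))

    m = len(pairs)
    if adjustment == "bonferroni":
        for pr in pairs:
            pr.p_adjusted = min(1.0, pr.p_raw * m)
    elif adjustment == "holm":
        order = sorted(range(m), key=lambda idx: pairs[idx].p_raw)
        running = 0.0
        for rank, idx in enumerate(order):
            adj = min(1.0, (m - rank) * pairs[idx].p_raw)
            running = max(running, adj)
            pairs[idx].p_adjusted = running

    significant = {
        (pr.group_i, pr.group_j) for pr in pairs if pr.p_adjusted <= alpha
    }
    letters = _compact_letters(k, significant)
    return DunnResult(
        pairs=pairs,
        letters=letters,
        alpha=alpha,
        adjustment=adjustment,
        mean_ranks=mean_ranks,
    )


def dagostino_pearson(values: list[float] | np.ndarray) -> TestResult:
    """D'Agostino-Pearson omnibus K2 normality test.

    K2 = Z(sqrt(b1))^2 + Z(b2)^2 combining the D'Agostino skewness transform
    with the Anscombe-Glynn kurtosis transform; p from chi-square with 2 df.
    Samples below n = 8 cannot support the transforms and are reported with
    an ``insufficient n`` note instead of a statistic (three qPCR replicates
    per stage fall in this regime).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 8:
        return TestResult(
            method="dagostino_pearson",
            statistic=None,
            p_value=None,
            group_sizes=(n,),
            note="insufficient n",
        )
    m = x.mean()
    dev = x - m
    m2 = float(np.mean(dev**2))
    if m2 == 0.0:
        raise ValidationError("dagostino_pearson: zero variance input")
    b1_sqrt = float(np.mean(dev**3)) / m2**1.5
    b2 = float(np.mean(dev**4)) / m2**2

    # skewness transform (D'Agostino 1970)
    y = b1_sqrt * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = 3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / (
        (n - 2.0) * (n + 5) * (n + 7) * (n + 9)
    )
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(0.5 * math.log(w2))
    alpha = math.sqrt(2.0 / (w2 - 1.0))
    y = y if y != 0 else 1e-30
    z_skew = delta * math.log(y / alpha + math.sqrt((y / alpha) ** 2 + 1.0))

    # kurtosis transform (Anscombe & Glynn 1983)
    e_b2 = 3.0 * (n - 1) / (n + 1)
    var_b2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xk = (b2 - e_b2) / math.sqrt(var_b2)
    sqrt_beta1 = (
        6.0 * (n**2 - 5 * n + 2) / ((n + 7.0) * (n + 9))
        * math.sqrt(6.0 * (n + 3) * (n + 5) / (n * (n - 2.0) * (n - 3)))
    )
    a = 6.0 + 8.0 / sqrt_beta1 * (2.0 / sqrt_beta1 + math.sqrt(1.0 + 4.0 / sqrt_beta1**2))
    term = (1.0 - 2.0 / a) / (1.0 + xk * math.sqrt(2.0 / (a - 4.0)))
    z_kurt = ((1.0 - 2.0 / (9.0 * a)) - math.copysign(abs(term) ** (1.0 / 3.0), term)) / math.sqrt(
        2.0 / (9.0 * a)
    )

    k2 = z_skew**2 + z_kurt**2
    p = float(chi2.sf(k2, 2))
    return TestResult(
        method="dagostino_pearson",
        statistic=float(k2),
        p_value=p,
        df=2,
        group_sizes=(n,),
    )
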