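"""Pairwise overlap of gene / pathway signatures and level-comparison tests.

The overlap percentage between two signature lists is
``100 * m / (n1 + n2 - m)`` where m is the number of shared entries —
the Jaccard index in percent. Computing it for every unordered pair of
datasets at the gene level (COPA outlier-gene lists) and at the pathway
level (significant enriched-set name lists) yields paired vectors whose
difference is assessed with a paired t-test and a Wilcoxon signed-rank
test: the question is whether signatures agree better at the pathway
level than at the gene level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

SIDES = ("two", "greater", "less")


@dataclass
class OverlapMatrix:
    """Symmetric pairwise overlap percentages for one observation level."""

    dataset_names: list[str]
    level: str                      # "gene" or "pathway"
    percent: np.ndarray             # D x D, diagonal 100 for non-empty lists
    m: np.ndarray                   # D x D overlap counts
    sizes: np.ndarray               # per-dataset list sizes

    def pair_percents(self) -> tuple[list[tuple[str, str]], np.ndarray]:
        """Upper-triangle pairs in lexicographic index order and their percents."""
        D = len(self.dataset_names)
        pairs, vals = [], []
        for i, j in combinations(range(D), 2):
            pairs.append((self.dataset_names[i], self.dataset_names[j]))
            vals.append(self.percent[i, j])
        return pairs, np.array(vals)


@dataclass
class LevelComparison:
    """Paired comparison of gene-level vs pathway-level overlap percentages."""

    pair_ids: list[tuple[str, str]]
    gene_percents: np.ndarray
    pathway_percents: np.ndarray
    t_stat: float
    t_df: int
    t_p: float
    w_stat: float
    w_p: float
    side: str
    n_pairs_pathway_higher: int

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)


def overlap_percentage(set_a: Sequence[str], set_b: Sequence[str]) -> float:
    """Overlap percentage 100*m/(n1+n2-m) between two signature lists.

    Defined as 0 (with a warning) when either list is empty.
    """
    A, B = set(set_a), set(set_b)
    if not A or not B:
        warnings.warn("overlap_percentage: empty signature list; returning 0")
        return 0.0
    m = len(A & B)
    return 100.0 * m / (len(A) + len(B) - m)


def pairwise_overlap(lists: Mapping[str, Sequence[str]], level: str = "gene") -> OverlapMatrix:
    """All-pairs overlap percentages over >= 2 datasets' signature lists."""
    names = list(lists)
    D = len(names)
    if D < 2:
        raise ValueError("pairwise overlap needs >= 2 datasets")
    sets = {nm: set(lists[nm]) for nm in names}
    percent = np.zeros((D, D))
    m = np.zeros((D, D), dtype=int)
    sizes = np.array([len(sets[nm]) for nm in names])
    for i in range(D):
        percent[i, i] = 100.0 if sizes[i] else 0.0
        m[i, i] = sizes[i]
        for j in range(i + 1, D):
            mm = len(sets[names[i]] & sets[names[j]])
            m[i, j] = m[j, i] = mm
            percent[i, j] = percent[j, i] = overlap_percentage(
                sets[names[i]], sets[names[j]]
            ) if sizes[i] and sizes[j] else 0.0
    return OverlapMatrix(dataset_names=names, level=level, percent=percent, m=m, sizes=sizes)


def paired_t_test(
    x: Sequence[float], y: Sequence[float], side: str = "two"
) -> tuple[float, int, float]:
    """Paired t-test on d = y - x; returns (t, df, p).

    ``side="greater"`` tests the alternative mean(y) > mean(x).
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("paired t-test needs n >= 3 pairs")
    d = y - x
    if np.std(d, ddof=1) == 0:
        raise ValueError("all paired differences identical; t-test degenerate")
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[side]
    res = stats.ttest_rel(y, x, alternative=alternative)
    return float(res.statistic), n - 1, float(res.pvalue)


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    """W = sum of ranks of positive differences, average ranks on |d| ties."""
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def _exact_signed_rank_sf(n: int) -> np.ndarray:
    """Null counts of W over all 2^n sign assignments (integer ranks 1..n).

    counts[w] = number of sign vectors with positive-rank sum w. Dynamic
    programme equivalent to full enumeration.
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        new = counts.copy()
        new[r:] += counts[:-r] if r > 0 else counts
        counts = new
    return counts


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    side: str = "two",
    exact_max_n: int = 25,
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on d = y - x; returns (W, p).

    Zero differences are dropped; |d| ties get average ranks; W is the sum
    of positive-difference ranks. The p-value is exact (full enumeration
    of the 2^n sign assignments, via an equivalent dynamic programme) when
    the post-drop n <= ``exact_max_n`` and there are no ties; otherwise a
    normal approximation with tie correction and continuity correction.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    d = y - x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    W, ranks = _signed_rank_statistic(d)

    has_ties = len(np.unique(np.abs(d))) < n
    if n <= exact_max_n and not has_ties:
        counts = _exact_signed_rank_sf(n)
        total = 2.0 ** n
        w = int(round(W))
        p_ge = counts[w:].sum() / total
        p_le = counts[: w + 1].sum() / total
        if side == "greater":
            p = p_ge
        elif side == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return W, float(p)

    # normal approximation with tie + continuity correction
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
    sd = np.sqrt(var)
    if sd == 0:
        raise ValueError("zero variance in signed ranks")
    if side == "greater":
        z = (W - mean - 0.5) / sd
        p = stats.norm.sf(z)
    elif side == "less":
        z = (W - mean + 0.5) / sd
        p = stats.norm.cdf(z)
    else:
        z = (abs(W - mean) - 0.5) / sd
        p = 2.0 * stats.norm.sf(max(z, 0.0))
    return W, float(min(p, 1.0))


def compare_levels(
    gene_overlaps: OverlapMatrix,
    pathway_overlaps: OverlapMatrix,
    side: str = "two",
) -> LevelComparison:
    """Paired tests of pathway-level vs gene-level overlap across all pairs.

    With ``side="greater"`` the alternative is that pathway-level overlap
    exceeds gene-level overlap.
    """
    if gene_overlaps.dataset_names != pathway_overlaps.dataset_names:
        raise ValueError("overlap matrices cover different datasets")
    pairs, gvals = gene_overlaps.pair_percents()
    _, pvals = pathway_overlaps.pair_percents()
    t, df, p_t = paired_t_test(gvals, pvals, side=side)
    W, p_w = wilcoxon_signed_rank(gvals, pvals, side=side)
    return LevelComparison(
        pair_ids=pairs,
        gene_percents=gvals,
        pathway_percents=pvals,
        t_stat=t,
        t_df=df,
        t_p=p_t,
        w_stat=W,
        w_p=p_w,
        side=side,
        n_pairs_pathway_higher=int(np.sum(pvals > gvals)),
    )
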