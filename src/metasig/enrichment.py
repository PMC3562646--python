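"""Over-representation analysis of an outlier-gene list against gene sets.

For a query list of n genes drawn from a universe of N genes, a set with
K members in the universe and k members in the query is scored by the
hypergeometric upper tail P(X >= k), with Benjamini-Hochberg step-up
control of the false discovery rate across the tested sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    set_name: str
    k: int   # overlap between query and set
    K: int   # set size in universe
    n: int   # query size in universe
    N: int   # universe size
    p_value: float
    q_value: float = np.nan
    significant: bool = False


@dataclass
class EnrichmentTable:
    """Per-set enrichment results, sorted by p then set name."""

    records: list[EnrichmentRecord]
    alpha: float
    rule: str  # "p" or "pq"

    def significant_sets(self) -> list[str]:
        return [r.set_name for r in self.records if r.significant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set_name": [r.set_name for r in self.records],
                "k": [r.k for r in self.records],
                "K": [r.K for r in self.records],
                "n": [r.n for r in self.records],
                "N": [r.N for r in self.records],
                "p_value": [r.p_value for r in self.records],
                "q_value": [r.q_value for r in self.records],
                "significant": [int(r.significant) for r in self.records],
            }
        )


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Computed via the survival function (log-space internally in scipy)
    for numerical stability; k = 0 returns exactly 1.
    """
    if K > N or n > N:
        raise ValueError(f"set size K={K} and query size n={n} must not exceed N={N}")
    if k < 0 or k > min(n, K):
        raise ValueError(f"overlap k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich(
    query: Sequence[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    rule: str = "p",
    include_empty: bool = False,
) -> EnrichmentTable:
    """Score every gene set against the query list.

    Query genes outside the collection's universe are dropped with a
    logged count. Sets with zero overlap are excluded before the FDR
    adjustment unless ``include_empty``. ``rule`` selects the
    significance call: ``"p"`` for p < alpha, ``"pq"`` for
    p < alpha AND q < alpha.
    """
    if rule not in ("p", "pq"):
        raise ValueError("rule must be 'p' or 'pq'")
    universe = set(collection.universe)
    N = len(universe)
    q_genes = [g for g in dict.fromkeys(query)]
    in_uni = [g for g in q_genes if g in universe]
    dropped = len(q_genes) - len(in_uni)
    if dropped:
        logger.info("enrich: dropped %d query genes outside the universe", dropped)
    if not in_uni:
        raise ValueError("query does not intersect the gene-set universe")
    qset = set(in_uni)
    n = len(qset)

    records = []
    for name, (_, members) in collection.sets.items():
        mem = set(members) & universe
        K = len(mem)
        k = len(mem & qset)
        if k == 0 and not include_empty:
            continue
        records.append(
            EnrichmentRecord(
                set_name=name, k=k, K=K, n=n, N=N,
                p_value=hypergeometric_pvalue(k, K, n, N),
            )
        )
    if records:
        qvals = bh_adjust([r.p_value for r in records])
        for r, qv in zip(records, qvals):
            r.q_value = float(qv)
            if rule == "p":
                r.significant = r.p_value < alpha
            else:
                r.significant = (r.p_value < alpha) and (r.q_value < alpha)
    records.sort(key=lambda r: (r.p_value, r.set_name))
    return EnrichmentTable(records=records, alpha=alpha, rule=rule)
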