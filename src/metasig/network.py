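"""Dataset similarity networks over significant-pathway profiles.

Each dataset is represented by a binary indicator vector over the union
of significant pathways; five distances (euclidean, manhattan, hamming,
pearson, kendall) quantify dataset similarity, and an association
network links datasets whose pathway-level overlap percentage exceeds a
threshold (default two-thirds, i.e. 200/3 %). Connected components of
that network define dataset groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import kendalltau

from .concordance import OverlapMatrix

METRICS = ("euclidean", "manhattan", "hamming", "pearson", "kendall")
TWO_THIRDS_PERCENT = 200.0 / 3.0


@dataclass
class DatasetNetwork:
    nodes: list[str]
    indicator: pd.DataFrame                 # datasets x pathways, 0/1
    distances: dict[str, pd.DataFrame]
    edges: list[tuple[str, str, float]]     # (a, b, overlap percent)
    edge_rule_threshold: float

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, pct in self.edges:
            g.add_edge(a, b, percent=pct)
        return g


def pathway_indicator_matrix(
    significant_sets: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Datasets x pathways binary membership matrix, columns lexicographic."""
    names = list(significant_sets)
    if len(names) < 2:
        raise ValueError("indicator matrix needs >= 2 datasets")
    union = sorted({p for lst in significant_sets.values() for p in lst})
    if not union:
        raise ValueError("all significant-pathway lists are empty")
    data = np.zeros((len(names), len(union)), dtype=int)
    col = {p: j for j, p in enumerate(union)}
    for i, nm in enumerate(names):
        for p in set(significant_sets[nm]):
            data[i, col[p]] = 1
    return pd.DataFrame(data, index=names, columns=union)


def distance_matrix(indicator: pd.DataFrame, metric: str) -> pd.DataFrame:
    """D x D distance matrix over row vectors for one of the five metrics.

    hamming counts differing positions; pearson distance is 1 - r (on
    binary rows this is 1 minus the phi coefficient); kendall distance is
    1 - tau-b.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    X = indicator.to_numpy(dtype=float)
    names = list(indicator.index)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 datasets")
    if metric in ("pearson", "kendall"):
        const = np.ptp(X, axis=1) == 0
        if const.any():
            bad = [names[i] for i in np.flatnonzero(const)]
            raise ValueError(
                f"constant indicator row(s) {bad} undefined under {metric} distance"
            )
    if metric == "euclidean":
        D = cdist(X, X, metric="euclidean")
    elif metric == "manhattan":
        D = cdist(X, X, metric="cityblock")
    elif metric == "hamming":
        D = cdist(X, X, metric="hamming") * X.shape[1]
    elif metric == "pearson":
        D = 1.0 - np.corrcoef(X)
    else:  # kendall, tau-b with tie correction
        n = X.shape[0]
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                tau = kendalltau(X[i], X[j], variant="b").statistic
                D[i, j] = D[j, i] = 1.0 - tau
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=names, columns=names)


def build_network(
    overlaps: OverlapMatrix,
    threshold: float = TWO_THIRDS_PERCENT,
    indicator: pd.DataFrame | None = None,
    metrics: Sequence[str] = METRICS,
) -> DatasetNetwork:
    """Edge (i, j) iff pathway-level overlap percent is strictly > threshold.

    Each edge carries its overlap percentage. If an indicator matrix is
    supplied, the requested distance matrices are attached.
    """
    if not (0 <= threshold <= 100):
        raise ValueError("threshold must lie in [0, 100]")
    names = overlaps.dataset_names
    edges = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pct = float(overlaps.percent[i, j])
            if pct > threshold:
                edges.append((names[i], names[j], pct))
    distances: dict[str, pd.DataFrame] = {}
    if indicator is not None:
        for m in metrics:
            try:
                distances[m] = distance_matrix(indicator, m)
            except ValueError:
                continue  # constant rows make correlational metrics undefined
    return DatasetNetwork(
        nodes=list(names),
        indicator=indicator if indicator is not None else pd.DataFrame(index=names),
        distances=distances,
        edges=edges,
        edge_rule_threshold=threshold,
    )


def connected_groups(network: DatasetNetwork) -> list[list[str]]:
    """Connected components as sorted name lists, ordered by smallest member."""
    g = network.graph()
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    return comps
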