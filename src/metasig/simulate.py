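"""Synthetic multi-dataset expression collections with planted pathway signal.

The generator emulates the structure of a multi-study cancer microarray
compendium: D independent datasets that share the same "true" cancer
pathways, but in each dataset only a random q-fraction of each true
pathway's member genes is actually differentially expressed, and each
such gene is overexpressed (by +delta log2 units) in only a random
f-fraction of the tumor samples — the subset-specific outlier profile
COPA is designed to detect. Because the q-fraction is resampled
independently per dataset, gene-level signatures diverge across datasets
while pathway-level signatures coincide. An optional partition of the
datasets into groups with disjoint true-pathway sets creates planted
group structure for the similarity network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import ExpressionDataset, GeneSetCollection, NORMAL, TUMOR


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults define the headline study conditions."""

    n_datasets: int = 5
    n_genes: int = 2000
    n_normal: int = 15
    n_tumor: int = 15
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (15, 40)
    n_true_pathways: int = 8        # per group
    de_fraction: float = 0.3        # q: fraction of a true pathway's genes DE per dataset
    outlier_fraction: float = 0.4   # f: fraction of tumor samples carrying the signal
    effect_size: float = 3.0        # delta, log2 units
    noise_sd: float = 1.0           # sigma
    background_de_rate: float = 0.005  # b: per-gene off-pathway DE probability
    baseline_mean: float = 8.0
    baseline_mean_sd: float = 1.0
    groups: tuple[tuple[int, ...], ...] | None = None  # partition of dataset indices
    seed: int = 0

    def __post_init__(self) -> None:
        for nm in ("de_fraction", "outlier_fraction", "background_de_rate"):
            v = getattr(self, nm)
            if not (0 <= v <= 1):
                raise ValueError(f"{nm} must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if min(self.n_datasets, self.n_genes, self.n_normal, self.n_tumor,
               self.n_pathways) <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid pathway size range")
        n_groups = len(self.groups) if self.groups else 1
        if self.n_true_pathways * n_groups > self.n_pathways:
            raise ValueError("not enough pathways for the requested true pathways per group")
        if self.groups:
            flat = sorted(i for g in self.groups for i in g)
            if flat != list(range(self.n_datasets)):
                raise ValueError("groups must partition the dataset indices")


def two_group_config(**overrides) -> SimConfig:
    """Two groups of three datasets with disjoint true-pathway sets.

    The default network-recovery condition: within a group every dataset
    shares the same 8 true pathways, across groups none are shared. The
    DE fraction is 0.5 here (vs 0.3 in the headline config) so that each
    dataset's enriched-pathway profile is a reliable readout of its
    group's true pathways: with q = 0.3 a 15-member pathway contributes
    only ~4 of its genes to a ~160-gene outlier list, a hypergeometric
    overlap that sits at the significance boundary, and a missed pathway
    can push a within-group overlap below the two-thirds edge rule.
    """
    base = dict(
        n_datasets=6,
        n_pathways=24,
        groups=((0, 1, 2), (3, 4, 5)),
        de_fraction=0.5,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated compendium."""

    collection: GeneSetCollection
    true_pathways: dict[int, list[str]]            # group index -> pathway names
    de_genes: dict[str, list[str]]                 # dataset name -> DE gene list
    outlier_samples: dict[str, dict[str, list[str]]]  # dataset -> gene -> samples
    group_of: dict[str, int]                       # dataset name -> group index

    def planted_partition(self) -> list[list[str]]:
        """Dataset groups as sorted name lists, ordered by smallest member."""
        groups: dict[int, list[str]] = {}
        for nm, g in self.group_of.items():
            groups.setdefault(g, []).append(nm)
        out = [sorted(v) for v in groups.values()]
        out.sort(key=lambda c: c[0])
        return out


def _gene_names(G: int) -> list[str]:
    width = len(str(G))
    return [f"g{i:0{width}d}" for i in range(1, G + 1)]


def generate_collection(
    config: SimConfig, rng: np.random.Generator | None = None
) -> GeneSetCollection:
    """Sample P gene sets (no within-set duplicates; overlap across sets OK)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.pathway_size_range
    if hi > config.n_genes:
        raise ValueError(
            f"pathway size up to {hi} infeasible with a {config.n_genes}-gene universe"
        )
    genes = _gene_names(config.n_genes)
    width = len(str(config.n_pathways))
    sets = {}
    for p in range(1, config.n_pathways + 1):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(config.n_genes, size=size, replace=False))
        sets[f"P{p:0{width}d}"] = (
            f"synthetic pathway {p}",
            [genes[i] for i in sorted(members)],
        )
    return GeneSetCollection(sets=sets, universe=genes)


def generate_multidataset(
    config: SimConfig,
) -> tuple[list[ExpressionDataset], SyntheticTruth]:
    """Generate D expression datasets plus their ground truth.

    Baseline expression is Gaussian on the log2 scale, x[g,s] ~
    N(mu_g, sigma) with per-dataset gene means mu_g ~ N(8, 1). DE genes
    (the per-dataset q-fraction of each true pathway plus rate-b
    background genes) gain +delta in a fresh f-fraction of tumor samples.
    Fully deterministic given the config (which carries the seed).
    """
    rng = np.random.default_rng(config.seed)
    n_out = round(config.outlier_fraction * config.n_tumor)
    if n_out == 0 and config.effect_size > 0 and config.de_fraction > 0:
        raise ValueError(
            "outlier_fraction * n_tumor rounds to 0 tumor samples; "
            "the planted signal cannot be placed"
        )
    collection = generate_collection(config, rng)
    pathway_names = collection.names()
    groups = config.groups or (tuple(range(config.n_datasets)),)

    # disjoint true-pathway sets per group
    perm = list(rng.permutation(len(pathway_names)))
    true_pathways: dict[int, list[str]] = {}
    for gi in range(len(groups)):
        idx = perm[gi * config.n_true_pathways:(gi + 1) * config.n_true_pathways]
        true_pathways[gi] = sorted(pathway_names[i] for i in idx)

    genes = collection.universe
    gene_index = {g: i for i, g in enumerate(genes)}
    samples = [f"n{i}" for i in range(1, config.n_normal + 1)] + [
        f"t{i}" for i in range(1, config.n_tumor + 1)
    ]
    labels = {s: (NORMAL if s.startswith("n") else TUMOR) for s in samples}
    tumor_cols = np.arange(config.n_normal, config.n_normal + config.n_tumor)

    datasets: list[ExpressionDataset] = []
    de_genes: dict[str, list[str]] = {}
    outlier_samples: dict[str, dict[str, list[str]]] = {}
    group_of: dict[str, int] = {}

    for gi, members in enumerate(groups):
        for d in members:
            name = f"ds{d + 1}"
            group_of[name] = gi
            mu = rng.normal(config.baseline_mean, config.baseline_mean_sd,
                            size=config.n_genes)
            values = rng.normal(
                mu[:, None], config.noise_sd,
                size=(config.n_genes, len(samples)),
            )

            de: dict[str, None] = {}
            for pw in true_pathways[gi]:
                pw_members = collection.members(pw)
                n_de = max(1, round(config.de_fraction * len(pw_members)))
                chosen = rng.choice(len(pw_members), size=n_de, replace=False)
                for c in sorted(chosen):
                    de.setdefault(pw_members[c])
            if config.background_de_rate > 0:
                bg = rng.random(config.n_genes) < config.background_de_rate
                for i in np.flatnonzero(bg):
                    de.setdefault(genes[i])

            per_gene_outliers: dict[str, list[str]] = {}
            if config.effect_size > 0 and n_out > 0:
                for g in de:
                    cols = rng.choice(tumor_cols, size=n_out, replace=False)
                    values[gene_index[g], cols] += config.effect_size
                    per_gene_outliers[g] = sorted(samples[c] for c in cols)

            datasets.append(
                ExpressionDataset(
                    name=name,
                    genes=list(genes),
                    samples=list(samples),
                    values=values,
                    missing_mask=np.zeros_like(values, dtype=bool),
                    labels=labels.copy(),
                    log2=True,
                    platform="synthetic",
                )
            )
            de_genes[name] = list(de)
            outlier_samples[name] = per_gene_outliers

    # keep dataset order by index even when groups interleave
    order = {ds.name: int(ds.name[2:]) for ds in datasets}
    datasets.sort(key=lambda ds: order[ds.name])

    truth = SyntheticTruth(
        collection=collection,
        true_pathways=true_pathways,
        de_genes=de_genes,
        outlier_samples=outlier_samples,
        group_of=group_of,
    )
    return datasets, truth


def reseeded(config: SimConfig, seed: int) -> SimConfig:
    """Copy of the config with a different seed."""
    return replace(config, seed=seed)
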