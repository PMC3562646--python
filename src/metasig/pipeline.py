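"""End-to-end orchestration: simulate -> copa -> enrich -> concordance -> network.

`run_meta_analysis` is the in-memory composition used by scripts and
tests; `run_pipeline` drives it from a RunConfig, writes every stage's
table to a run directory, and records a manifest (parameters, seed,
versions) so a run is reproducible and restartable from intermediates.
"""

from __future__ import annotations

import configparser
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .concordance import LevelComparison, OverlapMatrix, compare_levels, pairwise_overlap
from .copa import CopaResult, call_outlier_genes
from .enrichment import EnrichmentTable, enrich
from .io import (
    CopaParams,
    ExpressionDataset,
    GeneSetCollection,
    read_expression_matrix,
    read_gmt,
    write_expression_matrix,
    write_gmt,
    write_labels,
)
from .network import (
    METRICS,
    TWO_THIRDS_PERCENT,
    DatasetNetwork,
    build_network,
    connected_groups,
    pathway_indicator_matrix,
)
from .simulate import SimConfig, generate_multidataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat run configuration; every stage parameter has the field default."""

    copa: CopaParams = field(default_factory=CopaParams)
    alpha: float = 0.05
    rule: str = "p"                      # significance rule: "p" or "pq"
    metrics: tuple[str, ...] = METRICS
    edge_threshold: float = TWO_THIRDS_PERCENT
    side: str = "two"                    # level-comparison test side
    seed: int = 0
    sim: SimConfig | None = None         # simulate stage; None = read from disk
    expression_paths: tuple[tuple[str, str], ...] = ()  # (matrix, labels) pairs
    gmt_path: str | None = None
    out_dir: str = "run"

    @classmethod
    def from_ini(cls, path: str | Path) -> "RunConfig":
        cp = configparser.ConfigParser()
        cp.read(path)
        run = cp["run"] if "run" in cp else {}
        copa = cp["copa"] if "copa" in cp else {}
        sim = cp["simulate"] if "simulate" in cp else None
        seed = int(run.get("seed", 0))
        cfg = cls(
            copa=CopaParams(
                outlier_cutoff=float(copa.get("cutoff", 1.7)),
                prefilter_percentile=float(copa.get("percentile", 95)),
                center_on=copa.get("center_on", "all"),
                two_sided=copa.get("two_sided", "false").lower() == "true",
            ),
            alpha=float(run.get("alpha", 0.05)),
            rule=run.get("rule", "p"),
            edge_threshold=float(run.get("edge_threshold", TWO_THIRDS_PERCENT)),
            side=run.get("side", "two"),
            seed=seed,
            out_dir=run.get("out_dir", "run"),
            gmt_path=run.get("gmt") or None,
        )
        if sim is not None:
            cfg.sim = SimConfig(
                n_datasets=int(sim.get("n_datasets", 5)),
                n_genes=int(sim.get("n_genes", 2000)),
                n_normal=int(sim.get("n_normal", 15)),
                n_tumor=int(sim.get("n_tumor", 15)),
                n_pathways=int(sim.get("n_pathways", 20)),
                n_true_pathways=int(sim.get("n_true_pathways", 8)),
                de_fraction=float(sim.get("de_fraction", 0.3)),
                outlier_fraction=float(sim.get("outlier_fraction", 0.4)),
                effect_size=float(sim.get("effect_size", 3.0)),
                noise_sd=float(sim.get("noise_sd", 1.0)),
                background_de_rate=float(sim.get("background_de_rate", 0.005)),
                seed=seed,
            )
        return cfg


@dataclass
class MetaAnalysisResult:
    """All per-stage outputs of one multi-dataset run."""

    copa_results: dict[str, CopaResult]
    enrichment_tables: dict[str, EnrichmentTable]
    gene_overlaps: OverlapMatrix
    pathway_overlaps: OverlapMatrix
    comparison: LevelComparison
    network: DatasetNetwork
    groups: list[list[str]]


def run_meta_analysis(
    datasets: list[ExpressionDataset],
    collection: GeneSetCollection,
    copa_params: CopaParams = CopaParams(),
    alpha: float = 0.05,
    rule: str = "p",
    edge_threshold: float = TWO_THIRDS_PERCENT,
    side: str = "two",
    metrics: tuple[str, ...] = METRICS,
) -> MetaAnalysisResult:
    """COPA + enrichment per dataset, both overlap levels, tests, network."""
    if len(datasets) < 2:
        raise ValueError("meta-analysis needs >= 2 datasets")
    copa_results: dict[str, CopaResult] = {}
    enr_tables: dict[str, EnrichmentTable] = {}
    gene_lists: dict[str, list[str]] = {}
    pathway_lists: dict[str, list[str]] = {}
    for ds in datasets:
        try:
            res = call_outlier_genes(ds, copa_params)
        except ValueError as exc:
            raise RuntimeError(f"copa stage failed on dataset {ds.name!r}: {exc}") from exc
        copa_results[ds.name] = res
        gene_lists[ds.name] = res.outlier_gene_list
        # universe: genes measured on this (filtered) platform that the
        # collection also covers
        restricted = collection.restrict_to(
            [g for g in ds.genes if g in set(collection.universe)]
        )
        try:
            table = enrich(res.outlier_gene_list, restricted, alpha=alpha, rule=rule)
        except ValueError as exc:
            raise RuntimeError(
                f"enrichment stage failed on dataset {ds.name!r}: {exc}"
            ) from exc
        enr_tables[ds.name] = table
        pathway_lists[ds.name] = table.significant_sets()

    gene_overlaps = pairwise_overlap(gene_lists, level="gene")
    pathway_overlaps = pairwise_overlap(pathway_lists, level="pathway")
    comparison = compare_levels(gene_overlaps, pathway_overlaps, side=side)
    indicator = pathway_indicator_matrix(pathway_lists)
    network = build_network(
        pathway_overlaps, threshold=edge_threshold, indicator=indicator,
        metrics=metrics,
    )
    groups = connected_groups(network)
    return MetaAnalysisResult(
        copa_results=copa_results,
        enrichment_tables=enr_tables,
        gene_overlaps=gene_overlaps,
        pathway_overlaps=pathway_overlaps,
        comparison=comparison,
        network=network,
        groups=groups,
    )


# ---------------------------------------------------------------------------
# On-disk run directory
# ---------------------------------------------------------------------------


def _overlap_long_frame(om: OverlapMatrix) -> pd.DataFrame:
    pairs, vals = om.pair_percents()
    idx = {nm: i for i, nm in enumerate(om.dataset_names)}
    rows = []
    for (a, b), pct in zip(pairs, vals):
        i, j = idx[a], idx[b]
        rows.append(
            dict(pair=f"{a}|{b}", level=om.level, n1=int(om.sizes[i]),
                 n2=int(om.sizes[j]), m=int(om.m[i, j]), percent=pct)
        )
    return pd.DataFrame(rows)


def write_run_outputs(result: MetaAnalysisResult, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, cr in result.copa_results.items():
        df = pd.DataFrame(
            {
                "gene": cr.retained_genes,
                "count": [cr.outlier_counts[cr.genes.index(g)] for g in cr.retained_genes],
                "max_transformed": [
                    cr.max_tumor_value[cr.genes.index(g)] for g in cr.retained_genes
                ],
            }
        )
        df.to_csv(out / f"copa_{name}.tsv", sep="\t", index=False, float_format="%.6g")
    for name, table in result.enrichment_tables.items():
        table.to_frame().to_csv(
            out / f"enrichment_{name}.tsv", sep="\t", index=False, float_format="%.6g"
        )
    overlaps = pd.concat(
        [_overlap_long_frame(result.gene_overlaps),
         _overlap_long_frame(result.pathway_overlaps)],
        ignore_index=True,
    )
    overlaps.to_csv(out / "overlaps.tsv", sep="\t", index=False, float_format="%.6g")

    c = result.comparison
    summary = pd.DataFrame(
        [dict(level_test="pathway_vs_gene", n_pairs=c.n_pairs, side=c.side,
              t=c.t_stat, df=c.t_df, p_t=c.t_p, W=c.w_stat, p_w=c.w_p,
              n_pairs_pathway_higher=c.n_pairs_pathway_higher)]
    )
    summary.to_csv(out / "level_comparison.tsv", sep="\t", index=False,
                   float_format="%.6g")

    edges = pd.DataFrame(result.network.edges, columns=["nodeA", "nodeB", "percent"])
    edges.to_csv(out / "network_edges.tsv", sep="\t", index=False, float_format="%.6g")
    for metric, dm in result.network.distances.items():
        dm.to_csv(out / f"distance_{metric}.tsv", sep="\t", float_format="%.6g")
    with open(out / "groups.json", "w", encoding="utf-8") as fh:
        json.dump(result.groups, fh, indent=1)
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Run all enabled stages and write a seeded, reproducible run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.sim is not None:
        sim_cfg = config.sim
        datasets, truth = generate_multidataset(sim_cfg)
        write_gmt(truth.collection, out / "sets.gmt")
        # GMT carries no universe; persist it so a file-based rerun uses
        # the same N in the hypergeometric test
        (out / "universe.txt").write_text(
            "\n".join(truth.collection.universe) + "\n"
        )
        for ds in datasets:
            write_expression_matrix(ds, out / f"{ds.name}_expression.tsv")
            write_labels(ds.labels, out / f"{ds.name}_labels.tsv")
        collection = truth.collection
        with open(out / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(
                dict(
                    true_pathways={str(k): v for k, v in truth.true_pathways.items()},
                    de_genes=truth.de_genes,
                    group_of=truth.group_of,
                ),
                fh, indent=1,
            )
    else:
        if not config.expression_paths or not config.gmt_path:
            raise ValueError(
                "run_pipeline: no simulate stage and no input expression/GMT paths"
            )
        datasets = [
            read_expression_matrix(
                m, l, name=Path(m).stem.removesuffix("_expression")
            )
            for m, l in config.expression_paths
        ]
        universe_file = Path(config.gmt_path).with_name("universe.txt")
        universe = (
            universe_file.read_text().split() if universe_file.exists() else None
        )
        collection = read_gmt(config.gmt_path, universe=universe)

    result = run_meta_analysis(
        datasets, collection,
        copa_params=config.copa, alpha=config.alpha, rule=config.rule,
        edge_threshold=config.edge_threshold, side=config.side,
        metrics=config.metrics,
    )
    write_run_outputs(result, out)

    manifest = dict(
        version=__version__,
        seed=config.seed,
        copa=asdict(config.copa),
        alpha=config.alpha,
        rule=config.rule,
        edge_threshold=config.edge_threshold,
        side=config.side,
        n_datasets=len(datasets),
        numpy=np.__version__,
    )
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("pipeline complete: %s", out)
    return out
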