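"""Cancer Outlier Profile Analysis (COPA).

COPA targets genes overexpressed in only a subset of tumor samples —
the heterogeneous-activation profile typical of fusion oncogenes — which
mean-based statistics (t, SAM, z) dilute away. Each gene's profile is
median-centered and MAD-scaled across samples; tumor samples whose
transformed value exceeds a cutoff (default 1.7) are outliers, and genes
whose outlier count reaches the upper tail of the count distribution
(default the 95th percentile, nearest-rank) are retained as the
dataset's outlier-gene signature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io import CopaParams, ExpressionDataset, NORMAL, TUMOR

logger = logging.getLogger(__name__)


@dataclass
class CopaResult:
    """Transformed matrix, per-gene tumor outlier counts, and retained genes."""

    dataset_name: str
    genes: list[str]
    transformed: np.ndarray
    outlier_counts: np.ndarray        # tumor samples only, -1 for degenerate genes
    degenerate: np.ndarray            # bool per gene: MAD == 0, excluded
    retained_genes: list[str]
    prefilter_threshold_count: int
    params: CopaParams
    max_tumor_value: np.ndarray = field(default=None)  # per gene, NaN if degenerate

    @property
    def outlier_gene_list(self) -> list[str]:
        """The DEG list used by downstream overlap analysis."""
        return list(self.retained_genes)


def copa_transform(
    dataset: ExpressionDataset, params: CopaParams = CopaParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise median-center and MAD-scale the expression matrix.

    Returns ``(transformed, degenerate)``. Median and MAD are computed over
    the gene's non-missing values — over all samples by default, or over
    normal samples only with ``params.center_on == "normal"``. Genes with
    zero MAD are flagged degenerate (NaN rows) rather than raising.
    """
    vals = dataset.values.copy()
    vals[dataset.missing_mask] = np.nan
    if params.center_on == "normal":
        ref_cols = dataset.class_indices(NORMAL)
        ref = vals[:, ref_cols]
    else:
        ref = vals

    n_ok = np.isfinite(vals).sum(axis=1)
    if np.any(n_ok < 4):
        bad = [g for g, n in zip(dataset.genes, n_ok) if n < 4]
        raise ValueError(
            f"dataset {dataset.name!r}: genes with < 4 non-missing values "
            f"(filter first): {bad[:3]}"
        )

    med = np.nanmedian(ref, axis=1, keepdims=True)
    mad_raw = np.nanmedian(np.abs(ref - med), axis=1, keepdims=True)
    scale = params.mad_constant * mad_raw
    degenerate = (scale == 0).ravel()
    if degenerate.any():
        logger.info(
            "copa_transform(%s): %d degenerate genes (MAD=0) excluded",
            dataset.name, int(degenerate.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        transformed = (vals - med) / scale
    transformed[degenerate, :] = np.nan
    return transformed, degenerate


def count_outliers(
    transformed: np.ndarray,
    dataset: ExpressionDataset,
    params: CopaParams = CopaParams(),
) -> np.ndarray:
    """Count, per gene, the tumor samples strictly above the outlier cutoff.

    A value exactly at the cutoff is not an outlier. With
    ``params.two_sided`` the comparison is on ``|t|``.
    """
    tumor_cols = dataset.class_indices(TUMOR)
    if tumor_cols.size == 0:
        raise ValueError(f"dataset {dataset.name!r} has no tumor samples")
    t = transformed[:, tumor_cols]
    if params.two_sided:
        exceed = np.abs(t) > params.outlier_cutoff
    else:
        exceed = t > params.outlier_cutoff
    return np.nansum(exceed, axis=1).astype(int)


def copa_prefilter(
    counts: np.ndarray,
    genes: list[str],
    degenerate: np.ndarray,
    percentile: float,
    max_tumor_value: np.ndarray | None = None,
) -> tuple[list[str], int]:
    """Keep genes whose outlier count reaches the nearest-rank percentile.

    The threshold is the ``ceil(percentile/100 * G)``-th order statistic of
    the count distribution over non-degenerate genes; genes with count >=
    threshold are retained, ordered by (count desc, max transformed tumor
    value desc, gene ID asc).
    """
    if not (0 < percentile <= 100):
        raise ValueError("percentile must be in (0, 100]")
    ok = ~np.asarray(degenerate, dtype=bool)
    counts = np.asarray(counts)
    valid_counts = counts[ok]
    if valid_counts.size == 0:
        raise ValueError("no non-degenerate genes to filter")
    k = math.ceil(percentile / 100.0 * valid_counts.size)
    threshold = int(np.sort(valid_counts)[k - 1])

    if max_tumor_value is None:
        max_tumor_value = np.zeros(len(genes))
    order = []
    for i, g in enumerate(genes):
        if ok[i] and counts[i] >= threshold:
            mv = max_tumor_value[i]
            order.append((-counts[i], -(mv if np.isfinite(mv) else -np.inf), g))
    order.sort()
    retained = [g for _, _, g in order]
    return retained, threshold


def call_outlier_genes(
    dataset: ExpressionDataset, params: CopaParams = CopaParams()
) -> CopaResult:
    """Full COPA call: transform, count tumor outliers, percentile pre-filter."""
    transformed, degenerate = copa_transform(dataset, params)
    counts = count_outliers(transformed, dataset, params)
    counts = np.where(degenerate, -1, counts)

    tumor_cols = dataset.class_indices(TUMOR)
    with np.errstate(all="ignore"):
        t = transformed[:, tumor_cols]
        all_nan = np.all(np.isnan(t), axis=1)
        max_tumor = np.where(all_nan, np.nan, np.nanmax(np.where(np.isnan(t), -np.inf, t), axis=1))

    retained, threshold = copa_prefilter(
        np.where(degenerate, 0, counts),
        dataset.genes,
        degenerate,
        params.prefilter_percentile,
        max_tumor,
    )
    return CopaResult(
        dataset_name=dataset.name,
        genes=list(dataset.genes),
        transformed=transformed,
        outlier_counts=counts,
        degenerate=degenerate,
        retained_genes=retained,
        prefilter_threshold_count=threshold,
        params=params,
        max_tumor_value=max_tumor,
    )
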