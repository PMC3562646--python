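"""Preprocessing for heterogeneous microarray datasets.

Covers the standard cleanup chain for two-channel cDNA arrays and mixed
collections: median background subtraction, within-chip LOWESS
normalization of the M (log-ratio) vs A (average log-intensity) trend,
between-chip MAD scaling to a common robust scale, and removal of genes
absent in too many samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .io import ExpressionDataset

logger = logging.getLogger(__name__)

MAD_CONSTANT = 1.4826  # normal-consistency scaling


def median(x: np.ndarray) -> float:
    """Median; for an even count, the mean of the two central order statistics."""
    return float(np.median(x))


def mad(x: np.ndarray, constant: float = MAD_CONSTANT) -> float:
    """Median absolute deviation, scaled for consistency at the normal."""
    x = np.asarray(x, dtype=float)
    return constant * median(np.abs(x - median(x)))


@dataclass
class TwoChannelArray:
    """Per-spot foreground/background intensities of a two-channel array."""

    spots: list[str]
    fg_red: np.ndarray
    bg_red: np.ndarray
    fg_green: np.ndarray
    bg_green: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.spots)
        for attr in ("fg_red", "bg_red", "fg_green", "bg_green"):
            v = np.asarray(getattr(self, attr), dtype=float)
            setattr(self, attr, v)
            if v.shape != (n,):
                raise ValueError(f"{attr} must have length {n}")
            if np.any(v < 0):
                raise ValueError(f"{attr} contains negative intensities")


def read_two_channel(path) -> TwoChannelArray:
    """Read a 5-column TSV (gene, fgR, bgR, fgG, bgG), header optional."""
    spots, cols = [], ([], [], [], [])
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ValueError(
                    f"{path}: line {lineno}: expected 5 fields, got {len(parts)}"
                )
            try:
                vals = [float(v) for v in parts[1:]]
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise ValueError(f"{path}: line {lineno}: non-numeric intensity")
            spots.append(parts[0])
            for c, v in zip(cols, vals):
                c.append(v)
    return TwoChannelArray(
        spots=spots,
        fg_red=np.array(cols[0]), bg_red=np.array(cols[1]),
        fg_green=np.array(cols[2]), bg_green=np.array(cols[3]),
    )


def background_correct(array: TwoChannelArray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Subtract background from foreground in both channels.

    Returns ``(R, G, missing)`` where spots with a non-positive corrected
    intensity in either channel are flagged missing (their log-ratio is
    undefined) rather than clamped.
    """
    R = array.fg_red - array.bg_red
    G = array.fg_green - array.bg_green
    missing = (R <= 0) | (G <= 0)
    if missing.any():
        logger.info("background_correct: %d spots flagged missing", int(missing.sum()))
    return R, G, missing


def lowess_normalize(
    R: np.ndarray,
    G: np.ndarray,
    missing: np.ndarray | None = None,
    span: float = 2.0 / 3.0,
) -> np.ndarray:
    """LOWESS-normalize two-channel log-ratios against average intensity.

    Computes M = log2(R/G) and A = (log2 R + log2 G)/2 per spot, fits a
    locally weighted regression of M on A with the given span (one
    robustness iteration), and returns M minus the fit. Missing spots stay
    NaN in the output.
    """
    R = np.asarray(R, dtype=float)
    G = np.asarray(G, dtype=float)
    if missing is None:
        missing = ~(np.isfinite(R) & np.isfinite(G) & (R > 0) & (G > 0))
    missing = np.asarray(missing, dtype=bool)
    usable = ~missing
    if int(usable.sum()) < 10:
        raise ValueError(
            f"lowess_normalize: only {int(usable.sum())} usable spots; need >= 10"
        )
    M = np.full(R.shape, np.nan)
    A = np.full(R.shape, np.nan)
    M[usable] = np.log2(R[usable] / G[usable])
    A[usable] = 0.5 * (np.log2(R[usable]) + np.log2(G[usable]))

    fitted = _sm_lowess(
        M[usable], A[usable], frac=span, it=1, return_sorted=False
    )
    out = np.full(R.shape, np.nan)
    out[usable] = M[usable] - fitted
    return out


def mad_scale_between_arrays(
    arrays: list[np.ndarray], constant: float = MAD_CONSTANT
) -> list[np.ndarray]:
    """Median-center each array and rescale to the common target MAD.

    The target is the median of the per-array MADs before scaling; after
    the transform every array has median 0 and MAD equal to the target.
    NaNs are ignored when computing the statistics and preserved in place.
    """
    if len(arrays) < 2:
        raise ValueError("between-chip scaling needs >= 2 arrays")
    meds, mads = [], []
    for i, a in enumerate(arrays):
        a = np.asarray(a, dtype=float)
        vals = a[np.isfinite(a)]
        if vals.size < 4:
            raise ValueError(f"array {i}: fewer than 4 non-missing values")
        m = median(vals)
        s = mad(vals, constant)
        if s == 0:
            raise ValueError(f"array {i}: MAD is 0; cannot rescale a constant array")
        meds.append(m)
        mads.append(s)
    target = median(np.array(mads))
    out = []
    for a, m, s in zip(arrays, meds, mads):
        a = np.asarray(a, dtype=float)
        out.append((a - m) * (target / s))
    return out


def mad_scale_dataset(dataset: ExpressionDataset, constant: float = MAD_CONSTANT) -> ExpressionDataset:
    """Apply between-chip MAD scaling to the columns (arrays) of a dataset."""
    cols = [dataset.values[:, j] for j in range(dataset.n_samples)]
    scaled = mad_scale_between_arrays(cols, constant)
    values = np.column_stack(scaled)
    values[dataset.missing_mask] = np.nan
    return ExpressionDataset(
        name=dataset.name,
        genes=list(dataset.genes),
        samples=list(dataset.samples),
        values=values,
        missing_mask=dataset.missing_mask.copy(),
        labels=dict(dataset.labels),
        log2=dataset.log2,
        platform=dataset.platform,
    )


def filter_absent_genes(
    dataset: ExpressionDataset, max_absent_frac: float = 0.60, inclusive: bool = True
) -> ExpressionDataset:
    """Drop genes missing in at least ``max_absent_frac`` of the samples.

    The boundary is inclusive by default (a gene missing in exactly 60% of
    samples is removed); set ``inclusive=False`` for a strict comparison.
    Gene order is preserved. Idempotent.
    """
    frac = dataset.missing_mask.mean(axis=1)
    if inclusive:
        keep = frac < max_absent_frac
    else:
        keep = frac <= max_absent_frac
    kept_genes = [g for g, k in zip(dataset.genes, keep) if k]
    n_dropped = dataset.n_genes - len(kept_genes)
    if n_dropped:
        logger.info(
            "filter_absent_genes(%s): removed %d/%d genes",
            dataset.name, n_dropped, dataset.n_genes,
        )
    if not kept_genes:
        raise ValueError(f"dataset {dataset.name!r}: absence filter removed all genes")
    return dataset.subset_genes(kept_genes)
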