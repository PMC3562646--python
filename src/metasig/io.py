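"""Domain types and readers/writers for expression matrices, labels and GMT gene sets.

The on-disk formats are the plain-text conventions of microarray
meta-analysis: a genes x samples TSV with a header row of sample
identifiers, a two-column sample->class labels TSV, and the standard GMT
gene-set format (set name, description, then member genes, tab-separated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Cell contents recognised as a missing measurement (case-insensitive).
MISSING_TOKENS = {"", "na", "nan"}

NORMAL = "normal"
TUMOR = "tumor"
VALID_CLASSES = frozenset({NORMAL, TUMOR})


class DataFormatError(ValueError):
    """Raised when an input file violates the expected format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with class labels.

    Parameters
    ----------
    name : str
        Dataset identifier (conventionally the first author of the study).
    genes, samples : list of str
        Ordered row / column identifiers. Gene identifiers must be unique.
    values : ndarray of float, shape (n_genes, n_samples)
        Expression values; entries under ``missing_mask`` are undefined
        (stored as NaN by the readers).
    missing_mask : ndarray of bool, same shape
        True where the measurement is missing.
    labels : mapping sample -> {"normal", "tumor"}
    log2 : bool
        Whether ``values`` are on log2 scale.
    platform : str
        Free-text platform annotation.
    """

    name: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray
    missing_mask: np.ndarray
    labels: dict[str, str]
    log2: bool = True
    platform: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"dataset {self.name!r}: value matrix shape {self.values.shape} "
                f"does not match {len(self.genes)} genes x {len(self.samples)} samples"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape does not match values")
        dupes = _duplicates(self.genes)
        if dupes:
            raise DataFormatError(
                f"dataset {self.name!r}: duplicate gene identifier {dupes[0]!r}"
            )
        for s in self.samples:
            if s not in self.labels:
                raise DataFormatError(
                    f"dataset {self.name!r}: sample {s!r} has no class label"
                )
            if self.labels[s] not in VALID_CLASSES:
                raise DataFormatError(
                    f"dataset {self.name!r}: sample {s!r} has invalid class "
                    f"{self.labels[s]!r} (expected normal/tumor)"
                )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def class_indices(self, cls: str) -> np.ndarray:
        """Column indices of samples with the given class label."""
        return np.array(
            [i for i, s in enumerate(self.samples) if self.labels[s] == cls],
            dtype=int,
        )

    @property
    def n_normal(self) -> int:
        return len(self.class_indices(NORMAL))

    @property
    def n_tumor(self) -> int:
        return len(self.class_indices(TUMOR))

    def subset_genes(self, keep: Sequence[str]) -> "ExpressionDataset":
        """Return a copy restricted to ``keep`` (order preserved as given)."""
        idx = {g: i for i, g in enumerate(self.genes)}
        rows = [idx[g] for g in keep]
        return ExpressionDataset(
            name=self.name,
            genes=list(keep),
            samples=list(self.samples),
            values=self.values[rows, :].copy(),
            missing_mask=self.missing_mask[rows, :].copy(),
            labels=dict(self.labels),
            log2=self.log2,
            platform=self.platform,
        )


@dataclass
class GeneSetCollection:
    """Named gene sets over a stated gene universe (GMT-backed).

    ``sets`` maps set name -> (description, ordered member gene list).
    ``universe`` defaults to the union of all members.
    """

    sets: dict[str, tuple[str, list[str]]]
    universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.universe:
            seen: dict[str, None] = {}
            for _, (_, members) in self.sets.items():
                for g in members:
                    seen.setdefault(g)
            self.universe = list(seen)
        uni = set(self.universe)
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            missing = [g for g in members if g not in uni]
            if missing:
                raise ValueError(
                    f"gene set {name!r} has members outside the universe: "
                    f"{missing[:3]}"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def restrict_to(self, universe: Sequence[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop sets that become empty."""
        uni = set(universe)
        new_sets = {}
        for name, (desc, members) in self.sets.items():
            kept = [g for g in members if g in uni]
            if kept:
                new_sets[name] = (desc, kept)
        if not new_sets:
            raise ValueError("no gene set survives restriction to the given universe")
        return GeneSetCollection(sets=new_sets, universe=[g for g in universe])


@dataclass(frozen=True)
class CopaParams:
    """Tuning parameters of the outlier-gene caller.

    outlier_cutoff : threshold on the median/MAD-transformed value above
        which a tumor sample counts as an outlier (default 1.7).
    prefilter_percentile : nearest-rank percentile of the per-gene outlier
        count distribution below which genes are dropped (default 95).
    mad_constant : normal-consistency constant for the MAD (1.4826).
    center_on : "all" (median/MAD over all samples) or "normal".
    two_sided : also count strong under-expression (|t| > cutoff).
    """

    outlier_cutoff: float = 1.7
    prefilter_percentile: float = 95.0
    mad_constant: float = 1.4826
    center_on: str = "all"
    two_sided: bool = False

    def __post_init__(self) -> None:
        if self.outlier_cutoff <= 0:
            raise ValueError("outlier_cutoff must be > 0")
        if not (0 < self.prefilter_percentile <= 100):
            raise ValueError("prefilter_percentile must be in (0, 100]")
        if self.center_on not in ("all", "normal"):
            raise ValueError("center_on must be 'all' or 'normal'")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dupes = []
    for x in items:
        if x in seen:
            dupes.append(x)
        seen.add(x)
    return dupes


def _is_missing(token: str) -> bool:
    return token.strip().lower() in MISSING_TOKENS


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of sample -> class (normal/tumor)."""
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataFormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(parts)}"
                )
            sample, cls = parts[0].strip(), parts[1].strip().lower()
            # allow a header line
            if lineno == 1 and cls not in VALID_CLASSES:
                continue
            if cls not in VALID_CLASSES:
                raise DataFormatError(
                    f"{path}: line {lineno}: class {parts[1]!r} is not normal/tumor"
                )
            labels[sample] = cls
    if not labels:
        raise DataFormatError(f"{path}: no labels found")
    return labels


def read_expression_matrix(
    path: str | Path,
    labels_path: str | Path,
    *,
    name: str | None = None,
    log2: bool = True,
    platform: str = "",
) -> ExpressionDataset:
    """Read a genes x samples TSV plus a labels TSV into an ExpressionDataset.

    The matrix file has a header row of sample identifiers and the gene
    identifier in the first column. Empty cells, ``NA`` and ``NaN``
    (case-insensitive) are treated as missing. A 2-line GCT preamble
    (``#1.2`` then dimensions) is skipped if present.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if lines and lines[0].startswith("#1."):
        lines = lines[2:]  # tolerate a GCT preamble
    if not lines:
        raise DataFormatError(f"{path}: empty file")

    header = lines[0].split("\t")
    samples = [h.strip() for h in header[1:]]
    if not samples:
        raise DataFormatError(f"{path}: header row has no sample columns")

    genes: list[str] = []
    rows: list[list[float]] = []
    mask_rows: list[list[bool]] = []
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(samples) + 1:
            raise DataFormatError(
                f"{path}: line {lineno}: expected {len(samples) + 1} fields, "
                f"got {len(parts)}"
            )
        gene = parts[0].strip()
        if gene in set(genes):
            raise DataFormatError(f"{path}: duplicate gene identifier {gene!r}")
        vals, miss = [], []
        for j, cell in enumerate(parts[1:]):
            if _is_missing(cell):
                vals.append(np.nan)
                miss.append(True)
            else:
                try:
                    vals.append(float(cell))
                except ValueError as exc:
                    raise DataFormatError(
                        f"{path}: line {lineno}, sample {samples[j]!r}: "
                        f"non-numeric cell {cell!r}"
                    ) from exc
                miss.append(False)
        genes.append(gene)
        rows.append(vals)
        mask_rows.append(miss)

    labels = read_labels(labels_path)
    for s in samples:
        if s not in labels:
            raise DataFormatError(
                f"{path}: sample {s!r} in matrix is absent from labels file"
            )

    return ExpressionDataset(
        name=name or path.stem,
        genes=genes,
        samples=samples,
        values=np.array(rows, dtype=float),
        missing_mask=np.array(mask_rows, dtype=bool),
        labels={s: labels[s] for s in samples},
        log2=log2,
        platform=platform,
    )


def write_expression_matrix(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset back to the genes x samples TSV dialect."""
    df = pd.DataFrame(dataset.values, index=dataset.genes, columns=dataset.samples)
    df = df.mask(pd.DataFrame(dataset.missing_mask, index=df.index, columns=df.columns))
    df.to_csv(path, sep="\t", index_label="gene", na_rep="NA")


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sample, cls in labels.items():
            fh.write(f"{sample}\t{cls}\n")


def read_gmt(path: str | Path, universe: Sequence[str] | None = None) -> GeneSetCollection:
    """Read a GMT gene-set file: name TAB description TAB gene TAB gene ..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataFormatError(
                    f"{path}: line {lineno}: GMT line needs >= 3 fields "
                    f"(name, description, >= 1 gene), got {len(parts)}"
                )
            name, desc = parts[0], parts[1]
            if name in sets:
                raise DataFormatError(
                    f"{path}: line {lineno}: duplicate set name {name!r}"
                )
            members = [g.strip() for g in parts[2:] if g.strip()]
            if not members:
                raise DataFormatError(
                    f"{path}: line {lineno}: set {name!r} has no genes"
                )
            sets[name] = (desc, members)
    if not sets:
        raise DataFormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, universe=list(universe) if universe else [])


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection to GMT; round-trips through :func:`read_gmt`."""
    if not collection.sets:
        raise ValueError("cannot write an empty collection")
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")
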