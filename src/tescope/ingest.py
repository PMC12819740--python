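"""Readers and core containers for locus-level TE + gene expression data.

Count matrices arrive as an MTX triplet (matrix, features, barcodes) in
which transposable-element features carry their genomic locus encoded in
the feature name::

    TE|<chrom>|<start>|<end>|<subfamily>:<family>:<class>|<strand>

Coordinates are 0-based half-open (BED convention) throughout the
package.  Strand is parsed and carried but ignored by every distance
computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

__all__ = [
    "TELocus",
    "ExpressionMatrix",
    "TENameError",
    "parse_te_name",
    "format_te_name",
    "normalize_te_class",
    "filter_low_expression",
    "te_fraction_per_cell",
    "read_matrix_dir",
    "read_cell_metadata",
    "read_bed",
    "read_gene_models",
    "read_gene_list",
    "read_gene_sets",
]

#: canonical TE class vocabulary
TE_CLASSES = ("SINE", "LINE", "LTR", "DNA", "other")

_CLASS_ALIASES = {
    "SINE": "SINE",
    "LINE": "LINE",
    "LTR": "LTR",
    "ERV": "LTR",
    "ERVK": "LTR",
    "ERVL": "LTR",
    "DNA": "DNA",
    "RC": "DNA",
}

CONDITIONS = ("AD", "control")


class TENameError(ValueError):
    """A TE feature name does not follow the locus-name grammar."""


@dataclass(frozen=True)
class TELocus:
    """A genomically anchored TE instance.

    ``te_class`` is normalized to one of :data:`TE_CLASSES`; ``start``/
    ``end`` are 0-based half-open base-pair coordinates.
    """

    chrom: str
    start: int
    end: int
    subfamily: str
    family: str
    te_class: str
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise TENameError(
                f"start >= end ({self.start} >= {self.end}) for {self.subfamily}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def name(self) -> str:
        return format_te_name(self)


def normalize_te_class(raw: str) -> str:
    """Map a RepeatMasker-style class label onto the canonical vocabulary."""
    base = raw.split("/")[0].rstrip("?")
    return _CLASS_ALIASES.get(base, "other")


def parse_te_name(name: str) -> TELocus:
    """Parse a locus-encoded TE feature name.

    Raises :class:`TENameError` naming the offending token on any
    malformed input.
    """
    parts = name.split("|")
    if len(parts) != 6 or parts[0] != "TE":
        raise TENameError(f"not a TE locus name (expected 6 '|' fields): {name!r}")
    _, chrom, start_s, end_s, tax, strand = parts
    if not chrom:
        raise TENameError(f"empty chromosome in {name!r}")
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise TENameError(f"non-integer coordinate {start_s!r}/{end_s!r} in {name!r}") from exc
    if start < 0:
        raise TENameError(f"negative start {start} in {name!r}")
    tax_parts = tax.split(":")
    if len(tax_parts) != 3 or not tax_parts[0]:
        raise TENameError(f"bad subfamily:family:class token {tax!r} in {name!r}")
    subfamily, family, te_class = tax_parts
    if strand not in ("+", "-", "."):
        raise TENameError(f"bad strand {strand!r} in {name!r}")
    return TELocus(chrom, start, end, subfamily, family, normalize_te_class(te_class), strand)


def format_te_name(locus: TELocus) -> str:
    """Inverse of :func:`parse_te_name` (round-trips exactly)."""
    return (
        f"TE|{locus.chrom}|{locus.start}|{locus.end}|"
        f"{locus.subfamily}:{locus.family}:{locus.te_class}|{locus.strand}"
    )


@dataclass
class ExpressionMatrix:
    """Sparse features x cells count matrix with per-feature kind flags.

    ``kind`` is ``"TE"`` for locus-level TE features (name parses under
    the TE grammar) and ``"gene"`` otherwise.
    """

    counts: sp.csr_matrix
    feature_ids: pd.Index
    kind: np.ndarray  # "gene" | "TE", parallel to feature_ids
    cell_ids: pd.Index

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.feature_ids = pd.Index(self.feature_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        self.kind = np.asarray(self.kind, dtype=object)
        if self.counts.shape != (len(self.feature_ids), len(self.cell_ids)):
            raise ValueError("counts shape does not match feature/cell ids")
        if len(self.kind) != len(self.feature_ids):
            raise ValueError("kind flags do not match features")
        if not self.feature_ids.is_unique:
            raise ValueError("duplicate feature ids")
        if not self.cell_ids.is_unique:
            raise ValueError("duplicate cell ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @classmethod
    def from_counts(cls, counts, feature_ids, cell_ids) -> "ExpressionMatrix":
        """Build a matrix, inferring feature kinds from the TE name grammar."""
        kind = np.array(
            ["TE" if str(f).startswith("TE|") else "gene" for f in feature_ids],
            dtype=object,
        )
        return cls(sp.csr_matrix(counts), pd.Index(feature_ids), kind, pd.Index(cell_ids))

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def te_loci(self) -> list[TELocus]:
        """Parse every TE feature name into a :class:`TELocus`."""
        return [parse_te_name(f) for f in self.feature_ids[self.kind == "TE"]]

    def subset_features(self, mask) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return ExpressionMatrix(
            self.counts[mask], self.feature_ids[mask], self.kind[mask], self.cell_ids
        )

    def subset_cells(self, mask) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return ExpressionMatrix(
            self.counts[:, mask], self.feature_ids, self.kind, self.cell_ids[mask]
        )


def filter_low_expression(matrix: ExpressionMatrix, min_cells: int = 10) -> ExpressionMatrix:
    """Drop features detected (count > 0) in fewer than ``min_cells`` cells.

    Applied uniformly to genes and TE loci.  Idempotent; raising
    ``min_cells`` never adds features back.  Cells are untouched.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    n_detected = (matrix.counts > 0).sum(axis=1).A1
    keep = n_detected >= min_cells
    if not keep.any():
        warnings.warn("low-expression filter removed every feature", stacklevel=2)
    return matrix.subset_features(keep)


def te_fraction_per_cell(matrix: ExpressionMatrix) -> pd.Series:
    """Percentage of each cell's total counts that comes from TE features.

    Cells with zero total counts get NaN (undefined, flagged by the
    caller via ``isna``).
    """
    total = np.asarray(matrix.counts.sum(axis=0)).ravel()
    te_total = np.asarray(matrix.counts[matrix.kind == "TE"].sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, 100.0 * te_total / total, np.nan)
    return pd.Series(frac, index=matrix.cell_ids, name="te_fraction_pct")


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def read_matrix_dir(path) -> ExpressionMatrix:
    """Read an MTX triplet directory (matrix.mtx, features.tsv, barcodes.tsv)."""
    path = Path(path)
    counts = sp.csr_matrix(mmread(path / "matrix.mtx"))
    features = pd.read_csv(path / "features.tsv", sep="\t")
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
    return ExpressionMatrix(
        counts,
        pd.Index(features["feature_id"]),
        features["kind"].to_numpy(dtype=object),
        pd.Index(barcodes),
    )


REQUIRED_META_COLUMNS = ("cell_id", "sample_id", "condition", "cell_type")


def read_cell_metadata(path) -> pd.DataFrame:
    """Read per-cell annotations; rejects duplicate cell ids and unknown conditions."""
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"cell metadata missing columns: {missing}")
    if meta["cell_id"].duplicated().any():
        dups = meta.loc[meta["cell_id"].duplicated(), "cell_id"].head(3).tolist()
        raise ValueError(f"duplicate cell ids in metadata, e.g. {dups}")
    bad = set(meta["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition labels {sorted(bad)}; expected {CONDITIONS}")
    return meta


def read_bed(path) -> pd.DataFrame:
    """Read a BED6 (or BED3/4) file into a DataFrame (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"BED interval with start >= end in {path}")
    return df


def read_gene_models(path) -> pd.DataFrame:
    """Read gene models (TSV: gene_id, chrom, start, end, strand, tss)."""
    genes = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "start", "end", "strand", "tss"]
    missing = [c for c in required if c not in genes.columns]
    if missing:
        raise ValueError(f"gene models missing columns: {missing}")
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in gene models")
    return genes


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_gene_sets(path) -> dict[str, list[str]]:
    """JSON map of set name -> gene symbols."""
    import json

    with open(path) as fh:
        sets = json.load(fh)
    if not isinstance(sets, dict):
        raise ValueError("gene-set collection must be a JSON object")
    return {str(k): [str(g) for g in v] for k, v in sets.items()}
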