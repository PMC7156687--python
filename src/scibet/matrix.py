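"""Expression-matrix containers, readers/writers, normalization and gene alignment.

The canonical in-memory object is :class:`ExpressionMatrix`: a dense
genes × cells matrix with unique row/column names and an explicit ``state``
flag that records whether values are raw counts or log-normalized expression
(``ln(1 + x)``).  All downstream steps (marker selection, training,
prediction) assume the log-normalized state; the two normalizers here produce
it from raw counts.  Natural logarithms are used throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "MatrixState",
    "ExpressionMatrix",
    "LabelVector",
    "OrthologTable",
    "GeneAlignment",
    "ValidationError",
    "MatrixFormatError",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "read_ortholog_table",
    "normalize_umi",
    "normalize_tpm",
    "align_genes",
    "map_orthologs",
]


class ValidationError(ValueError):
    """An input violates a documented invariant (names, shapes, signs)."""


class MatrixFormatError(ValueError):
    """A file could not be parsed as the declared matrix format."""


class MatrixState(str, Enum):
    RAW_COUNTS = "raw_counts"
    NORMALIZED_LOG = "normalized_log"


def _check_unique(names: Sequence[str], what: str) -> None:
    seen = pd.Index(names)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """Dense genes × cells expression matrix with named axes.

    Parameters
    ----------
    gene_names, cell_names
        Unique row and column identifiers (exact, case-sensitive matching).
    values
        Non-negative float matrix of shape ``(n_genes, n_cells)``.
    state
        ``RAW_COUNTS`` or ``NORMALIZED_LOG`` (values are ``ln(1+x)``).
    """

    gene_names: list[str]
    cell_names: list[str]
    values: np.ndarray
    state: MatrixState = MatrixState.RAW_COUNTS

    def __post_init__(self) -> None:
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_names = [str(c) for c in self.cell_names]
        self.values = np.asarray(self.values, dtype=np.float64)
        self.state = MatrixState(self.state)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D genes × cells matrix")
        if self.values.shape != (len(self.gene_names), len(self.cell_names)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_names)} genes × {len(self.cell_names)} cells"
            )
        _check_unique(self.gene_names, "gene names")
        _check_unique(self.cell_names, "cell names")
        if not np.isfinite(self.values).all():
            raise ValidationError("values contain NaN or infinite entries")
        if (self.values < 0).any():
            raise ValidationError("values contain negative entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_cells(self) -> int:
        return len(self.cell_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_names, columns=self.cell_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, state: MatrixState = MatrixState.RAW_COUNTS) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=np.float64), state)

    def select_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = pd.Index(self.gene_names).get_indexer(list(genes))
        if (idx < 0).any():
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise ValidationError(f"genes not in matrix: {missing[:10]}")
        return replace(self, gene_names=list(genes), values=self.values[idx, :])

    def select_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        idx = pd.Index(self.cell_names).get_indexer(list(cells))
        if (idx < 0).any():
            missing = [c for c, i in zip(cells, idx) if i < 0]
            raise ValidationError(f"cells not in matrix: {missing[:10]}")
        return replace(self, cell_names=list(cells), values=self.values[:, idx])


@dataclass
class LabelVector:
    """Per-cell type labels, parallel to ``cell_names``."""

    cell_names: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.cell_names = [str(c) for c in self.cell_names]
        self.labels = [str(l) for l in self.labels]
        if len(self.cell_names) != len(self.labels):
            raise ValidationError(
                f"{len(self.labels)} labels for {len(self.cell_names)} cells"
            )
        _check_unique(self.cell_names, "cell names")
        if any(l == "" for l in self.labels):
            raise ValidationError("empty label encountered")

    def __len__(self) -> int:
        return len(self.cell_names)

    @property
    def type_names(self) -> list[str]:
        return sorted(set(self.labels))

    def labels_for(self, m: ExpressionMatrix) -> np.ndarray:
        """Labels reordered to ``m``'s cell order; every cell must be labeled."""
        s = pd.Series(self.labels, index=self.cell_names)
        missing = [c for c in m.cell_names if c not in s.index]
        if missing:
            raise ValidationError(f"cells without a label: {missing[:10]}")
        return s.reindex(m.cell_names).to_numpy()

    def subset(self, cells: Sequence[str]) -> "LabelVector":
        s = pd.Series(self.labels, index=self.cell_names)
        return LabelVector(list(cells), list(s.reindex(list(cells))))


@dataclass
class OrthologTable:
    """One-to-one source → target gene lookup (e.g. mouse → human symbols)."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        src = [p[0] for p in self.pairs]
        tgt = [p[1] for p in self.pairs]
        if len(set(src)) != len(src) or len(set(tgt)) != len(tgt):
            raise ValidationError("ortholog table is not one-to-one")

    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)


class GeneAlignment(NamedTuple):
    """align_genes result: the reordered matrix plus the missing-gene report."""

    matrix: ExpressionMatrix
    missing_fraction: float


# ---------------------------------------------------------------------------
# I/O

def _read_names(path: Path, what: str) -> list[str]:
    if not path.exists():
        raise MatrixFormatError(f"missing {what} sidecar file: {path}")
    names = [ln.split("\t")[0].strip() for ln in path.read_text().splitlines() if ln.strip()]
    return names


def read_matrix(
    path: str | Path,
    layout: str = "genes_in_rows",
    fmt: str | None = None,
    state: MatrixState = MatrixState.RAW_COUNTS,
) -> ExpressionMatrix:
    """Read a dense TSV/CSV table or a MatrixMarket triplet directory.

    Dense files: first column holds gene names (or cell names with
    ``layout="cells_in_rows"``), header row holds the other axis.  Sparse:
    ``path`` is a directory containing ``matrix.mtx`` with ``genes.tsv`` and
    ``barcodes.tsv`` name sidecars (10x-style).
    """
    path = Path(path)
    if layout not in ("genes_in_rows", "cells_in_rows"):
        raise ValidationError(f"unknown layout {layout!r}")
    if fmt is None:
        if path.is_dir():
            fmt = "mtx"
        elif path.suffix == ".csv":
            fmt = "csv"
        else:
            fmt = "tsv"
    if fmt == "mtx":
        mtx_path = path / "matrix.mtx" if path.is_dir() else path
        base = mtx_path.parent
        if not mtx_path.exists():
            raise MatrixFormatError(f"no matrix.mtx under {path}")
        try:
            mat = spio.mmread(mtx_path)
        except Exception as exc:  # scipy raises bare ValueError on bad headers
            raise MatrixFormatError(f"cannot parse {mtx_path}: {exc}") from exc
        values = np.asarray(sparse.coo_matrix(mat).todense(), dtype=np.float64)
        rows = _read_names(base / "genes.tsv", "gene-name")
        cols = _read_names(base / "barcodes.tsv", "cell-name")
        if layout == "cells_in_rows":
            values = values.T
            rows, cols = cols, rows
        if values.shape != (len(rows), len(cols)):
            raise ValidationError(
                f"mtx shape {values.shape} does not match sidecars "
                f"({len(rows)} genes, {len(cols)} cells)"
            )
        return ExpressionMatrix(rows, cols, values, state)
    if fmt not in ("tsv", "csv"):
        raise ValidationError(f"unknown format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    if not path.exists():
        raise MatrixFormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
        df = df.astype(np.float64)
    except (ValueError, pd.errors.ParserError) as exc:
        raise MatrixFormatError(f"cannot parse {path}: {exc}") from exc
    if layout == "cells_in_rows":
        df = df.T
    return ExpressionMatrix.from_frame(df, state)


def write_matrix(
    m: ExpressionMatrix,
    path: str | Path,
    layout: str = "genes_in_rows",
    fmt: str | None = None,
) -> None:
    """Inverse of :func:`read_matrix`; for ``mtx`` writes a triplet directory."""
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == "" else ("csv" if path.suffix == ".csv" else "tsv")
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.coo_matrix(m.values))
        (path / "genes.tsv").write_text("".join(f"{g}\n" for g in m.gene_names))
        (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_names))
        return
    df = m.to_frame()
    if layout == "cells_in_rows":
        df = df.T
    df.to_csv(path, sep="\t" if fmt == "tsv" else ",")


def read_labels(path: str | Path) -> LabelVector:
    """Two-column TSV ``cell<TAB>label`` with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise MatrixFormatError(f"label file {path} needs two columns")
    return LabelVector(list(df.iloc[:, 0]), list(df.iloc[:, 1]))


def write_labels(labels: LabelVector, path: str | Path) -> None:
    pd.DataFrame({"cell": labels.cell_names, "label": labels.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_ortholog_table(path: str | Path, header: bool = False) -> OrthologTable:
    """Two-column TSV of (source_gene, target_gene); no header by default."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=0 if header else None)
    if df.shape[1] < 2:
        raise MatrixFormatError(f"ortholog table {path} needs two columns")
    return OrthologTable([(a, b) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])])


# ---------------------------------------------------------------------------
# Normalization

def normalize_umi(raw: ExpressionMatrix, size_factor: float = 10_000.0) -> ExpressionMatrix:
    """Per-cell size-factor scaling followed by ``ln(1 + ·)``.

    Each cell's counts are scaled to a common library size (default 10,000),
    then log-transformed: ``v' = ln(1 + size_factor · x / colsum)``.
    """
    if raw.state is not MatrixState.RAW_COUNTS:
        raise ValidationError("normalize_umi expects raw counts")
    if size_factor <= 0:
        raise ValidationError("size_factor must be positive")
    totals = raw.values.sum(axis=0)
    bad = np.asarray(totals <= 0).nonzero()[0]
    if bad.size:
        names = [raw.cell_names[i] for i in bad[:10]]
        raise ValidationError(f"cells with zero total count: {names}")
    values = np.log1p(size_factor * raw.values / totals)
    return ExpressionMatrix(raw.gene_names, raw.cell_names, values, MatrixState.NORMALIZED_LOG)


def normalize_tpm(
    raw: ExpressionMatrix,
    gene_lengths: Mapping[str, float] | None = None,
) -> ExpressionMatrix:
    """Transcripts-per-million (length-normalized) then ``ln(1 + ·)``.

    For full-length protocols counts are first divided by gene length; without
    a length table the computation degrades to counts-per-million.  Each
    cell's rates are rescaled to sum to 10^6 before the log transform.
    """
    if raw.state is not MatrixState.RAW_COUNTS:
        raise ValidationError("normalize_tpm expects raw counts")
    if gene_lengths is not None:
        missing = [g for g in raw.gene_names if g not in gene_lengths]
        if missing:
            raise ValidationError(f"genes without a length: {missing[:10]}")
        lengths = np.array([float(gene_lengths[g]) for g in raw.gene_names])
        if (lengths <= 0).any():
            bad = [g for g, L in zip(raw.gene_names, lengths) if L <= 0]
            raise ValidationError(f"non-positive gene lengths: {bad[:10]}")
        rates = raw.values / lengths[:, None]
    else:
        rates = raw.values
    totals = rates.sum(axis=0)
    bad = np.asarray(totals <= 0).nonzero()[0]
    if bad.size:
        names = [raw.cell_names[i] for i in bad[:10]]
        raise ValidationError(f"cells with zero total rate: {names}")
    tpm = 1e6 * rates / totals
    return ExpressionMatrix(
        raw.gene_names, raw.cell_names, np.log1p(tpm), MatrixState.NORMALIZED_LOG
    )


# ---------------------------------------------------------------------------
# Gene-space alignment

def align_genes(reference_genes: Sequence[str], query: ExpressionMatrix) -> GeneAlignment:
    """Restrict/reorder a query to a reference gene list.

    Genes of the reference absent from the query become all-zero rows, so a
    stored model scores any query on exactly its own gene space.  The
    fraction of reference genes missing from the query is reported, with a
    warning above 20%.
    """
    reference_genes = [str(g) for g in reference_genes]
    _check_unique(reference_genes, "reference gene names")
    idx = pd.Index(query.gene_names).get_indexer(reference_genes)
    values = np.zeros((len(reference_genes), query.n_cells))
    present = idx >= 0
    values[present, :] = query.values[idx[present], :]
    missing_fraction = float((~present).mean()) if reference_genes else 0.0
    if missing_fraction > 0.2:
        warnings.warn(
            f"{missing_fraction:.1%} of reference genes are missing from the query",
            stacklevel=2,
        )
    aligned = ExpressionMatrix(reference_genes, list(query.cell_names), values, query.state)
    return GeneAlignment(aligned, missing_fraction)


def map_orthologs(m: ExpressionMatrix, table: OrthologTable) -> ExpressionMatrix:
    """Rename genes via a one-to-one ortholog table, keeping the intersection."""
    lookup = table.as_dict()
    keep = [g for g in m.gene_names if g in lookup]
    if not keep:
        warnings.warn("no genes shared with the ortholog table", stacklevel=2)
        return ExpressionMatrix([], list(m.cell_names), np.zeros((0, m.n_cells)), m.state)
    sub = m.select_genes(keep)
    return ExpressionMatrix(
        [lookup[g] for g in keep], sub.cell_names, sub.values, sub.state
    )
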