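"""Count-matrix containers and readers for standard single-cell formats.

Internal orientation is cells x genes (N x P).  Droplet pipelines ship
MatrixMarket triplets in genes x cells orientation; the reader transposes.
Files ending in ``.gz`` are decompressed transparently.  No reader or
writer ever filters cells or genes silently.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "CountMatrix",
    "FormatError",
    "StateError",
    "read_counts_mtx",
    "read_counts_dense",
    "write_counts_dense",
    "write_counts_mtx",
    "log_normalize",
    "nonzero_fractions",
]


class FormatError(ValueError):
    """Malformed input file."""


class StateError(RuntimeError):
    """Operation invalid for the matrix's current state."""


@dataclass
class CountMatrix:
    """Cells x genes expression values with identifiers.

    ``values`` may be dense (ndarray) or sparse (scipy CSR); zeros are
    implicit in the sparse case.  ``normalized`` records whether a log
    transform has been applied ("none", "log2" or "log10").
    """

    values: np.ndarray | sp.spmatrix
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    normalized: str = "none"

    def __post_init__(self):
        if sp.issparse(self.values):
            self.values = sp.csr_matrix(self.values)
        else:
            self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell_{i}" for i in range(n)]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j}" for j in range(p)]
        if len(self.cell_ids) != n or len(self.gene_ids) != p:
            raise FormatError(
                f"id/dimension mismatch: matrix is {n} cells x {p} genes but "
                f"{len(self.cell_ids)} cell ids and {len(self.gene_ids)} gene ids given"
            )
        if len(set(self.cell_ids)) != n or len(set(self.gene_ids)) != p:
            raise FormatError("cell or gene identifiers are not unique")
        if self.min() < 0:
            raise FormatError("negative expression values are not allowed")
        if self.normalized not in ("none", "log2", "log10"):
            raise FormatError(f"unknown normalization state {self.normalized!r}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def min(self) -> float:
        return float(self.values.min()) if self.values.size else 0.0

    def to_dense(self) -> np.ndarray:
        return self.values.toarray() if sp.issparse(self.values) else self.values


def _open_maybe_gz(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_id_file(path) -> list[str]:
    with _open_maybe_gz(path) as fh:
        # 10x feature files are TSV (id, name, type); take the first column
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts_mtx(matrix_path, features_path, barcodes_path) -> CountMatrix:
    """Read a 10x-style MatrixMarket triplet as a cells x genes CountMatrix.

    The on-disk matrix is genes x cells with 1-based coordinates (the
    MatrixMarket convention); it is transposed to the in-memory cells x
    genes, 0-based convention.
    """
    with _open_maybe_gz(matrix_path, "rb") as fh:
        M = mmread(fh)
    genes = _read_id_file(features_path)
    cells = _read_id_file(barcodes_path)
    n_genes, n_cells = M.shape
    if len(genes) != n_genes:
        raise FormatError(
            f"features file lists {len(genes)} genes but matrix has {n_genes} rows "
            "(genes x cells on disk)"
        )
    if len(cells) != n_cells:
        raise FormatError(
            f"barcodes file lists {len(cells)} cells but matrix has {n_cells} columns "
            "(genes x cells on disk)"
        )
    M = sp.csr_matrix(M.T)
    if M.nnz and M.data.min() < 0:
        raise FormatError("matrix contains negative entries")
    return CountMatrix(values=M, cell_ids=cells, gene_ids=genes)


def read_counts_dense(path, delimiter: str = "\t") -> CountMatrix:
    """Read a dense table: first row gene ids, first column cell ids."""
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except pd.errors.ParserError as err:
        raise FormatError(f"malformed dense count table {path}: {err}") from err
    bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
    if len(bad):
        raise FormatError(f"non-numeric values in gene column(s) {list(bad)[:5]}")
    return CountMatrix(
        values=df.to_numpy(dtype=float),
        cell_ids=[str(c) for c in df.index],
        gene_ids=[str(g) for g in df.columns],
    )


def write_counts_dense(counts: CountMatrix, path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(counts.to_dense(), index=counts.cell_ids, columns=counts.gene_ids)
    df.to_csv(path, sep=delimiter)


def write_counts_mtx(counts: CountMatrix, matrix_path, features_path, barcodes_path) -> None:
    """Write genes x cells MatrixMarket plus id files (10x layout)."""
    M = sp.coo_matrix(
        counts.values.T if sp.issparse(counts.values) else sp.csr_matrix(counts.values).T
    )
    with open(matrix_path, "wb") as fh:
        mmwrite(fh, M)
    Path(features_path).write_text("".join(f"{g}\n" for g in counts.gene_ids))
    Path(barcodes_path).write_text("".join(f"{c}\n" for c in counts.cell_ids))


def log_normalize(counts: CountMatrix, base: int = 10) -> CountMatrix:
    """Entrywise log_base(1 + y); preserves the sparsity pattern exactly."""
    if counts.normalized != "none":
        raise StateError(f"matrix is already {counts.normalized}-normalized")
    if base not in (2, 10):
        raise ValueError("base must be 2 or 10")
    denom = np.log(base)
    if sp.issparse(counts.values):
        out = counts.values.copy()
        out.data = np.log1p(out.data) / denom
    else:
        out = np.log1p(counts.values) / denom
    return CountMatrix(
        values=out,
        cell_ids=list(counts.cell_ids),
        gene_ids=list(counts.gene_ids),
        normalized=f"log{base}",
    )


def nonzero_fractions(counts: CountMatrix) -> np.ndarray:
    """Fraction of cells in which each gene is expressed (value > 0)."""
    values = counts.values
    if sp.issparse(values):
        frac = np.asarray((values > 0).sum(axis=0)).ravel() / values.shape[0]
    else:
        frac = (values > 0).mean(axis=0)
    return np.asarray(frac, dtype=float)
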