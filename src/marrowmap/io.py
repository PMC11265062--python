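"""Reading, writing and QC of single-cell count matrices.

Counts are held gene x cell (rows = genes), matching the 10x MatrixMarket
triplet convention. Supported on-disk formats: a 10x-style directory
(matrix.mtx(.gz) + barcodes.tsv(.gz) + features.tsv(.gz)) and dense
delimited gene x cell tables with a header row of barcodes.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "QCReport",
    "FormatError",
    "EmptyAfterQCError",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_dense",
    "write_dense",
    "qc_filter",
    "normalize_log1p",
    "dedupe_symbols",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


class EmptyAfterQCError(ValueError):
    """Raised when QC filtering removes every cell."""


def dedupe_symbols(symbols: list[str]) -> list[str]:
    """Make gene symbols unique by suffixing duplicates with .1, .2, ...

    The first occurrence keeps its name, mirroring the 10x/Seurat
    convention of preserving feature count rather than summing collisions.
    """
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


@dataclass
class CountMatrix:
    """Sparse gene x cell matrix of non-negative integer counts."""

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix  # genes x cells
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.nnz:
            data = self.counts.data
            if data.min() < 0:
                raise FormatError("negative count entry")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer count entry")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene symbols after dedup policy")
        if len(set(self.cells)) != len(self.cells):
            raise FormatError("duplicate cell barcodes")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def total(self) -> int:
        return int(self.counts.sum())

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.genes == other.genes
            and self.cells == other.cells
            and (self.counts != other.counts).nnz == 0
        )


@dataclass
class QCReport:
    """Provenance record of a qc_filter run (thresholds + removals)."""

    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    min_genes_per_cell: int
    max_mito_fraction: float
    min_cells_per_gene: int
    mito_prefix: str = "MT-"
    n_cells_low_genes: int = 0
    n_cells_high_mito: int = 0

    def __post_init__(self) -> None:
        assert self.n_cells_out <= self.n_cells_in
        assert self.n_genes_out <= self.n_genes_in


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FileNotFoundError(f"missing {stem}(.gz) in {dir_path}")


def _read_lines(path: Path) -> list[str]:
    with _open_maybe_gz(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def _feature_symbol(line: str) -> str:
    """Symbol from a features.tsv row: 1-col = symbol; 2-col = (id, symbol);
    3-col 10x dialect = (id, symbol, type) -> take the last non-type column."""
    cols = line.split("\t")
    if len(cols) == 1:
        return cols[0]
    if len(cols) == 2:
        return cols[1]
    return cols[-2]


def read_mtx_triplet(dir_path: str | Path, sample_id: str | None = None) -> CountMatrix:
    """Read a 10x-style MTX triplet directory into a CountMatrix.

    MTX rows are genes, columns are cells (1-based coordinate format).
    Duplicate gene symbols are made unique by numeric suffixing.
    """
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, "matrix.mtx")
    barcodes_path = _find(dir_path, "barcodes.tsv")
    features_path = _find(dir_path, "features.tsv")

    with _open_maybe_gz(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    barcodes = _read_lines(barcodes_path)
    symbols = [_feature_symbol(ln) for ln in _read_lines(features_path)]

    if mat.shape[0] != len(symbols):
        raise FormatError(
            f"MTX header says {mat.shape[0]} genes but features.tsv has "
            f"{len(symbols)} lines"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"MTX header says {mat.shape[1]} cells but barcodes.tsv has "
            f"{len(barcodes)} lines"
        )
    return CountMatrix(
        genes=dedupe_symbols(symbols),
        cells=barcodes,
        counts=sp.csr_matrix(mat),
        sample_id=sample_id or dir_path.name,
    )


def write_mtx_triplet(cm: CountMatrix, dir_path: str | Path) -> None:
    """Write a CountMatrix as matrix.mtx + barcodes.tsv + features.tsv.

    The features file uses the 3-column 10x dialect (id, symbol, type).
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(cm.counts)
    scipy.io.mmwrite(
        str(dir_path / "matrix.mtx"), coo, field="integer"
    )
    (dir_path / "barcodes.tsv").write_text("\n".join(cm.cells) + "\n")
    (dir_path / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in cm.genes)
    )


def read_dense(path: str | Path, delimiter: str = "\t",
               sample_id: str | None = None) -> CountMatrix:
    """Read a dense gene x cell table (header = barcodes, first column = symbols)."""
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    values = df.to_numpy()
    if values.size and (not np.issubdtype(values.dtype, np.number)
                        or np.any(values != np.floor(values))):
        raise FormatError("dense table contains non-integer entries")
    if values.size and values.min() < 0:
        raise FormatError("dense table contains negative entries")
    return CountMatrix(
        genes=dedupe_symbols([str(g) for g in df.index]),
        cells=[str(c) for c in df.columns],
        counts=sp.csr_matrix(values.astype(np.int64)),
        sample_id=sample_id or path.stem,
    )


def write_dense(cm: CountMatrix, path: str | Path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(
        cm.counts.toarray(), index=cm.genes, columns=cm.cells, dtype=np.int64
    )
    df.to_csv(path, sep=delimiter)


def qc_filter(
    cm: CountMatrix,
    min_genes_per_cell: int = 200,
    max_mito_fraction: float = 0.15,
    min_cells_per_gene: int = 3,
    mito_prefix: str = "MT-",
) -> tuple[CountMatrix, QCReport]:
    """Two-stage QC: drop poor cells first, then rarely detected genes.

    Stage 1 removes cells with fewer than ``min_genes_per_cell`` detected
    genes or with a mitochondrial count fraction above ``max_mito_fraction``
    (mitochondrial genes identified by symbol prefix). Stage 2 removes genes
    detected in fewer than ``min_cells_per_gene`` of the remaining cells.
    """
    X = sp.csc_matrix(cm.counts)
    detected = np.asarray((X > 0).sum(axis=0)).ravel()
    totals = np.asarray(X.sum(axis=0)).ravel()
    mito_mask = np.array([g.startswith(mito_prefix) for g in cm.genes])
    mito_counts = (
        np.asarray(X[mito_mask].sum(axis=0)).ravel()
        if mito_mask.any() else np.zeros_like(totals, dtype=float)
    )
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    low_genes = detected < min_genes_per_cell
    high_mito = mito_frac > max_mito_fraction
    keep_cells = ~(low_genes | high_mito)
    if not keep_cells.any():
        raise EmptyAfterQCError("all cells removed: empty after QC")

    X = X[:, keep_cells]
    genes_detected_in = np.asarray((X > 0).sum(axis=1)).ravel()
    keep_genes = genes_detected_in >= min_cells_per_gene

    out = CountMatrix(
        genes=[g for g, k in zip(cm.genes, keep_genes) if k],
        cells=[c for c, k in zip(cm.cells, keep_cells) if k],
        counts=sp.csr_matrix(X[keep_genes]),
        sample_id=cm.sample_id,
    )
    report = QCReport(
        n_cells_in=cm.n_cells,
        n_cells_out=out.n_cells,
        n_genes_in=cm.n_genes,
        n_genes_out=out.n_genes,
        min_genes_per_cell=min_genes_per_cell,
        max_mito_fraction=max_mito_fraction,
        min_cells_per_gene=min_cells_per_gene,
        mito_prefix=mito_prefix,
        n_cells_low_genes=int(low_genes.sum()),
        n_cells_high_mito=int(high_mito.sum()),
    )
    return out, report


def normalize_log1p(cm: CountMatrix, target_sum: float = 1e4) -> sp.csr_matrix:
    """Library-size normalization followed by log1p (LogNormalize).

    Per cell j: value_gj = ln(1 + count_gj / colsum_j * target_sum).
    Returns a sparse gene x cell float matrix; zero counts stay exactly 0.
    """
    colsums = np.asarray(cm.counts.sum(axis=0)).ravel()
    if np.any(colsums == 0):
        raise ValueError("cell with zero total count cannot be normalized")
    X = sp.csc_matrix(cm.counts, copy=True).astype(np.float64)
    X = X @ sp.diags(target_sum / colsums)
    return sp.csr_matrix(X.log1p())
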