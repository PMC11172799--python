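"""Readers and writers for count matrices, labels and edge lists.

Dense input is CSV/TSV with a header row of gene ids and a first column of
cell ids (orientation must be stated explicitly, never guessed).  Sparse
input is MatrixMarket plus two one-column sidecar files with cell and gene
ids.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread

from .cell_graph import CellGraph
from .preprocessing import CountMatrix, NormalizedMatrix

__all__ = [
    "read_counts_csv",
    "read_counts_mtx",
    "write_counts_csv",
    "write_matrix_csv",
    "read_labels_csv",
    "write_labels_csv",
    "write_edge_list",
]


def read_counts_csv(path: str | Path, cells_in_rows: bool, sep: str = ",") -> CountMatrix:
    """Read a dense counts table; ``cells_in_rows`` states the orientation."""
    df = pd.read_csv(path, index_col=0, sep=sep)
    if not cells_in_rows:
        df = df.T
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries in counts table")
    return CountMatrix(
        counts=np.asarray(np.rint(counts), dtype=np.int64),
        cell_ids=[str(c) for c in df.index],
        gene_ids=[str(g) for g in df.columns],
    )


def read_counts_mtx(
    mtx_path: str | Path,
    cells_path: str | Path,
    genes_path: str | Path,
    cells_in_rows: bool = True,
) -> CountMatrix:
    """Read MatrixMarket counts with one-column cell/gene id sidecars."""
    M = mmread(str(mtx_path))
    M = M.toarray() if sparse.issparse(M) else np.asarray(M)
    if not cells_in_rows:
        M = M.T
    cells = Path(cells_path).read_text().split()
    genes = Path(genes_path).read_text().split()
    return CountMatrix(
        counts=np.asarray(np.rint(M), dtype=np.int64), cell_ids=cells, gene_ids=genes
    )


def write_counts_csv(X: CountMatrix, path: str | Path) -> None:
    pd.DataFrame(X.counts, index=X.cell_ids, columns=X.gene_ids).to_csv(path)


def write_matrix_csv(
    M: np.ndarray | NormalizedMatrix, path: str | Path,
    index: list[str] | None = None, columns: list[str] | None = None,
) -> None:
    if isinstance(M, NormalizedMatrix):
        index, columns, M = M.cell_ids, M.kept_gene_ids, M.values
    pd.DataFrame(M, index=index, columns=columns).to_csv(path)


def read_labels_csv(path: str | Path) -> np.ndarray:
    """One-column labels CSV (with or without a cell-id index column)."""
    df = pd.read_csv(path)
    return df.iloc[:, -1].to_numpy()


def write_labels_csv(labels: np.ndarray, cell_ids: list[str], path: str | Path) -> None:
    pd.DataFrame({"cell_id": cell_ids, "label": np.asarray(labels)}).to_csv(
        path, index=False
    )


def write_edge_list(G: CellGraph, path: str | Path) -> None:
    """Two-column text file of 0-based node indices, one edge per line."""
    np.savetxt(path, G.edge_list(), fmt="%d")
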