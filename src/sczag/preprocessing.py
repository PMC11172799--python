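"""Count-matrix preprocessing: gene filtering, median-library normalization, HVG selection.

The pipeline mirrors standard scRNA-seq practice: drop genes detected in too
few cells, normalize each cell to the median library size and log-transform,
then keep the top highly variable genes by Seurat-style normalized dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "filter_genes",
    "normalize_counts",
    "select_hvg",
]


@dataclass
class CountMatrix:
    """Raw cell x gene count matrix with aligned id lists."""

    counts: np.ndarray  # (n_cells, n_genes), nonnegative integers
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D cell x gene matrix")
        n, g = self.counts.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError("id lists do not match matrix dimensions")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class NormalizedMatrix:
    """Log-scale normalized expression (cells x kept genes).

    ``median_total`` is the median per-cell library size m(X) used as the
    common scale factor.
    """

    values: np.ndarray
    median_total: float
    kept_gene_ids: list[str]
    cell_ids: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def filter_genes(X: CountMatrix, min_cell_fraction: float = 0.01) -> CountMatrix:
    """Keep genes with nonzero expression in at least ``min_cell_fraction`` of cells.

    Never-expressed genes are always dropped.  The cell set is unchanged.
    """
    if not 0.0 <= min_cell_fraction <= 1.0:
        raise ValueError("min_cell_fraction must lie in [0, 1]")
    detected = (X.counts > 0).sum(axis=0)
    keep = (detected > 0) & (detected >= min_cell_fraction * X.n_cells)
    if not keep.any():
        raise ValueError("no genes survive filtering")
    return CountMatrix(
        counts=X.counts[:, keep],
        cell_ids=list(X.cell_ids),
        gene_ids=[g for g, k in zip(X.gene_ids, keep) if k],
    )


def normalize_counts(X: CountMatrix) -> NormalizedMatrix:
    """Median-of-totals normalization followed by log1p.

    Each entry becomes ``ln(1 + m(X) * x_ij / sum_o x_io)`` where m(X) is the
    median per-cell total count.  Zero counts map to exactly 0 and all entries
    are finite and nonnegative.
    """
    totals = X.counts.sum(axis=1).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell {X.cell_ids[zero[0]]!r} has zero total count")
    m = float(np.median(totals))
    values = np.log1p(m * X.counts / totals[:, None])
    return NormalizedMatrix(
        values=values,
        median_total=m,
        kept_gene_ids=list(X.gene_ids),
        cell_ids=list(X.cell_ids),
    )


def _normalized_dispersion(values: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Seurat-flavor normalized dispersion of log-scale expression.

    Genes are binned by mean expression; within each bin the dispersion
    (variance/mean on the expm1 scale) is z-scored.  Matches the statistic
    scanpy computes for ``flavor="seurat"``.
    """
    X = np.expm1(values)
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    df = pd.DataFrame({"mean": mean, "disp": np.log1p(dispersion)})
    df["mean"] = np.log1p(df["mean"])
    df["bin"] = pd.cut(df["mean"], bins=n_bins, duplicates="drop")
    grouped = df.groupby("bin", observed=True)["disp"]
    bin_mean = grouped.transform("mean")
    bin_std = grouped.transform("std")
    # singleton bins have undefined std; fall back to the bin mean (z = 0)
    bin_std = bin_std.fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (df["disp"] - bin_mean) / bin_std.replace(0.0, np.inf)
    out = np.nan_to_num(z.to_numpy(), nan=-np.inf)
    out[dispersion == 0] = -np.inf  # constant genes always rank last
    return out


def select_hvg(Xn: NormalizedMatrix, n_top: int = 500) -> NormalizedMatrix:
    """Retain exactly ``n_top`` genes with the highest normalized dispersion.

    Ties are broken by gene index (earlier genes win) so selection is
    deterministic; gene order is preserved in the output.
    """
    n_genes = Xn.n_genes
    if n_top > n_genes:
        raise ValueError(f"n_top={n_top} exceeds gene count {n_genes}")
    if n_top < 1:
        raise ValueError("n_top must be positive")
    z = _normalized_dispersion(Xn.values)
    # stable sort on descending dispersion => ties resolved by gene index
    order = np.argsort(-z, kind="stable")[:n_top]
    keep = np.zeros(n_genes, dtype=bool)
    keep[order] = True
    return NormalizedMatrix(
        values=Xn.values[:, keep],
        median_total=Xn.median_total,
        kept_gene_ids=[g for g, k in zip(Xn.kept_gene_ids, keep) if k],
        cell_ids=list(Xn.cell_ids),
    )
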