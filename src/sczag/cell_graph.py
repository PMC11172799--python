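"""KNN cell graph construction and its symmetrically normalized adjacency."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .preprocessing import NormalizedMatrix

__all__ = ["CellGraph", "NormalizedAdjacency", "build_knn_graph", "normalize_adjacency"]


@dataclass
class CellGraph:
    """Undirected unit-weight graph over cells.

    ``adjacency`` is a dense symmetric 0/1 matrix without self-loops;
    ``edges`` the corresponding set of unordered index pairs.
    """

    n_nodes: int
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("adjacency shape does not match n_nodes")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("self-loops are not allowed")
        self.adjacency = A

    @property
    def edges(self) -> set[tuple[int, int]]:
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return {(int(i), int(j)) for i, j in zip(iu, ju)}

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def edge_list(self) -> np.ndarray:
        """Edges as an (n_edges, 2) array of 0-based node indices, u < v."""
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return np.column_stack([iu, ju])


@dataclass
class NormalizedAdjacency:
    """Symmetric renormalized adjacency D~^(-1/2) (A + I) D~^(-1/2)."""

    matrix: np.ndarray


def build_knn_graph(Xn: NormalizedMatrix | np.ndarray, k: int = 15) -> CellGraph:
    """Union-symmetrized K-nearest-neighbor graph under Euclidean distance.

    Each cell lists its ``k`` nearest other cells; an undirected unit edge is
    placed whenever either endpoint lists the other.  Distance ties at the
    k-th neighbor are broken toward the smaller cell index.
    """
    X = Xn.values if isinstance(Xn, NormalizedMatrix) else np.asarray(Xn, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    n = X.shape[0]
    if k < 1 or k >= n:
        raise ValueError(f"k must satisfy 1 <= k < n_cells, got k={k}, n={n}")
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    # stable argsort on distance: equal distances resolve to the smaller index
    nn = np.argsort(D, axis=1, kind="stable")[:, :k]
    A = np.zeros((n, n), dtype=np.int8)
    rows = np.repeat(np.arange(n), k)
    A[rows, nn.ravel()] = 1
    A = np.maximum(A, A.T)  # union symmetrization
    return CellGraph(n_nodes=n, adjacency=A)


def normalize_adjacency(G: CellGraph) -> NormalizedAdjacency:
    """Self-looped symmetric normalization: A^ = D~^(-1/2) (A + I) D~^(-1/2).

    The added self-loops guarantee positive degrees, and the spectrum of A^
    lies in [-1, 1].
    """
    A_tilde = G.adjacency.astype(float) + np.eye(G.n_nodes)
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return NormalizedAdjacency(matrix=A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :])
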