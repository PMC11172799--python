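import numpy as np
import pytest

from sczag.cell_graph import CellGraph
from sczag.preprocessing import CountMatrix


def make_counts(counts) -> CountMatrix:
    counts = np.asarray(counts)
    return CountMatrix(
        counts=counts,
        cell_ids=[f"c{i}" for i in range(counts.shape[0])],
        gene_ids=[f"g{j}" for j in range(counts.shape[1])],
    )


def graph_from_edges(n: int, edges) -> CellGraph:
    A = np.zeros((n, n), dtype=np.int8)
    for u, v in edges:
        A[u, v] = A[v, u] = 1
    return CellGraph(n_nodes=n, adjacency=A)


def random_graph(n: int, p: float, seed: int) -> CellGraph:
    """Erdos-Renyi graph, re-drawn until no node is isolated."""
    rng = np.random.default_rng(seed)
    while True:
        A = (rng.random((n, n)) < p).astype(np.int8)
        A = np.triu(A, k=1)
        A = A + A.T
        if A.sum(axis=1).min() > 0:
            return CellGraph(n_nodes=n, adjacency=A)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
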