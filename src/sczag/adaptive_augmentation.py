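"""Centrality-adaptive graph augmentation: biased edge dropping and feature masking.

Two stochastic views of the cell graph are drawn per training iteration.
Edges between low-centrality cells and feature dimensions concentrated in
low-centrality cells are perturbed with higher probability, so each view
keeps the structural backbone of the graph while discarding peripheral
detail.  Node importance is PageRank centrality on the bidirected graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell_graph import CellGraph

__all__ = [
    "AugmentationConfig",
    "CentralityScores",
    "EdgeDropProbabilities",
    "FeatureMaskProbabilities",
    "AugmentedView",
    "pagerank_centrality",
    "edge_centrality",
    "edge_drop_probabilities",
    "sample_edge_view",
    "feature_dim_weights",
    "feature_mask_probabilities",
    "sample_feature_mask",
    "make_views",
]

_W_FLOOR = 1e-12  # all-zero feature columns get log(floor), i.e. max masking


@dataclass
class AugmentationConfig:
    """Per-view perturbation strengths and shared truncation/damping.

    ``p_e*`` govern the overall edge-removal rate of each view, ``p_f*`` the
    feature-masking rate; ``p_tau`` truncates every individual probability.
    """

    damping: float = 0.85
    p_e1: float = 0.3
    p_e2: float = 0.4
    p_f1: float = 0.1
    p_f2: float = 0.2
    p_tau: float = 0.7


@dataclass
class CentralityScores:
    sigma: np.ndarray  # >= 1, one per node
    damping: float


@dataclass
class EdgeDropProbabilities:
    edges: np.ndarray  # (n_edges, 2), u < v
    p_edge: np.ndarray  # aligned with edges, each in [0, p_tau]
    p_e: float
    p_tau: float


@dataclass
class FeatureMaskProbabilities:
    p_dim: np.ndarray  # per feature dimension, each in [0, p_tau]
    p_f: float
    p_tau: float


@dataclass
class AugmentedView:
    adjacency: np.ndarray
    features: np.ndarray
    mask: np.ndarray  # 0/1 per feature dimension
    rng_seed: int = 0


def pagerank_centrality(
    G: CellGraph,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> CentralityScores:
    """Unnormalized PageRank scores solving sigma = a * A D^-1 sigma + 1.

    The undirected graph is treated as bidirected (each edge contributes a
    directed edge both ways), so D is the out-degree diagonal.  Fixed-point
    iteration converges geometrically at rate ``damping``; all scores are
    >= 1 by construction.
    """
    if not 0.0 < damping < 1.0:
        raise ValueError("damping must lie in (0, 1)")
    deg = G.degrees.astype(float)
    if np.any(deg == 0):
        raise ValueError("graph has isolated nodes; PageRank undefined")
    M = G.adjacency / deg[None, :]  # A D^-1, column-stochastic
    sigma = np.ones(G.n_nodes)
    for _ in range(max_iter):
        new = damping * (M @ sigma) + 1.0
        if np.max(np.abs(new - sigma)) < tol:
            return CentralityScores(sigma=new, damping=damping)
        sigma = new
    residual = float(np.max(np.abs(damping * (M @ sigma) + 1.0 - sigma)))
    raise RuntimeError(
        f"PageRank fixed point did not converge in {max_iter} iterations "
        f"(residual {residual:.3e})"
    )


def edge_centrality(sigma: CentralityScores, G: CellGraph) -> dict:
    """Edge centrality as the mean of endpoint scores, with its log.

    Returns ``{"edges", "w", "s"}`` where w_uv = (sigma_u + sigma_v)/2 and
    s_uv = log w_uv.
    """
    edges = G.edge_list()
    w = 0.5 * (sigma.sigma[edges[:, 0]] + sigma.sigma[edges[:, 1]])
    return {"edges": edges, "w": w, "s": np.log(w)}


def _normalized_probabilities(s: np.ndarray, p_base: float, p_tau: float) -> np.ndarray:
    """min(((s_max - s) / (s_max - mean(s))) * p_base, p_tau).

    When all scores coincide the ratio is the 0/0 limit 1, giving every item
    the "average importance" probability min(p_base, p_tau).
    """
    s_max = s.max()
    mu = s.mean()
    if s_max == mu:
        ratio = np.ones_like(s)
    else:
        ratio = (s_max - s) / (s_max - mu)
    return np.minimum(ratio * p_base, p_tau)


def edge_drop_probabilities(
    s_edges: dict, p_e: float, p_tau: float
) -> EdgeDropProbabilities:
    """Per-edge removal probabilities, anti-monotone in edge centrality."""
    if not (0.0 < p_e < 1.0 and 0.0 < p_tau < 1.0):
        raise ValueError("p_e and p_tau must lie in (0, 1)")
    s = np.asarray(s_edges["s"], dtype=float)
    if s.size == 0:
        raise ValueError("empty edge set")
    return EdgeDropProbabilities(
        edges=np.asarray(s_edges["edges"]),
        p_edge=_normalized_probabilities(s, p_e, p_tau),
        p_e=p_e,
        p_tau=p_tau,
    )


def sample_edge_view(
    G: CellGraph, p: EdgeDropProbabilities, seed: int
) -> np.ndarray:
    """Keep each edge independently with probability 1 - p_uv; symmetric result."""
    rng = np.random.default_rng(seed)
    keep = rng.random(len(p.p_edge)) >= p.p_edge
    A = np.zeros_like(G.adjacency)
    kept = p.edges[keep]
    A[kept[:, 0], kept[:, 1]] = 1
    A[kept[:, 1], kept[:, 0]] = 1
    return A


def feature_dim_weights(
    X: np.ndarray, sigma: CentralityScores, dense: bool = True
) -> np.ndarray:
    """Centrality-weighted importance per feature dimension.

    Dense features (the scRNA-seq case) use w_i = sum_u |x_ui| * sigma_u;
    one-hot features drop the absolute value.  Returns log-weights s_i, with
    all-zero columns clamped to a tiny floor so they mask with maximal
    probability.
    """
    X = np.asarray(X, dtype=float)
    w = (np.abs(X) if dense else X).T @ sigma.sigma
    if np.all(w == 0):
        raise ValueError("every feature dimension has zero weight")
    return np.log(np.maximum(w, _W_FLOOR))


def feature_mask_probabilities(
    s: np.ndarray, p_f: float, p_tau: float
) -> FeatureMaskProbabilities:
    """Per-dimension masking probabilities, anti-monotone in importance."""
    if not (0.0 < p_f < 1.0 and 0.0 < p_tau < 1.0):
        raise ValueError("p_f and p_tau must lie in (0, 1)")
    return FeatureMaskProbabilities(
        p_dim=_normalized_probabilities(np.asarray(s, dtype=float), p_f, p_tau),
        p_f=p_f,
        p_tau=p_tau,
    )


def sample_feature_mask(
    X: np.ndarray, p: FeatureMaskProbabilities, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One Bernoulli(1 - p_i) draw per dimension, broadcast over all cells.

    Returns ``(masked_features, mask)``; masked dimensions are exactly-zero
    columns.
    """
    rng = np.random.default_rng(seed)
    mask = (rng.random(len(p.p_dim)) >= p.p_dim).astype(float)
    return np.asarray(X, dtype=float) * mask[None, :], mask


def make_views(
    G: CellGraph,
    X: np.ndarray,
    config: AugmentationConfig,
    seed: int,
) -> tuple[AugmentedView, AugmentedView]:
    """Draw the two augmented views for one training iteration.

    Drop/mask probabilities are computed once from the un-augmented graph
    (centrality of the original topology) and shared by both views; each
    view then samples its own edges and feature mask from an independent
    sub-seed.
    """
    sigma = pagerank_centrality(G, damping=config.damping)
    s_edges = edge_centrality(sigma, G)
    s_dims = feature_dim_weights(X, sigma, dense=True)
    ss = np.random.SeedSequence(seed)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    views = []
    for i, (p_e, p_f) in enumerate(
        [(config.p_e1, config.p_f1), (config.p_e2, config.p_f2)]
    ):
        pe = edge_drop_probabilities(s_edges, p_e, config.p_tau)
        pf = feature_mask_probabilities(s_dims, p_f, config.p_tau)
        A = sample_edge_view(G, pe, sub[2 * i])
        Xm, mask = sample_feature_mask(X, pf, sub[2 * i + 1])
        views.append(
            AugmentedView(adjacency=A, features=Xm, mask=mask, rng_seed=sub[2 * i])
        )
    return views[0], views[1]
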