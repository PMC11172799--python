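"""Seeded ZINB count simulator with planted cluster structure.

Cells are split into clusters; each cluster up- or down-regulates its own
disjoint block of differentially expressed (DE) genes by a factor
exp(+-log_fold_change) on a shared baseline mean.  Counts are drawn from a
negative binomial NB(mu, theta) and then zeroed independently with the
dropout probability pi, i.e. exactly the zero-inflated NB mixture
pi * delta_0 + (1 - pi) * NB(mu, theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import CountMatrix

__all__ = ["SyntheticSpec", "generate", "sample_zinb_counts", "default_fixtures"]


@dataclass
class SyntheticSpec:
    n_cells: int = 300
    n_genes: int = 800
    n_clusters: int = 3
    de_fraction: float = 0.1
    log_fold_change: float = 2.0
    base_mean: float = 2.0
    dispersion: float = 2.0
    dropout_pi: float = 0.3
    cluster_proportions: tuple[float, ...] | None = None  # None = uniform
    seed: int = 0

    def proportions(self) -> np.ndarray:
        if self.cluster_proportions is None:
            return np.full(self.n_clusters, 1.0 / self.n_clusters)
        p = np.asarray(self.cluster_proportions, dtype=float)
        if len(p) != self.n_clusters or not np.isclose(p.sum(), 1.0):
            raise ValueError("cluster_proportions must sum to 1, one per cluster")
        return p


def sample_zinb_counts(
    mu: np.ndarray, theta: float | np.ndarray, pi: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ZINB counts entrywise: NB(mu, theta) zeroed with probability pi."""
    mu = np.asarray(mu, dtype=float)
    p_nb = theta / (theta + mu)
    counts = rng.negative_binomial(np.broadcast_to(theta, mu.shape), p_nb)
    if pi > 0:
        counts = np.where(rng.random(mu.shape) < pi, 0, counts)
    return counts


def _mean_matrix(spec: SyntheticSpec, labels: np.ndarray, rng: np.random.Generator):
    """Per-cell mean matrix with disjoint DE gene blocks per cluster."""
    n_de = int(np.floor(spec.de_fraction * spec.n_genes))
    if n_de * spec.n_clusters > spec.n_genes:
        raise ValueError("de_fraction too large for disjoint per-cluster DE blocks")
    mu = np.full((spec.n_cells, spec.n_genes), spec.base_mean, dtype=float)
    for c in range(spec.n_clusters):
        block = slice(c * n_de, (c + 1) * n_de)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        mu[np.ix_(labels == c, np.arange(*block.indices(spec.n_genes)))] *= np.exp(
            signs * spec.log_fold_change
        )
    return mu


def generate(spec: SyntheticSpec) -> tuple[CountMatrix, np.ndarray]:
    """Generate a seeded (CountMatrix, true_labels) pair from the spec."""
    if spec.n_cells < 1 or spec.n_genes < 1:
        raise ValueError("degenerate spec: need at least one cell and one gene")
    if spec.n_clusters < 1 or spec.n_clusters > spec.n_cells:
        raise ValueError("n_clusters must lie in [1, n_cells]")
    if not 0.0 <= spec.dropout_pi < 1.0:
        raise ValueError("dropout_pi must lie in [0, 1)")
    rng = np.random.default_rng(spec.seed)
    # largest-remainder allocation of cells to clusters, then a shuffle
    quota = spec.proportions() * spec.n_cells
    sizes = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - sizes))[: spec.n_cells - sizes.sum()]:
        sizes[i] += 1
    labels = rng.permutation(np.repeat(np.arange(spec.n_clusters), sizes))
    mu = _mean_matrix(spec, labels, rng)
    counts = sample_zinb_counts(mu, spec.dispersion, spec.dropout_pi, rng)
    cm = CountMatrix(
        counts=counts,
        cell_ids=[f"cell{i}" for i in range(spec.n_cells)],
        gene_ids=[f"gene{j}" for j in range(spec.n_genes)],
    )
    return cm, labels


def default_fixtures() -> dict[str, SyntheticSpec]:
    """Named simulation settings used throughout the test suite.

    ``easy3`` has strong, clearly separable cluster signal; ``hard6`` has
    weaker fold changes, heavier dropout and more clusters; ``tiny`` is a
    fast smoke-test size.
    """
    return {
        "tiny": SyntheticSpec(
            n_cells=60, n_genes=100, n_clusters=2,
            log_fold_change=2.0, dropout_pi=0.2, seed=7,
        ),
        "easy3": SyntheticSpec(
            n_cells=300, n_genes=800, n_clusters=3,
            log_fold_change=2.0, dropout_pi=0.3, seed=11,
        ),
        "hard6": SyntheticSpec(
            n_cells=600, n_genes=1200, n_clusters=6,
            log_fold_change=0.8, dropout_pi=0.5, seed=13,
        ),
    }
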