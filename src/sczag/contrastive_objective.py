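"""Multi-view InfoNCE objective over paired node embeddings.

Each cell's embedding in one augmented view is the anchor, the same cell in
the other view the positive, and every other embedding in either view a
negative.  Similarities are temperature-scaled cosines of projected
embeddings (two-layer ELU perceptron head g).  For anchor u_i,

    l(u_i, v_i) = theta(u_i, v_i)/tau
                  - log[ sum_{k != i} e^{theta(u_i,u_k)/tau}       (intra-view)
                       + sum_{k != i} e^{theta(u_i,v_k)/tau}       (inter-view)
                       + e^{theta(u_i,v_i)/tau} ],                 (positive)

and the objective J averages both directions over all cells; training
minimizes -J.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .appnp_encoder import glorot

__all__ = [
    "ContrastiveConfig",
    "init_projection_params",
    "project",
    "critic",
    "pair_loss",
    "objective",
]

_NORM_EPS = 1e-12
_NEG_INF = -1e30  # masks the self-similarity term out of the log-sum-exp


@dataclass
class ContrastiveConfig:
    """Temperature and projection-head widths (latent -> hidden -> output)."""

    tau: float = 0.4
    proj_hidden: int = 15
    proj_dim: int = 15


def init_projection_params(
    latent_dim: int, config: ContrastiveConfig, seed: int = 0
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    return {
        "P1": glorot(rng, latent_dim, config.proj_hidden),
        "q1": np.zeros(config.proj_hidden),
        "P2": glorot(rng, config.proj_hidden, config.proj_dim),
        "q2": np.zeros(config.proj_dim),
    }


def _elu(x):
    return anp.where(x > 0, x, anp.exp(anp.minimum(x, 0.0)) - 1.0)


def project(Z, params: dict | None):
    """Two-layer ELU projection head; ``params=None`` means identity."""
    if params is None:
        return Z
    h = _elu(anp.dot(Z, params["P1"]) + params["q1"])
    return anp.dot(h, params["P2"]) + params["q2"]


def _unit_rows(Z):
    """Row-normalize; zero rows stay zero (similarity 0 by convention)."""
    n = anp.sqrt(anp.sum(Z**2, axis=-1, keepdims=True))
    return Z / anp.maximum(n, _NORM_EPS)


def critic(u, v, params: dict | None = None, tau: float = 1.0) -> float:
    """Cosine similarity of the projected vectors, in [-1, 1]."""
    pu = _unit_rows(project(anp.reshape(u, (1, -1)), params))
    pv = _unit_rows(project(anp.reshape(v, (1, -1)), params))
    return float(anp.sum(pu * pv))


def _logsumexp(x, axis=-1):
    m = anp.max(x, axis=axis, keepdims=True)
    return anp.squeeze(m, axis=axis) + anp.log(
        anp.sum(anp.exp(x - m), axis=axis)
    )


def _pair_losses(U, V, params: dict | None, tau: float):
    """Vector of l(u_i, v_i) for all i (anchors in U, positives in V)."""
    Pu = _unit_rows(project(U, params))
    Pv = _unit_rows(project(V, params))
    S_uv = anp.dot(Pu, Pv.T) / tau  # inter-view, diagonal = positives
    S_uu = anp.dot(Pu, Pu.T) / tau  # intra-view, diagonal excluded
    n = U.shape[0]
    mask = _NEG_INF * np.eye(n)
    denom = _logsumexp(anp.concatenate([S_uv, S_uu + mask], axis=1), axis=1)
    return anp.diag(S_uv) - denom


def pair_loss(i: int, U, V, params: dict | None = None, tau: float = 1.0):
    """l(u_i, v_i) for a single anchor index i."""
    U = anp.atleast_2d(U)
    V = anp.atleast_2d(V)
    if U.shape != V.shape:
        raise ValueError("U and V must have identical shape")
    return _pair_losses(U, V, params, tau)[i]


def objective(U, V, params: dict | None = None, tau: float = 1.0):
    """J = (1/2N) sum_i [ l(u_i, v_i) + l(v_i, u_i) ]; always <= 0."""
    if U.shape != V.shape:
        raise ValueError("U and V must have identical shape")
    return 0.5 * (
        anp.mean(_pair_losses(U, V, params, tau))
        + anp.mean(_pair_losses(V, U, params, tau))
    )
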