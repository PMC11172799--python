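"""Latent encoder: a two-layer feature map followed by personalized-PageRank propagation.

Prediction and propagation are decoupled: a small dense network maps each
cell's expression profile to a latent prediction H, and a truncated
personalized-PageRank power iteration diffuses those predictions over the
cell graph,

    Z(0) = H,    Z(k+1) = (1 - alpha) * A_hat Z(k) + alpha * H,

whose fixed point is the personalized-PageRank limit
alpha * (I - (1 - alpha) A_hat)^(-1) H.  The teleport probability ``alpha``
controls how much of the original prediction each cell retains; the number
of steps K truncates the diffusion radius.

All array math goes through ``autograd.numpy`` so gradients flow through the
propagation scheme during end-to-end training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

from .cell_graph import NormalizedAdjacency

__all__ = [
    "EncoderConfig",
    "init_encoder_params",
    "predict_features",
    "appnp_propagate",
    "encode",
    "encode_gcn",
    "glorot",
]


@dataclass
class EncoderConfig:
    """Encoder architecture and propagation settings.

    ``alpha_prop`` is the APPNP teleport probability (distinct from the 0.85
    PageRank-centrality damping used in augmentation); ``n_prop_steps`` the
    truncation depth K of the power iteration.
    """

    hidden_dim: int = 128
    latent_dim: int = 15
    alpha_prop: float = 0.1
    n_prop_steps: int = 10
    final_softmax: bool = False


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    """Glorot/Xavier-uniform weight initialization."""
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def init_encoder_params(
    n_features: int, config: EncoderConfig, seed: int = 0
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    return {
        "W1": glorot(rng, n_features, config.hidden_dim),
        "b1": np.zeros(config.hidden_dim),
        "W2": glorot(rng, config.hidden_dim, config.latent_dim),
        "b2": np.zeros(config.latent_dim),
    }


def _relu(x):
    return anp.maximum(x, 0.0)


def predict_features(X, params: dict):
    """H = f_theta(X): dense ReLU layer to the hidden width, linear layer to latent."""
    if X.shape[1] != params["W1"].shape[0]:
        raise ValueError(
            f"feature dim {X.shape[1]} does not match encoder input "
            f"{params['W1'].shape[0]}"
        )
    h = _relu(anp.dot(X, params["W1"]) + params["b1"])
    return anp.dot(h, params["W2"]) + params["b2"]


def _softmax(x):
    m = anp.max(x, axis=1, keepdims=True)
    e = anp.exp(x - m)
    return e / anp.sum(e, axis=1, keepdims=True)


def appnp_propagate(
    H,
    A_hat: NormalizedAdjacency | np.ndarray,
    alpha_prop: float = 0.1,
    n_steps: int = 10,
    final_softmax: bool = False,
):
    """Truncated personalized-PageRank power iteration from Z(0) = H.

    With ``final_softmax`` the last step is pushed through a row softmax (the
    classification-style output); for latent clustering embeddings it is off
    by default.
    """
    A = A_hat.matrix if isinstance(A_hat, NormalizedAdjacency) else A_hat
    if H.shape[0] != A.shape[0]:
        raise ValueError("H row count must equal number of graph nodes")
    Z = H
    for _ in range(n_steps):
        Z = (1.0 - alpha_prop) * anp.dot(A, Z) + alpha_prop * H
    return _softmax(Z) if final_softmax else Z


def encode(A_hat, X, params: dict, config: EncoderConfig):
    """Full encoder: predict then propagate.  Shared weights across views."""
    H = predict_features(X, params)
    return appnp_propagate(
        H, A_hat, config.alpha_prop, config.n_prop_steps, config.final_softmax
    )


def encode_gcn(A_hat, X, params: dict, config: EncoderConfig):
    """Ablation encoder: two conventional graph-convolution layers.

    Each layer aggregates with the normalized adjacency, ReLU after the
    first, linear output.  Same parameter shapes and output width as the
    propagation encoder.
    """
    A = A_hat.matrix if isinstance(A_hat, NormalizedAdjacency) else A_hat
    h = _relu(anp.dot(A, anp.dot(X, params["W1"])) + params["b1"])
    return anp.dot(A, anp.dot(h, params["W2"])) + params["b2"]
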