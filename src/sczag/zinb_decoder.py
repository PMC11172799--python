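"""ZINB decoder and reconstruction likelihood.

The decoder maps latent embeddings back to per-entry parameters of a
zero-inflated negative binomial, the standard noise model for scRNA-seq
counts: a point mass at zero with probability pi (dropout) mixed with a
negative binomial of mean mu and dispersion theta,

    ZINB(x; pi, mu, theta) = pi * 1{x=0} + (1 - pi) * NB(x; mu, theta),
    NB(x; mu, theta) = Gamma(x + theta) / (x! Gamma(theta))
                       * (theta / (theta + mu))^theta * (mu / (theta + mu))^x.

The reconstruction loss is the mean per-entry negative log-likelihood of the
raw counts under these decoded parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np
from autograd.scipy.special import gammaln

from .appnp_encoder import glorot

__all__ = [
    "DecoderConfig",
    "ZINBParams",
    "init_decoder_params",
    "decode_trunk",
    "decode_zinb",
    "zinb_nll",
    "decode_linear",
    "mse_loss",
]

# clamps keeping log-gamma and the mixture log finite
PI_EPS = 1e-6
RATE_MIN = 1e-5
RATE_MAX = 1e6


@dataclass
class DecoderConfig:
    hidden_sizes: tuple[int, ...] = (128, 256, 512)


@dataclass
class ZINBParams:
    """Per-entry ZINB parameters, all cells x genes."""

    pi: np.ndarray
    mu: np.ndarray
    theta: np.ndarray


def init_decoder_params(
    latent_dim: int, n_genes: int, config: DecoderConfig, seed: int = 0
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    n_in = latent_dim
    for i, h in enumerate(config.hidden_sizes):
        params[f"W{i}"] = glorot(rng, n_in, h)
        params[f"b{i}"] = np.zeros(h)
        n_in = h
    for head in ("pi", "mu", "theta"):
        params[f"W_{head}"] = glorot(rng, n_in, n_genes)
        params[f"b_{head}"] = np.zeros(n_genes)
    return params


def decode_trunk(Z, params: dict, config: DecoderConfig):
    """Shared fully connected trunk, ReLU after every hidden layer."""
    h = Z
    for i in range(len(config.hidden_sizes)):
        h = anp.maximum(anp.dot(h, params[f"W{i}"]) + params[f"b{i}"], 0.0)
    return h


def _heads(h, params):
    pre_pi = anp.dot(h, params["W_pi"]) + params["b_pi"]
    pre_mu = anp.dot(h, params["W_mu"]) + params["b_mu"]
    pre_th = anp.dot(h, params["W_theta"]) + params["b_theta"]
    pi = anp.clip(1.0 / (1.0 + anp.exp(-pre_pi)), PI_EPS, 1.0 - PI_EPS)
    mu = anp.clip(anp.exp(pre_mu), RATE_MIN, RATE_MAX)
    theta = anp.clip(anp.exp(pre_th), RATE_MIN, RATE_MAX)
    return pi, mu, theta


def decode_zinb(Z, params: dict, config: DecoderConfig | None = None) -> ZINBParams:
    """Decode embeddings to (pi, mu, theta) via sigmoid/exp/exp output heads."""
    config = config or DecoderConfig()
    if Z.shape[1] != params["W0"].shape[0]:
        raise ValueError(
            f"latent dim {Z.shape[1]} does not match decoder input "
            f"{params['W0'].shape[0]}"
        )
    pi, mu, theta = _heads(decode_trunk(Z, params, config), params)
    return ZINBParams(pi=pi, mu=mu, theta=theta)


def _nb_log_pmf(x, mu, theta):
    return (
        gammaln(x + theta)
        - gammaln(x + 1.0)
        - gammaln(theta)
        + theta * (anp.log(theta) - anp.log(theta + mu))
        + x * (anp.log(mu) - anp.log(theta + mu))
    )


def zinb_log_likelihood(X, p: ZINBParams, validate: bool = True):
    """Per-entry ZINB log-likelihood of counts X under (pi, mu, theta).

    The x = 0 mixture term is evaluated in log space
    (logaddexp(log pi, log(1 - pi) + NB log-pmf at 0)) for stability.
    Accepts pi = 0 exactly, in which case this reduces to the plain NB
    log-likelihood.
    """
    if validate:
        Xv = np.asarray(X)
        if np.any(Xv < 0):
            raise ValueError("counts must be nonnegative")
        if not np.allclose(Xv, np.round(Xv)):
            raise ValueError("counts must be integers")
    is_zero = np.asarray(X) == 0
    log_nb = _nb_log_pmf(X, p.mu, p.theta)
    with np.errstate(divide="ignore"):
        zero_case = anp.logaddexp(anp.log(p.pi), anp.log(1.0 - p.pi) + log_nb)
    pos_case = anp.log(1.0 - p.pi) + log_nb
    return anp.where(is_zero, zero_case, pos_case)


def zinb_nll(X, p: ZINBParams, validate: bool = True):
    """Mean per-entry ZINB negative log-likelihood (the reconstruction loss)."""
    return -anp.mean(zinb_log_likelihood(X, p, validate=validate))


def decode_linear(Z, params: dict, config: DecoderConfig | None = None):
    """Linear reconstruction head over the shared trunk (ZINB-off ablation)."""
    config = config or DecoderConfig()
    h = decode_trunk(Z, params, config)
    return anp.dot(h, params["W_mu"]) + params["b_mu"]


def mse_loss(X_target, X_hat):
    """Mean squared reconstruction error (ZINB-off ablation loss)."""
    return anp.mean((X_target - X_hat) ** 2)
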