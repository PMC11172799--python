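"""Self-optimizing deep embedded clustering on the latent space.

Cluster centers are seeded by spectral clustering of the pretrained
embedding.  Soft assignments use a Student's-t kernel (one degree of
freedom) between embeddings and centers,

    q_iu = (1 + ||z_i - mu_u||^2)^(-1) / sum_r (1 + ||z_i - mu_r||^2)^(-1),

sharpened into an auxiliary target p_iu ~ q_iu^2 / f_u (f_u the soft cluster
mass), and matched by minimizing KL(P || Q).  Centers are trainable: the
clustering gradient flows into both the encoder and the centers.
"""

from __future__ import annotations

import warnings

import autograd.numpy as anp
import numpy as np
from sklearn.cluster import SpectralClustering

__all__ = [
    "init_centers",
    "soft_assign",
    "target_distribution",
    "kl_loss",
    "hard_labels",
]

_ROW_SUM_TOL = 1e-8


def init_centers(Z: np.ndarray, n_clusters: int, seed: int = 0) -> np.ndarray:
    """Cluster centers from spectral clustering of the embedding.

    Labels come from seeded spectral clustering (RBF affinity); each center
    is the mean embedding of its cluster.  If a cluster comes back empty the
    clustering is re-run once with a shifted seed before giving up.
    """
    Z = np.asarray(Z, dtype=float)
    if n_clusters < 2:
        raise ValueError("n_clusters must be at least 2")
    if n_clusters > Z.shape[0]:
        raise ValueError("n_clusters cannot exceed the number of cells")
    if n_clusters == Z.shape[0]:
        return Z.copy()
    for attempt, s in enumerate([seed, seed + 1]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = SpectralClustering(
                n_clusters=n_clusters,
                affinity="rbf",
                assign_labels="kmeans",
                random_state=s % (2**31),
            ).fit_predict(Z)
        if len(np.unique(labels)) == n_clusters:
            return np.vstack(
                [Z[labels == c].mean(axis=0) for c in range(n_clusters)]
            )
    raise RuntimeError("spectral initialization produced an empty cluster")


def soft_assign(Z, centers):
    """Student's-t soft assignment matrix Q; rows sum to 1."""
    d2 = anp.sum((Z[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    num = 1.0 / (1.0 + d2)
    return num / anp.sum(num, axis=1, keepdims=True)


def target_distribution(Q: np.ndarray) -> np.ndarray:
    """Sharpened auxiliary target P from Q: p_iu ~ q_iu^2 / f_u, row-normalized."""
    Q = np.asarray(Q, dtype=float)
    f = Q.sum(axis=0)
    if np.any(f == 0):
        raise ValueError("empty soft cluster")
    W = Q**2 / f
    return W / W.sum(axis=1, keepdims=True)


def kl_loss(P, Q):
    """KL(P || Q) = sum_iu p_iu log(p_iu / q_iu); zero p entries contribute 0."""
    P_arr = np.asarray(P, dtype=float)
    Q_arr = np.asarray(Q._value if hasattr(Q, "_value") else Q, dtype=float)
    if P_arr.shape != Q_arr.shape:
        raise ValueError("P and Q shapes differ")
    if np.any((Q_arr == 0) & (P_arr > 0)):
        raise ValueError("infinite divergence: q_iu = 0 where p_iu > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.where(P_arr > 0, np.log(P_arr), 0.0)
    safe_Q = anp.where(P_arr > 0, Q, 1.0)
    return anp.sum(anp.where(P_arr > 0, P_arr * (logP - anp.log(safe_Q)), 0.0))


def hard_labels(Q: np.ndarray) -> np.ndarray:
    """Argmax cluster per row; ties go to the lower cluster index."""
    return np.argmax(np.asarray(Q), axis=1)
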