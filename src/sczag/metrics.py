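"""Clustering agreement metrics: adjusted Rand index and normalized mutual information."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

__all__ = ["ari", "nmi"]


def _validate(predicted, reference) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted).ravel()
    r = np.asarray(reference).ravel()
    if p.shape != r.shape:
        raise ValueError(f"label length mismatch: {p.shape[0]} vs {r.shape[0]}")
    if p.size < 2:
        raise ValueError("need at least two samples")
    return p, r


def ari(predicted, reference) -> float:
    """Adjusted Rand index: chance-corrected pair-counting agreement, in [-1, 1]."""
    p, r = _validate(predicted, reference)
    return float(adjusted_rand_score(r, p))


def nmi(predicted, reference, average_method: str = "arithmetic") -> float:
    """Normalized mutual information in [0, 1].

    Normalization divides MI by the ``average_method`` mean of the two label
    entropies (arithmetic by default).
    """
    p, r = _validate(predicted, reference)
    return float(
        normalized_mutual_info_score(r, p, average_method=average_method)
    )
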