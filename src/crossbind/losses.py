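"""The composite training objective: binary cross-entropy plus alignment MSE.

The total loss is ``L = L_BCE + lambda * L_align`` where the alignment term
pulls the cross-attended representation toward the TCR embedding (mean
squared error over the batch) and ``lambda >= 0`` weights it.  ``lambda = 0``
reduces the objective exactly to plain BCE.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bce_loss", "align_loss", "total_loss", "EPS_CLAMP"]

EPS_CLAMP = 1e-12  # floor for log arguments


def bce_loss(y_hat, y, eps: float = EPS_CLAMP) -> float:
    """Mean binary cross-entropy, -(1/N) sum[y log p + (1-y) log(1-p)].

    Probabilities are clamped to [eps, 1-eps] before the logs.
    """
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if y_hat.size == 0:
        raise ValueError("empty batch")
    if y_hat.shape != y.shape:
        raise ValueError("y_hat and y must have the same length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    p = np.clip(y_hat, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def align_loss(e_align, e_protein) -> float:
    """Mean squared alignment error, (1/N) sum_i ||e_align_i - e_protein_i||^2."""
    a = np.atleast_2d(np.asarray(e_align, dtype=float))
    p = np.atleast_2d(np.asarray(e_protein, dtype=float))
    if a.shape != p.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {p.shape}")
    diff = a - p
    return float(np.mean(np.sum(diff * diff, axis=1)))


def total_loss(bce: float, align: float, lam: float) -> float:
    """Composite objective ``bce + lam * align`` with ``lam >= 0``."""
    if lam < 0:
        raise ValueError("alignment weight must be non-negative")
    return float(bce) + float(lam) * float(align)
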