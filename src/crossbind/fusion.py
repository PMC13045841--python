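"""Cross-modality alignment (multi-head cross-attention) and the binding head.

The TCR embedding supplies the attention queries; the peptide (molecule)
embedding supplies keys and values, so the protein side selectively reads
chemical features of the peptide.  Per head: ``softmax(Q K^T / sqrt(d_k)) V``;
heads are concatenated and projected, yielding the aligned representation
``e_align`` with the same width as the inputs.

Two granularities are supported.  In the default ``pooled`` mode each
embedding is a single d_out vector treated as a length-1 token sequence; the
softmax over one key is identically 1, so the cross-attention degenerates to
a deterministic linear map of the molecule embedding - this keeps the
alignment loss ``||e_align - e_protein||^2`` well formed on vectors.  In
``tokens`` mode the pre-pooling token matrices are fused instead, and the
attended output is mean-pooled afterwards.

The classifier concatenates ``z = [e_protein; e_align]`` and applies a
single affine map with a sigmoid, giving a binding probability strictly in
(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .encoders import AttentionParams, attention

__all__ = ["FusionOutput", "HeadParams", "mhca", "predict"]


@dataclass
class FusionOutput:
    """Aligned representation, classifier input and binding probability."""

    e_align: np.ndarray
    z: np.ndarray
    y_hat: float


@dataclass
class HeadParams:
    """Affine classifier head over z = [e_protein; e_align]."""

    w: object  # (2 * d_out, 1)
    b: object  # (1,)

    @classmethod
    def init(cls, rng: np.random.Generator, d_out: int) -> "HeadParams":
        return cls(w=rng.normal(0.0, 1.0 / np.sqrt(2 * d_out), (2 * d_out, 1)),
                   b=np.zeros(1))


def _as2d(x):
    data = x.data if isinstance(x, Tensor) else np.asarray(x)
    if data.ndim == 1:
        if isinstance(x, Tensor):
            raise ValueError("pass Tensors as (1, d) row matrices")
        return np.asarray(x)[None, :]
    return x


def mhca(e_protein, e_molecule, p: AttentionParams, return_weights: bool = False):
    """Cross-attend the protein query onto molecule keys/values.

    Accepts either pooled vectors (treated as length-1 sequences) or token
    matrices; the output has one row per query row and the input width.
    """
    q = _as2d(e_protein)
    kv = _as2d(e_molecule)
    return attention(q, kv, p, return_weights=return_weights)


def predict(e_protein, e_align, head: HeadParams) -> FusionOutput:
    """Binding probability: ``sigmoid(w . [e_protein; e_align] + b)``."""
    ep = np.asarray(e_protein, dtype=float).ravel()
    ea = np.asarray(e_align, dtype=float).ravel()
    if ep.shape != ea.shape:
        raise ValueError(f"width mismatch: {ep.shape} vs {ea.shape}")
    z = np.concatenate([ep, ea])
    logit = float(z @ np.asarray(head.w).ravel() + np.asarray(head.b).ravel()[0])
    # clamp so the probability stays strictly inside (0, 1) at extreme logits
    y_hat = float(np.clip(ad.sigmoid(np.asarray(logit)), 1e-12, 1.0 - 1e-12))
    return FusionOutput(e_align=ea, z=z, y_hat=y_hat)
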