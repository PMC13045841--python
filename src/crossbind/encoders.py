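"""Built-in lightweight transformer encoders and the pretrained-adapter hook.

Two independently parameterised branches share this code: a protein branch
over residue tokens (the TCR beta-chain CDR3) and a molecule branch over
SMILES tokens (the peptide).  A branch embeds its tokens, applies layer
normalisation, multi-head self-attention and a position-wise feed-forward
network, then mean-pools the token outputs and projects them to a fixed
``d_out`` (256 by default) vector.

The block computes ``FFN(LN(X) + MHSA(LN(X)))`` literally - the FFN is
applied to the residual sum with no second residual connection and no
post-normalisation, which deviates from the standard transformer block on
purpose.  How the L x d token matrix becomes a single vector is an open
design choice; mean pooling followed by a learnable linear map is used as
the simplest order-insensitive reduction (positional encodings re-introduce
order sensitivity upstream).

Everything here runs on plain ndarrays for inference and on autodiff
Tensors for training - the ops in :mod:`crossbind._autodiff` dispatch on
their input type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

__all__ = [
    "AttentionParams",
    "FfnParams",
    "Vocabulary",
    "EncoderStack",
    "PretrainedEncoderAdapter",
    "layer_norm",
    "mhsa",
    "attention",
    "encoder_block",
    "embed_tokens",
    "sinusoidal_positions",
]

D_OUT_DEFAULT = 256


@dataclass
class AttentionParams:
    """Per-head Q/K/V projections plus the output projection.

    wq, wk, wv have shape (h, d, d_k); wo has shape (h * d_k, d).
    """

    wq: object
    wk: object
    wv: object
    wo: object

    @property
    def n_heads(self) -> int:
        return _data(self.wq).shape[0]

    @property
    def d_k(self) -> int:
        return _data(self.wq).shape[2]

    @classmethod
    def init(cls, rng: np.random.Generator, d: int, n_heads: int,
             d_k: int | None = None) -> "AttentionParams":
        d_k = d_k if d_k is not None else max(1, d // n_heads)
        scale = 1.0 / np.sqrt(d)
        return cls(
            wq=rng.normal(0.0, scale, (n_heads, d, d_k)),
            wk=rng.normal(0.0, scale, (n_heads, d, d_k)),
            wv=rng.normal(0.0, scale, (n_heads, d, d_k)),
            wo=rng.normal(0.0, 1.0 / np.sqrt(n_heads * d_k), (n_heads * d_k, d)),
        )


@dataclass
class FfnParams:
    """Position-wise feed-forward parameters: d -> hidden -> d."""

    w1: object
    b1: object
    w2: object
    b2: object

    @classmethod
    def init(cls, rng: np.random.Generator, d: int, hidden: int) -> "FfnParams":
        return cls(
            w1=rng.normal(0.0, 1.0 / np.sqrt(d), (d, hidden)),
            b1=np.zeros(hidden),
            w2=rng.normal(0.0, 1.0 / np.sqrt(hidden), (hidden, d)),
            b2=np.zeros(d),
        )


def _data(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x)


# -- core ops -----------------------------------------------------------------

def layer_norm(m, gain=None, bias=None, eps: float = 1e-5):
    """Row-wise zero-mean unit-variance normalisation with optional affine."""
    if _data(m).shape[-1] < 1:
        raise ValueError("cannot normalise an empty row")
    out = ad.layernorm_last(m, eps=eps)
    if gain is not None:
        out = out * gain
    if bias is not None:
        out = out + bias
    return out


def attention(q_in, kv_in, p: AttentionParams, return_weights: bool = False):
    """Multi-head scaled dot-product attention.

    Queries come from ``q_in`` (Lq x d); keys and values from ``kv_in``
    (Lk x d).  Self-attention passes the same matrix for both.  Per head:
    ``softmax(Q K^T / sqrt(d_k)) V``; heads are concatenated and projected
    by ``wo`` back to width d.
    """
    d = _data(q_in).shape[-1]
    if _data(p.wq).shape[1] != d or _data(kv_in).shape[-1] != _data(p.wk).shape[1]:
        raise ValueError(
            f"width mismatch: inputs {d}/{_data(kv_in).shape[-1]} vs "
            f"projections {_data(p.wq).shape[1]}/{_data(p.wk).shape[1]}"
        )
    inv_sqrt = 1.0 / np.sqrt(p.d_k)
    heads = []
    weights = []
    for i in range(p.n_heads):
        q = ad.matmul(q_in, _head(p.wq, i))
        k = ad.matmul(kv_in, _head(p.wk, i))
        v = ad.matmul(kv_in, _head(p.wv, i))
        scores = ad.matmul(q, ad.transpose(k)) * inv_sqrt
        a = ad.softmax_last(scores)
        weights.append(_data(a))
        heads.append(ad.matmul(a, v))
    out = ad.matmul(ad.concat(heads, axis=-1), p.wo)
    if return_weights:
        return out, np.stack(weights)
    return out


def _head(w, i: int):
    """Slice head i out of an (h, d, d_k) stack, keeping the tape if any."""
    if isinstance(w, Tensor):
        out = Tensor(w.data[i], _parents=(w,))

        def bwd(g, w=w, i=i):
            if w.grad is None:
                w.grad = np.zeros_like(w.data)
            w.grad[i] += g

        out._backward = bwd
        return out
    return np.asarray(w)[i]


def mhsa(m, p: AttentionParams, return_weights: bool = False):
    """Multi-head self-attention over a single token matrix (L x d)."""
    return attention(m, m, p, return_weights=return_weights)


def ffn(x, f: FfnParams):
    """ReLU(x W1 + b1) W2 + b2, applied position-wise."""
    return ad.matmul(ad.relu(ad.matmul(x, f.w1) + f.b1), f.w2) + f.b2


def encoder_block(m, p: AttentionParams, f: FfnParams, pool=None):
    """One encoder block: ``FFN(LN(m) + MHSA(LN(m)))``, optionally pooled.

    With ``pool=None`` the L x d token outputs are returned.  With
    ``pool=(w, b)`` the tokens are mean-pooled and linearly projected to the
    pooled embedding width.
    """
    xt = layer_norm(m)
    tokens = ffn(xt + mhsa(xt, p), f)
    if pool is None:
        return tokens
    w, b = pool
    pooled = ad.mean(tokens, axis=0, keepdims=True)
    return ad.matmul(pooled, w) + b


def sinusoidal_positions(length: int, d: int) -> np.ndarray:
    """Fixed sinusoidal positional encodings, (length x d)."""
    pos = np.arange(length)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


@dataclass
class Vocabulary:
    """Token -> id map with an optional UNK fallback."""

    tokens: tuple[str, ...]
    unk: bool = True
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens) + (1 if self.unk else 0)

    @property
    def unk_id(self) -> int:
        if not self.unk:
            raise ValueError("vocabulary has no UNK entry")
        return len(self.tokens)

    def encode(self, tokens) -> np.ndarray:
        ids = []
        for t in tokens:
            j = self._index.get(t)
            if j is None:
                if not self.unk:
                    raise KeyError(f"token {t!r} not in vocabulary and UNK is disabled")
                j = self.unk_id
            ids.append(j)
        return np.asarray(ids, dtype=np.intp)

    @classmethod
    def from_corpus(cls, token_sequences, unk: bool = True) -> "Vocabulary":
        seen: dict[str, None] = {}
        for seq in token_sequences:
            for t in seq:
                seen.setdefault(t, None)
        return cls(tokens=tuple(sorted(seen)), unk=unk)


def embed_tokens(token_ids, embedding, d: int | None = None):
    """Lookup-table embedding plus fixed sinusoidal positional addition."""
    ids = np.asarray(token_ids, dtype=np.intp)
    if ids.size == 0:
        raise ValueError("cannot embed an empty token sequence")
    rows = ad.gather_rows(embedding, ids)
    d = _data(embedding).shape[1] if d is None else d
    return rows + sinusoidal_positions(len(ids), d)


class EncoderStack:
    """A depth-``depth`` stack of encoder blocks with pooling to d_out.

    Bundles the embedding table, per-block attention/FFN parameters, and the
    mean-pool projection.  ``forward`` returns (token_matrix, pooled_vector);
    the pooled vector is the branch's fixed-width embedding.
    """

    def __init__(self, rng: np.random.Generator, vocab: Vocabulary, d_model: int = 32,
                 n_heads: int = 2, depth: int = 1, ffn_hidden: int | None = None,
                 d_out: int = D_OUT_DEFAULT):
        ffn_hidden = ffn_hidden if ffn_hidden is not None else 2 * d_model
        self.vocab = vocab
        self.d_model = d_model
        self.d_out = d_out
        self.embedding = rng.normal(0.0, 1.0, (len(vocab), d_model))
        self.blocks = [
            (AttentionParams.init(rng, d_model, n_heads), FfnParams.init(rng, d_model, ffn_hidden))
            for _ in range(depth)
        ]
        self.pool_w = rng.normal(0.0, 1.0 / np.sqrt(d_model), (d_model, d_out))
        self.pool_b = np.zeros(d_out)

    def forward(self, token_ids):
        x = embed_tokens(token_ids, self.embedding)
        for attn, f in self.blocks:
            x = encoder_block(x, attn, f, pool=None)
        pooled = ad.matmul(ad.mean(x, axis=0, keepdims=True), self.pool_w) + self.pool_b
        return x, pooled

    def encode(self, tokens):
        """Pooled d_out embedding for one token sequence (inference path)."""
        _, pooled = self.forward(self.vocab.encode(tokens))
        return _data(pooled)[0]

    # -- parameter bookkeeping for the optimiser -----------------------------
    def parameters(self, prefix: str) -> dict[str, object]:
        params = {f"{prefix}.embedding": self.embedding,
                  f"{prefix}.pool_w": self.pool_w, f"{prefix}.pool_b": self.pool_b}
        for j, (attn, f) in enumerate(self.blocks):
            params.update({
                f"{prefix}.block{j}.wq": attn.wq, f"{prefix}.block{j}.wk": attn.wk,
                f"{prefix}.block{j}.wv": attn.wv, f"{prefix}.block{j}.wo": attn.wo,
                f"{prefix}.block{j}.w1": f.w1, f"{prefix}.block{j}.b1": f.b1,
                f"{prefix}.block{j}.w2": f.w2, f"{prefix}.block{j}.b2": f.b2,
            })
        return params

    def set_parameters(self, prefix: str, params: dict) -> None:
        self.embedding = params[f"{prefix}.embedding"]
        self.pool_w = params[f"{prefix}.pool_w"]
        self.pool_b = params[f"{prefix}.pool_b"]
        for j in range(len(self.blocks)):
            attn = AttentionParams(
                wq=params[f"{prefix}.block{j}.wq"], wk=params[f"{prefix}.block{j}.wk"],
                wv=params[f"{prefix}.block{j}.wv"], wo=params[f"{prefix}.block{j}.wo"],
            )
            f = FfnParams(
                w1=params[f"{prefix}.block{j}.w1"], b1=params[f"{prefix}.block{j}.b1"],
                w2=params[f"{prefix}.block{j}.w2"], b2=params[f"{prefix}.block{j}.b2"],
            )
            self.blocks[j] = (attn, f)


class PretrainedEncoderAdapter:
    """Adapter contract for external pretrained sequence encoders.

    Wraps either a user-supplied embedding table on disk (TSV:
    ``sequence<TAB>v1<TAB>v2...``) or a callable ``seq -> vector``.  The
    output is projected to ``d_out`` with a fixed, seeded linear map when
    widths differ, so adapters satisfy the same contract as the built-in
    :class:`EncoderStack` and the fusion stage is backend-agnostic.  Nothing
    is ever downloaded.
    """

    def __init__(self, source, d_out: int = D_OUT_DEFAULT, freeze: bool = True, seed: int = 0):
        self.d_out = d_out
        self.freeze = freeze
        self._seed = seed
        self._proj = None
        if callable(source):
            self._fn = source
            self._table = None
        else:
            path = Path(source)
            if not path.exists():
                raise FileNotFoundError(
                    f"pretrained encoder source {str(path)!r} not found; supply an "
                    "embedding table or callable, or use the built-in encoder "
                    "(encoder.backend = 'builtin')"
                )
            table = {}
            with open(path) as fh:
                for line in fh:
                    parts = line.rstrip("\n").split("\t")
                    if len(parts) > 1:
                        table[parts[0]] = np.asarray([float(x) for x in parts[1:]])
            self._table = table
            self._fn = None

    def encode(self, seq: str) -> np.ndarray:
        if self._fn is not None:
            vec = np.asarray(self._fn(seq), dtype=float).ravel()
        else:
            if seq not in self._table:
                raise KeyError(f"sequence {seq!r} missing from the adapter's embedding table")
            vec = self._table[seq]
        if vec.shape[0] != self.d_out:
            if self._proj is None or self._proj.shape[0] != vec.shape[0]:
                rng = np.random.default_rng([303, self._seed])
                self._proj = rng.normal(0.0, 1.0 / np.sqrt(vec.shape[0]),
                                        (vec.shape[0], self.d_out))
            vec = vec @ self._proj
        return vec
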