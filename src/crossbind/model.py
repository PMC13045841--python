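"""The cross-attention TCR-peptide binding classifier.

A scikit-learn style estimator wrapping the full pipeline: residue tokens
for the TCR branch, SMILES (or residue) tokens for the peptide branch, two
independent transformer encoder stacks, multi-head cross-attention fusion,
and a sigmoid head, trained with Adam on the composite objective

    L = BCE(y, y_hat) + lambda_align * mean ||e_align - e_protein||^2

with early stopping on peptide-disjoint validation AUC-ROC.

``X`` is an (n, 2) array-like of strings - column 0 the TCR beta-chain CDR3
sequence, column 1 the peptide - or a DataFrame with ``tcr``/``peptide``
columns, or a :class:`~crossbind.simulate.PairDataset`.  ``y`` holds binary
labels.  The estimator composes with sklearn model selection; fitted
attributes carry the trailing underscore convention.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from . import _autodiff as ad
from ._autodiff import Adam, Tensor
from .encoders import AttentionParams, EncoderStack, Vocabulary
from .fusion import HeadParams, mhca
from .simulate import AMINO_ACIDS, PairDataset
from .smiles import peptide_to_smiles, tokenize_protein, tokenize_smiles
from .splits import grouped_split

__all__ = ["TcrPeptideBindingClassifier", "LossConfig", "train"]


@dataclass(frozen=True)
class LossConfig:
    """Objective and optimisation settings for the functional training API."""

    lambda_align: float = 0.1
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 30
    patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.lambda_align < 0:
            raise ValueError("lambda_align must be non-negative")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


def _protein_vocab() -> Vocabulary:
    return Vocabulary(tokens=tuple(AMINO_ACIDS), unk=False)


def _smiles_vocab() -> Vocabulary:
    """Fixed SMILES vocabulary: every token the converter can emit, plus UNK."""
    corpus = [tokenize_smiles(peptide_to_smiles(aa).text).tokens for aa in AMINO_ACIDS]
    corpus += [tokenize_smiles(peptide_to_smiles(aa, stereo=False).text).tokens
               for aa in AMINO_ACIDS]
    return Vocabulary.from_corpus(corpus, unk=True)


def _extract_pairs(X) -> tuple[list[str], list[str]]:
    if isinstance(X, PairDataset):
        return list(X.df["tcr"]), list(X.df["peptide"])
    if isinstance(X, pd.DataFrame):
        return list(X["tcr"].astype(str)), list(X["peptide"].astype(str))
    arr = np.asarray(X, dtype=object)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("X must be an (n, 2) array of [tcr, peptide] strings")
    return [str(t) for t in arr[:, 0]], [str(p) for p in arr[:, 1]]


class TcrPeptideBindingClassifier(BaseEstimator, ClassifierMixin):
    """Dual-encoder cross-attention binding classifier.

    Parameters
    ----------
    d_model : token embedding width of the built-in encoders.
    n_heads, depth, ffn_hidden : encoder block geometry (per branch).
    d_out : pooled embedding width shared by both branches (256 default).
    fusion_heads : cross-attention head count.
    fusion_granularity : "pooled" fuses the two d_out vectors as length-1
        sequences; "tokens" cross-attends the pre-pooling token matrices.
    peptide_input : "smiles" feeds the peptide branch chemical tokens,
        "sequence" feeds residue tokens (the no-SMILES ablation).
    smiles_map : optional peptide -> SMILES override (randomised-SMILES
        ablation); ignored when peptide_input="sequence".
    stereo : write L-stereochemistry into generated SMILES.
    lambda_align : weight of the alignment regulariser.
    learning_rate, batch_size, max_epochs, patience : Adam / early stopping.
    validation_fraction : peptide-grouped fraction held out when fit() is
        not given explicit validation data.
    random_state : seed for parameter init, shuffling and the internal split.

    Attributes
    ----------
    classes_ : array([0, 1]).
    history_ : list of per-epoch records (train loss, val AUC).
    best_val_auc_ : best validation AUC-ROC reached.
    n_epochs_ : number of epochs actually run.
    """

    def __init__(self, d_model: int = 32, n_heads: int = 2, depth: int = 1,
                 ffn_hidden: int | None = None, d_out: int = 256, fusion_heads: int = 2,
                 fusion_granularity: str = "pooled", peptide_input: str = "smiles",
                 smiles_map: dict | None = None, stereo: bool = True,
                 lambda_align: float = 0.1, learning_rate: float = 1e-3,
                 batch_size: int = 64, max_epochs: int = 30, patience: int = 5,
                 validation_fraction: float = 0.2, random_state: int | None = None,
                 verbose: int = 0):
        self.d_model = d_model
        self.n_heads = n_heads
        self.depth = depth
        self.ffn_hidden = ffn_hidden
        self.d_out = d_out
        self.fusion_heads = fusion_heads
        self.fusion_granularity = fusion_granularity
        self.peptide_input = peptide_input
        self.smiles_map = smiles_map
        self.stereo = stereo
        self.lambda_align = lambda_align
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    # -- tokenisation --------------------------------------------------------
    def _peptide_tokens(self, pep: str):
        if self.peptide_input == "sequence":
            return tokenize_protein(pep).tokens
        if self.peptide_input != "smiles":
            raise ValueError(f"unknown peptide_input {self.peptide_input!r}")
        if self.smiles_map is not None:
            smi = self.smiles_map[pep]
        else:
            smi = peptide_to_smiles(pep, stereo=self.stereo).text
        return tokenize_smiles(smi).tokens

    def _token_ids(self, seq: str, branch: str) -> np.ndarray:
        cache = self._id_cache_[branch]
        ids = cache.get(seq)
        if ids is None:
            if branch == "tcr":
                ids = self._tcr_enc_.vocab.encode(tokenize_protein(seq).tokens)
            else:
                ids = self._pep_enc_.vocab.encode(self._peptide_tokens(seq))
            cache[seq] = ids
        return ids

    # -- architecture --------------------------------------------------------
    def _build(self, rng: np.random.Generator) -> None:
        if self.fusion_granularity not in ("pooled", "tokens"):
            raise ValueError(f"unknown fusion_granularity {self.fusion_granularity!r}")
        pep_vocab = _smiles_vocab() if self.peptide_input == "smiles" else _protein_vocab()
        kw = dict(d_model=self.d_model, n_heads=self.n_heads, depth=self.depth,
                  ffn_hidden=self.ffn_hidden, d_out=self.d_out)
        self._tcr_enc_ = EncoderStack(rng, _protein_vocab(), **kw)
        self._pep_enc_ = EncoderStack(rng, pep_vocab, **kw)
        fusion_width = self.d_out if self.fusion_granularity == "pooled" else self.d_model
        self._fusion_ = AttentionParams.init(rng, fusion_width, self.fusion_heads)
        if self.fusion_granularity == "tokens":
            self._fusion_pool_w_ = rng.normal(0.0, 1.0 / np.sqrt(self.d_model),
                                              (self.d_model, self.d_out))
            self._fusion_pool_b_ = np.zeros(self.d_out)
        self._head_ = HeadParams.init(rng, self.d_out)
        self._id_cache_ = {"tcr": {}, "pep": {}}

    def _parameters(self) -> dict[str, object]:
        params = {}
        params.update(self._tcr_enc_.parameters("tcr"))
        params.update(self._pep_enc_.parameters("pep"))
        params.update({"fusion.wq": self._fusion_.wq, "fusion.wk": self._fusion_.wk,
                       "fusion.wv": self._fusion_.wv, "fusion.wo": self._fusion_.wo,
                       "head.w": self._head_.w, "head.b": self._head_.b})
        if self.fusion_granularity == "tokens":
            params.update({"fusion.pool_w": self._fusion_pool_w_,
                           "fusion.pool_b": self._fusion_pool_b_})
        return params

    def _set_parameters(self, params: dict) -> None:
        self._tcr_enc_.set_parameters("tcr", params)
        self._pep_enc_.set_parameters("pep", params)
        self._fusion_ = AttentionParams(wq=params["fusion.wq"], wk=params["fusion.wk"],
                                        wv=params["fusion.wv"], wo=params["fusion.wo"])
        self._head_ = HeadParams(w=params["head.w"], b=params["head.b"])
        if self.fusion_granularity == "tokens":
            self._fusion_pool_w_ = params["fusion.pool_w"]
            self._fusion_pool_b_ = params["fusion.pool_b"]

    # -- forward -------------------------------------------------------------
    def _forward_pair(self, tcr_out, pep_out):
        """Fuse one (protein, molecule) encoding into (e_p, e_align, logit)."""
        t_tokens, t_pooled = tcr_out
        p_tokens, p_pooled = pep_out
        if self.fusion_granularity == "pooled":
            e_align = mhca(t_pooled, p_pooled, self._fusion_)
        else:
            attended = mhca(t_tokens, p_tokens, self._fusion_)
            pooled = ad.mean(attended, axis=0, keepdims=True)
            e_align = ad.matmul(pooled, self._fusion_pool_w_) + self._fusion_pool_b_
        z = ad.concat([t_pooled, e_align], axis=-1)
        logit = ad.matmul(z, self._head_.w) + self._head_.b
        return t_pooled, e_align, logit

    def _encode_batch(self, tcrs, peps):
        """Encode with per-batch reuse of repeated sequences."""
        t_cache, p_cache = {}, {}
        outs = []
        for t, p in zip(tcrs, peps):
            if t not in t_cache:
                t_cache[t] = self._tcr_enc_.forward(self._token_ids(t, "tcr"))
            if p not in p_cache:
                p_cache[p] = self._pep_enc_.forward(self._token_ids(p, "pep"))
            outs.append((t_cache[t], p_cache[p]))
        return outs

    def _batch_loss(self, tcrs, peps, y):
        """Composite loss Tensor for one minibatch."""
        outs = self._encode_batch(tcrs, peps)
        bce_terms, align_terms = [], []
        for (t_out, p_out), label in zip(outs, y):
            e_p, e_align, logit = self._forward_pair(t_out, p_out)
            # BCE via the logit: (1-y) * l + softplus(-l) is stable for y in {0,1}
            bce = logit * (1.0 - float(label)) + ad.softplus(-logit)
            bce_terms.append(ad.sum_(bce))
            diff = e_align - e_p
            align_terms.append(ad.sum_(ad.square(diff)))
        n = float(len(y))
        bce_total = bce_terms[0]
        for t in bce_terms[1:]:
            bce_total = bce_total + t
        align_total = align_terms[0]
        for t in align_terms[1:]:
            align_total = align_total + t
        return bce_total / n + (self.lambda_align / n) * align_total

    def _predict_logits(self, tcrs, peps) -> np.ndarray:
        outs = self._encode_batch(tcrs, peps)
        logits = np.empty(len(outs))
        for i, (t_out, p_out) in enumerate(outs):
            _, _, logit = self._forward_pair(t_out, p_out)
            data = logit.data if isinstance(logit, Tensor) else np.asarray(logit)
            logits[i] = float(np.ravel(data)[0])
        return logits

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y=None, validation_data=None):
        """Train with Adam and early stopping on validation AUC-ROC.

        Without explicit ``validation_data`` (an (X_val, y_val) tuple), a
        peptide-grouped ``validation_fraction`` split of the training rows
        is held out, so validation peptides are never seen in training.
        """
        tcrs, peps = _extract_pairs(X)
        if isinstance(X, PairDataset) and y is None:
            y = X.df["label"].to_numpy()
        y = np.asarray(y, dtype=int).ravel()
        if len(y) != len(tcrs):
            raise ValueError("X and y length mismatch")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        self.classes_ = np.array([0, 1])

        seed = 0 if self.random_state is None else int(self.random_state)
        rng = np.random.default_rng([404, seed])
        self._build(rng)

        if validation_data is None:
            df = pd.DataFrame({"tcr": tcrs, "peptide": peps, "label": y})
            # re-permute on a derived seed if the grouped split strands a
            # single class in validation (AUC would be undefined)
            for attempt in range(10):
                tr, va = grouped_split(df, r=self.validation_fraction,
                                       seed=seed + 1009 * attempt)
                if va["label"].nunique() == 2:
                    break
            else:
                raise ValueError("could not form a two-class peptide-grouped "
                                 "validation split; AUC is undefined")
            tcrs_tr, peps_tr, y_tr = list(tr["tcr"]), list(tr["peptide"]), tr["label"].to_numpy()
            tcrs_va, peps_va, y_va = list(va["tcr"]), list(va["peptide"]), va["label"].to_numpy()
        else:
            X_val, y_val = validation_data
            tcrs_tr, peps_tr, y_tr = tcrs, peps, y
            tcrs_va, peps_va = _extract_pairs(X_val)
            if isinstance(X_val, PairDataset) and y_val is None:
                y_val = X_val.df["label"].to_numpy()
            y_va = np.asarray(y_val, dtype=int).ravel()
        if len(np.unique(y_va)) < 2:
            raise ValueError("validation set must contain both classes; AUC is undefined")

        params = {k: Tensor(np.array(v, dtype=float), requires_grad=True)
                  for k, v in self._parameters().items()}
        self._set_parameters(params)
        opt = Adam(params, lr=self.learning_rate)

        self.history_ = []
        self.initial_val_auc_ = float(
            roc_auc_score(y_va, self._predict_logits(tcrs_va, peps_va)))
        best_auc, best_state, since_best = -np.inf, None, 0
        n_tr = len(y_tr)
        order = np.arange(n_tr)
        epochs_run = 0
        for epoch in range(self.max_epochs):
            rng.shuffle(order)
            epoch_loss = 0.0
            for start in range(0, n_tr, self.batch_size):
                idx = order[start:start + self.batch_size]
                opt.zero_grad()
                loss = self._batch_loss([tcrs_tr[i] for i in idx],
                                        [peps_tr[i] for i in idx], y_tr[idx])
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            epoch_loss /= n_tr
            val_auc = float(roc_auc_score(y_va, self._predict_logits(tcrs_va, peps_va)))
            self.history_.append({"epoch": epoch, "train_loss": epoch_loss,
                                  "val_auc": val_auc})
            if self.verbose:
                print(f"epoch {epoch}: loss={epoch_loss:.4f} val_auc={val_auc:.4f}")
            epochs_run = epoch + 1
            if val_auc > best_auc:
                best_auc = val_auc
                best_state = {k: p.data.copy() for k, p in params.items()}
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break

        if best_state is not None:
            for k, p in params.items():
                p.data = best_state[k]
        self.best_val_auc_ = float(best_auc)
        self.n_epochs_ = epochs_run
        return self

    def predict_proba(self, X) -> np.ndarray:
        tcrs, peps = _extract_pairs(X)
        p1 = np.asarray(ad.sigmoid(self._predict_logits(tcrs, peps)))
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X) -> np.ndarray:
        tcrs, peps = _extract_pairs(X)
        return self._predict_logits(tcrs, peps)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def embed(self, X) -> dict[str, np.ndarray]:
        """Pooled, aligned and concatenated embeddings for each pair."""
        tcrs, peps = _extract_pairs(X)
        outs = self._encode_batch(tcrs, peps)
        e_p = np.empty((len(outs), self.d_out))
        e_a = np.empty((len(outs), self.d_out))
        for i, (t_out, p_out) in enumerate(outs):
            ep, ea, _ = self._forward_pair(t_out, p_out)
            e_p[i] = (ep.data if isinstance(ep, Tensor) else np.asarray(ep)).ravel()
            e_a[i] = (ea.data if isinstance(ea, Tensor) else np.asarray(ea)).ravel()
        return {"e_protein": e_p, "e_align": e_a, "z": np.hstack([e_p, e_a])}


def train(model: TcrPeptideBindingClassifier, train_set, val_set, cfg: LossConfig):
    """Functional training entry point over an existing estimator.

    Applies the :class:`LossConfig` to the estimator, fits on ``train_set``
    with ``val_set`` as the early-stopping validation data (both
    :class:`PairDataset` or (X, y) tuples), and returns
    ``(model, history)``.
    """
    model = copy.deepcopy(model)
    model.set_params(lambda_align=cfg.lambda_align, learning_rate=cfg.learning_rate,
                     batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
                     patience=cfg.patience, random_state=cfg.seed)
    if isinstance(train_set, PairDataset):
        X_tr, y_tr = train_set, None
    else:
        X_tr, y_tr = train_set
    val = (val_set, None) if isinstance(val_set, PairDataset) else val_set
    model.fit(X_tr, y_tr, validation_data=val)
    return model, model.history_
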