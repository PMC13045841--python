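# crossbind

Cross-attention prediction of T-cell receptor (TCR) – peptide binding, with
SMILES-encoded peptides, leakage-safe peptide-grouped evaluation, two
negative-sampling regimes, and embedding-quality diagnostics.

## The problem

Whether a TCR recognises a peptide presented by the major histocompatibility
complex (pMHC) decides the outcome of an adaptive immune response, and
predicting it computationally underpins neoantigen vaccine design and
engineered T-cell therapies. The β-chain CDR3 loop dominates antigen contact
and serves as the TCR input; the epitope peptide (8–11 residues) is the
second input. Two modelling obstacles shape everything here:

* **Short peptides carry little sequence context.** crossbind converts each
  peptide into a SMILES string — a linear serialisation of its molecular
  graph (`P_molecule = DFS(P_peptide)`) — producing a much longer token
  sequence that encodes connectivity, functional groups and (optionally)
  stereochemistry explicitly.
* **Peptide redundancy leaks labels.** One peptide appears in thousands of
  pairs; a row-level random split puts the same peptide on both sides of the
  evaluation. All splitting here is grouped by peptide identity, so
  validation peptides are never seen in training.

## The model

Both modalities pass through independently parameterised encoder blocks.
For token matrix `X` (TCR residues) resp. `Y` (peptide SMILES tokens):

    X̃ = LN(X)
    MHSA(X̃) = Concat(head_1, …, head_h) W^O,   head_i = softmax(Q_i K_iᵀ / √d_k) V_i
    E_protein = FFN(X̃ + MHSA(X̃)),              FFN(x) = ReLU(x W₁ + b₁) W₂ + b₂

(the FFN is applied to the residual sum directly — no second residual, no
post-norm), followed by mean-pooling and a learnable projection to a fixed
width `d_out` (256 by default). The two embeddings are fused by multi-head
**cross**-attention with the TCR as query and the peptide as key/value:

    Q = E_protein W^Q,  K = E_molecule W^K,  V = E_molecule W^V
    E_align = MHCA(Q, K, V)

and classified by `ŷ = σ(W_MLP [E_protein; E_align] + b_MLP)`. Training
minimises

    L = L_BCE + λ · (1/N) Σ‖E_align − E_protein‖²

with Adam and early stopping on peptide-disjoint validation AUC-ROC. The
alignment term stabilises the TCR-centric fused representation; λ ≥ 0.

Because no deep-learning framework is a dependency, the encoders, fusion and
training loop run on a small reverse-mode autodiff engine over NumPy
(`crossbind._autodiff`), validated by finite-difference gradient checks.
Adapters for external pretrained encoders (protein or chemical language
models) satisfy the same embedding contract but are never downloaded.

Since real benchmark corpora cannot ship with the package, `crossbind.simulate`
generates synthetic CDR3-like TCRs and peptides with a *planted* binding
rule — a hidden residue motif in the TCR paired, under a fixed alphabet
involution, with a complement motif in the peptide — so the full pipeline is
testable end-to-end and the planted signal is provably recoverable.

## Worked example

```python
from crossbind import SyntheticConfig, make_dataset, TcrPeptideBindingClassifier
from crossbind.splits import grouped_split
from crossbind.metrics import classification_metrics, embedding_diagnostics

cfg = SyntheticConfig(n_tcr=1200, n_pep=60, motif_k=3, noise_rate=0.0, seed=0)
dataset, rule = make_dataset(cfg, pairs_per_peptide=40)
train, val = grouped_split(dataset, r=0.2, seed=0)

clf = TcrPeptideBindingClassifier(d_model=16, d_out=16, ffn_hidden=32,
                                  learning_rate=1e-2, max_epochs=10,
                                  patience=5, random_state=0)
clf.fit(train, validation_data=(val, None))
rep = classification_metrics(clf.predict_proba(val)[:, 1], val.df["label"])
diag = embedding_diagnostics(clf.embed(val)["z"], k=2, n_test=48, seed=0)
```

Output of this exact script:

```
pairs: 2400  positives: 600  unique peptides: 60
hidden motif: EHK -> peptide complement: TQN
best validation AUC-ROC: 0.930 after 10 epochs
val metrics: auc_roc=0.930 acc=0.671 recall=0.013 precision=1.000 f1=0.025 auc_pr=0.861
embedding diagnostics: hopkins=0.86 cts=0.95 silhouette=0.50 chi=643.4
```

The held-out peptides were never seen in training, yet ranking is strong
(AUC-ROC 0.93): the model recovered the planted cross-modality rule. The
threshold metrics at 0.5 are conservative because positives are a quarter of
the data — AUC-ROC and AUC-PR are the primary measures. The fused
embeddings of the validation pairs show clear cluster structure (Hopkins
0.86 against ~0.5 for structureless data; CTS 0.95 against ~0 for uniform).

A command-line interface mirrors the library:

```sh
crossbind simulate --n-tcr 1200 --n-pep 60 --seed 0 --out pairs.tsv
crossbind split --pairs pairs.tsv --r 0.2 --seed 0 --out splits/
crossbind sample-negatives --pairs pos.tsv --regime random --ratio 1 --seed 0 --out all.tsv
crossbind convert-smiles --in peptides.txt --out peptides.smi
crossbind train --pairs pairs.tsv --config cfg.yaml --out run/
crossbind embed-metrics --embeddings emb.tsv --n-test 100 --seed 0 --out diag.json
```

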