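# Methods

## Scope and data model

crossbind predicts a binary binding outcome for a (TCR β-chain CDR3,
peptide) pair. The unit of data is the labeled pair record; tables of such
records (`PairDataset`) are the unit of splitting, negative sampling and
training. The peptide string is its own group identifier: every split
operation is grouped on it, because peptide redundancy — not TCR redundancy
— is what leaks label structure across evaluation boundaries in this
problem.

## Encoders

Each modality has its own encoder stack over character-level tokens:
residues for the TCR, SMILES tokens (bracket atoms, two-letter halogens,
ring digits, bonds and parentheses as single tokens) for the peptide.
Tokens are embedded by a learnable lookup table plus fixed sinusoidal
positional encodings. A block computes `FFN(LN(X) + MHSA(LN(X)))` exactly
as written: the feed-forward network consumes the residual sum and there is
no second residual connection or post-normalisation. This deviates from the
standard transformer block deliberately; the printed composition is the
model. Blocks can be stacked (`depth`, default 1).

How the `L × d` token matrix becomes one fixed-width vector is a genuinely
open design point. We mean-pool the token outputs and apply a learnable
linear map to `d_out` (default 256): the simplest reduction whose
order-sensitivity is carried entirely by the positional encodings upstream.

The SMILES vocabulary is closed under the converter (every token any
peptide can produce appears in the 20 single-residue conversions), and an
UNK entry absorbs anything foreign; the residue vocabulary is strict.

Adapters for external pretrained encoders (a protein language model for the
TCR, a chemical language model for SMILES) implement the same
sequence-to-vector contract — a user-supplied embedding table or callable,
projected to `d_out` by a fixed seeded linear map when widths differ — so
the fusion stage is backend-agnostic. Nothing is downloaded; a missing
source is an explicit error that points at the built-in backend.

## Peptide → SMILES

The conversion walks the backbone N→C, emitting per-residue units
`N[C@@H](side)C(=O)` condensed through amide bonds, glycine without a
stereocentre, proline as its backbone ring, and the terminal carboxyl
retained. This is one valid depth-first serialisation of the linear peptide
graph; any other DFS order denotes the same molecule after
canonicalisation, which is why tests compare RDKit-canonicalised forms
rather than raw strings. With `stereo=True` (default) α-carbons are written
L-configured and the Thr/Ile side-chain centres follow the biological
isomers; the test suite verifies molecule-level identity against RDKit's
own sequence-built peptides for every residue and random peptides.
Non-canonical letters (B, J, O, U, X, Z) are rejected, not guessed. No
cyclic or modified peptides, no 3-D conformers.

## Fusion and head

Cross-attention takes queries from the protein side and keys/values from
the molecule side. Two granularities exist because the right one is
ambiguous when pooled embeddings are vectors but attention is defined over
matrices:

* `pooled` (default): each embedding is a length-1 token sequence. The
  softmax over a single key is identically 1, so cross-attention
  degenerates to a deterministic linear map of the molecule embedding —
  asserted exactly in tests. A corollary worth knowing: in this mode the
  gradients of W^Q and W^K are identically zero (the attention weights are
  constant), and the learnable fusion lives in W^V/W^O. This mode keeps the
  alignment loss well-formed on vectors and is the default.
* `tokens`: the pre-pooling token matrices are fused, the attended output
  mean-pooled and projected to `d_out`. Here the softmax is non-trivial and
  all four projections receive gradient (finite-difference-checked).

The classifier is a single affine map plus sigmoid over
`z = [e_protein; e_align]`; its output is clamped to stay strictly inside
(0, 1) at extreme logits. An optional hidden layer is deliberately absent
by default.

## Objective and training

`L = BCE + λ · mean‖e_align − e_protein‖²`. Log arguments in the public
BCE are clamped at 1e-12; the training path uses the numerically stable
softplus form on logits, and tests confirm both agree. Defaults: λ = 0.1,
Adam with learning rate 1e-3, batch 64, patience 5 — these hyperparameters
are this package's choices, selected once as ordinary values for a model of
this size, and all config-overridable.

Training is seeded end to end (parameter initialisation, shuffling, the
internal validation split) and single-threaded NumPy, so runs are
bit-reproducible. Early stopping monitors peptide-disjoint validation
AUC-ROC; the best checkpoint is restored. When `fit` has to carve its own
validation split and the grouped draw strands a single class in validation
(possible on small datasets), it re-permutes on a derived seed rather than
failing; an explicitly supplied single-class validation set is still an
error, because AUC is undefined there.

Because no autodiff framework is a dependency, gradients come from a small
reverse-mode tape over NumPy arrays (`crossbind._autodiff`) with a
hand-written Adam. Every fused backward rule (softmax, layer norm,
embedding gather) is finite-difference-checked in the test suite, as is the
composite loss gradient for every parameter group of the assembled model.

## Negative sampling

Random control: negatives are uniform draws from the cross product of the
TCR and peptide pools *of the positive training rows*, rejected on
collision with positives or earlier draws; the emitted set has exactly
`round(ratio · |positives|)` members (ratio defaults to 1 — equal numbers —
making the proportionality explicit). Sampling is with replacement across
draws but the emitted set is deduplicated, since the negatives are defined
as a set. Whether deduplication is the historical convention is unknowable
from descriptions alone; the set reading is the one consistent with the
defining equations. Reference control: verified non-binders are read from a
table; a pair listed on both sides is an inconsistency and raises, naming
the pair. Epitope-frequency-guided and structure-informed sampling are out
of scope.

## Splitting protocols

`grouped_split` implements the accumulate-until-covered procedure
literally: permute unique peptides, add them to the validation group until
the covered row count first reaches `⌈rN⌉`. The guarantee (no peptide
overlap) and the minimal-stopping property are asserted over randomised
inputs. A permutation that needs every peptide to reach the target would
leave the training side empty; that case raises rather than returning a
degenerate split. `grouped_kfold` partitions peptides into k blocks by
greedy bin-packing (descending row count into the lightest block, seeded
shuffle as tie-break) — the packing rule is our choice, and it bounds the
fold-size spread by the largest single-peptide row count. The few-shot
protocol keeps a seeded fraction of training peptides (`seen_ratio`) and at
most `pairs_per_peptide` rows per kept peptide, uniformly without
replacement; evaluation peptides are untouched. Hard disjointness between
any supplied test table and train+validation is an error on violation, not
a warning. No label stratification within folds.

## Embedding diagnostics

Hopkins score: N_T sampled data points (nearest-neighbour distance to the
rest of the data, self excluded) against N_T uniform reference points in
the axis-aligned bounding box (nearest-data distance); `HS = D_R/(D_R+D_T)`.
The CTS uses the same machinery with *squared* Euclidean distances and the
normalisation `2·max(ratio − 0.5, 0)`. The two sections describing these
statistics use different distance conventions, and each implementation
follows its own section's wording; their internal consistency on a shared
draw is asserted in tests. Degenerate all-coincident data returns 1.0 with
a warning. Default `N_T = min(100, n/10)`, floored at 10 — a choice, since
no subset size is canonical.

Silhouette and Calinski–Harabasz are computed from their definitions
(singleton clusters score 0; the 0/0 silhouette convention is 0; vanishing
within-cluster scatter returns a large finite sentinel with a warning) and
are cross-checked against scikit-learn's implementations and brute-force
loop oracles. The bundled diagnostics run seeded k-means with k = 2 for
SI/CHI — matching how such diagnostics are applied to binding/non-binding
embeddings — and HS/CTS on the raw points. t-SNE plotting is out of scope;
the CLI only dumps embeddings.

AUC-ROC uses tie-averaged ranks (equals the Mann–Whitney pair-count
statistic, asserted on fixtures); AUC-PR is step-integrated average
precision; thresholded metrics use 0.5.

## The synthetic generator

The generator emulates the surface statistics of real inputs: CDR3-like β
sequences (`C…F` frame, 10–20 residues — the frame is cosmetic and plays no
role in the rule) and peptides of 8–11 residues. The binding rule plants
one hidden motif `m` (default length 3): a pair binds iff `m` occurs in the
TCR and its residue-wise complement — under a fixed, arbitrary involution
of the 20-letter alphabet — occurs in the peptide. Labels optionally flip
with probability `noise_rate`.

The pair-table construction is deliberate: half the peptides carry the
complement motif, and motif-bearing TCRs are paired with bindable and
non-bindable peptides in equal measure. Consequently neither modality alone
separates the classes (asserted in tests), while an *additive* combination
of the two modality signals does. That matches what the default pooled
architecture can express — the head is affine over `[e_protein; e_align]`
and pooled cross-attention is linear in the molecule embedding — so the
planted signal is recoverable by the model whose recovery the tests claim,
and destroying the peptide-SMILES correspondence (the randomised-SMILES
control) measurably degrades it. A rule requiring XOR-like motif matching
would be unlearnable by this architecture and would test nothing.

What the generator does *not* emulate: V/J gene usage, realistic length or
amino-acid composition distributions, binding degeneracy across related
epitopes, or experimental label noise structure. Passing tests therefore
demonstrate that the machinery recovers a recoverable cross-modality
signal under leakage-safe evaluation — not that any particular accuracy
carries over to real repertoires.

## Problem sizes and numerical choices

The signal-recovery benchmark uses 60 peptides × 40 pairs (2400 rows, 25%
positive), a tiny model (d_model 16, d_out 16, 2 heads, FFN 32, learning
rate 1e-2), at most 10 epochs, three seeds — sizes chosen so the whole
suite runs comfortably on one CPU while leaving the recovery margin wide
(observed AUCs ≈ 0.89–0.93 against the 0.80 bar). Attention oracles use
L ≤ 5, d ≤ 8, h ≤ 2 at 1e-6; cluster-metric oracles N ≤ 30 at 1e-9; the
uniform-data calibration uses 20 seeds of 1000 points in 8 dimensions with
N_T = 100. Layer-norm ε is 1e-5; parameter initialisation is scaled
Gaussian (1/√fan-in).

## Known limitations

* The built-in encoders are deliberately small; they stand in for
  large pretrained encoders architecturally, not in capacity.
* Pooled-mode cross-attention is linear in the molecule embedding; genuine
  token-level attention requires `fusion_granularity="tokens"`.
* Training is pure Python/NumPy per-sample; it is sized for thousands of
  pairs, not hundreds of thousands.
* Reference-control negatives require an external table of verified
  non-binders; none ships with the package.
* Single-label binary outcome only: no binding affinity regression, no
  MHC context, no α-chain.
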