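"""Negative-pair construction and the SMILES ablation input variants.

Two negative-sampling regimes are supported.  The *random control* draws
(TCR, peptide) pairs uniformly from the training pools, rejecting any pair
present among the positives; the number of negatives is an explicit ratio
of the positive count (default 1, i.e. equal numbers).  The *reference
control* loads verified non-binding pairs from a table instead.  Random
negatives are harder: a random pairing may in truth bind, so labels are
noisier than curated non-binders.

Emitted random negatives form a set (no duplicates); draws are rejected on
collision with either the positives or earlier negatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import PairDataset
from .smiles import peptide_to_smiles

__all__ = [
    "SamplingSpec",
    "ModelInputSpec",
    "sample_random_negatives",
    "load_reference_negatives",
    "ablation_variant",
]


@dataclass(frozen=True)
class SamplingSpec:
    """Negative-sampling regime, negatives-per-positive ratio and seed."""

    regime: str = "random"  # "random" | "reference"
    ratio: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.regime not in ("random", "reference"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")


def sample_random_negatives(positives: PairDataset, spec: SamplingSpec) -> PairDataset:
    """Random-control negatives: uniform pairs from the positives' own pools.

    Draws from ``TCR_train x Pep_train`` (the pools observed in the positive
    rows), excludes every positive pair, deduplicates, and emits exactly
    ``round(ratio * |positives|)`` label-0 records.  Deterministic under the
    spec seed.  Raises if the admissible pair space is too small.
    """
    if len(positives) == 0:
        raise ValueError("positives must be non-empty")
    df = positives.df
    tcrs = pd.unique(df["tcr"])
    peps = pd.unique(df["peptide"])
    pos_pairs = set(zip(df["tcr"], df["peptide"]))
    n_needed = int(round(spec.ratio * len(df)))
    n_space = len(tcrs) * len(peps)
    # every positive pair lies inside the cross space by construction
    n_admissible = n_space - len(pos_pairs)
    if n_admissible < n_needed:
        raise ValueError(
            f"cannot draw {n_needed} negatives: only {n_admissible} admissible "
            f"non-positive pairs exist in the {len(tcrs)} x {len(peps)} pool"
        )

    rng = np.random.default_rng(spec.seed)
    chosen: set[tuple[str, str]] = set()
    out: list[tuple[str, str, int]] = []
    # rejection sampling; fall back to enumeration when the space is small
    max_draws = 50 * n_needed + 1000
    draws = 0
    while len(out) < n_needed and draws < max_draws:
        t = tcrs[int(rng.integers(len(tcrs)))]
        p = peps[int(rng.integers(len(peps)))]
        draws += 1
        if (t, p) in pos_pairs or (t, p) in chosen:
            continue
        chosen.add((t, p))
        out.append((t, p, 0))
    if len(out) < n_needed:
        admissible = [(t, p) for t in tcrs for p in peps
                      if (t, p) not in pos_pairs and (t, p) not in chosen]
        extra = rng.choice(len(admissible), size=n_needed - len(out), replace=False)
        out.extend((*admissible[i], 0) for i in extra)
    return PairDataset.from_records(
        out, provenance={"seed": spec.seed, "generator": "random_negatives",
                         "ratio": spec.ratio, "n_positives": len(df)}
    )


def load_reference_negatives(table, positives: PairDataset | None = None) -> PairDataset:
    """Reference-control negatives from a table of verified non-binding pairs.

    ``table`` is a TSV path or DataFrame with ``tcr`` and ``peptide``
    columns.  Every record is labeled 0.  If ``positives`` is supplied, any
    pair listed on both sides is an inconsistency and raises, naming the
    pair.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep="\t", dtype=str)
    if df.empty:
        return PairDataset(pd.DataFrame(columns=["tcr", "peptide", "label"]),
                           provenance={"generator": "reference_negatives"})
    df = df[["tcr", "peptide"]].assign(label=0)
    if positives is not None and len(positives):
        pos_pairs = set(zip(positives.df["tcr"], positives.df["peptide"]))
        for t, p in zip(df["tcr"], df["peptide"]):
            if (t, p) in pos_pairs:
                raise ValueError(
                    f"pair ({t!r}, {p!r}) is listed both as a positive and as a "
                    "reference negative"
                )
    return PairDataset(df, provenance={"generator": "reference_negatives"})


@dataclass(frozen=True)
class ModelInputSpec:
    """How the peptide branch consumes peptides for one run.

    ``peptide_input`` is ``"smiles"`` (chemical line notation through the
    molecule encoder) or ``"sequence"`` (residue tokens through a peptide
    protein-encoder instance).  ``smiles_map`` optionally overrides the
    peptide -> SMILES correspondence (used by the randomised-SMILES control).
    """

    variant: str
    peptide_input: str
    smiles_map: dict | None = None
    stereo: bool = True


def ablation_variant(dataset: PairDataset, variant: str, seed: int = 0,
                     stereo: bool = True) -> ModelInputSpec:
    """Build the model-input spec for one ablation arm.

    ``full``: peptides enter as their own SMILES strings.  ``no_smiles``:
    peptides enter as residue tokens (no SMILES machinery touched).
    ``randomized_smiles``: a seeded permutation reassigns each peptide's
    SMILES to a different peptide's SMILES, fixed for the whole run - the
    SMILES multiset is preserved while the peptide-structure correspondence
    is destroyed.
    """
    if variant == "full":
        return ModelInputSpec(variant=variant, peptide_input="smiles", stereo=stereo)
    if variant == "no_smiles":
        return ModelInputSpec(variant=variant, peptide_input="sequence", stereo=stereo)
    if variant == "randomized_smiles":
        peptides = sorted(set(dataset.df["peptide"]))
        if len(peptides) == 1:
            warnings.warn("only one unique peptide: the SMILES permutation is the identity")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(peptides))
        smiles = [peptide_to_smiles(p, stereo=stereo).text for p in peptides]
        mapping = {peptides[i]: smiles[perm[i]] for i in range(len(peptides))}
        return ModelInputSpec(variant=variant, peptide_input="smiles",
                              smiles_map=mapping, stereo=stereo)
    raise ValueError(f"unknown ablation variant {variant!r}")
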