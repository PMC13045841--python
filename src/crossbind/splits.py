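"""Peptide-level grouped splitting, peptide-disjoint k-fold CV, few-shot subsets.

TCR-peptide pair tables are heavily peptide-redundant: one peptide appears
in many rows.  A row-level random split lets the same peptide sit on both
sides and leaks label structure; all splitting here is therefore grouped by
peptide identity.

``grouped_split`` follows the accumulate-until-covered procedure exactly:
unique peptides are randomly permuted and added to the validation group one
at a time until the covered row count first reaches ``ceil(r * N)``.  The
stopping rule is minimal - removing the last-added peptide drops the count
below the target - and the peptide sets of the two sides are disjoint by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import PairDataset

__all__ = ["SplitSpec", "grouped_split", "grouped_kfold", "few_shot_subset", "assert_peptide_disjoint"]


@dataclass(frozen=True)
class SplitSpec:
    """Validation ratio, fold count, seed and optional few-shot protocol."""

    r: float = 0.2
    k: int = 5
    seed: int = 0
    seen_ratio: float | None = None
    pairs_per_peptide: int | None = None

    def __post_init__(self):
        if not (0.0 < self.r < 1.0):
            raise ValueError("validation ratio must lie strictly in (0, 1)")
        if self.k < 2:
            raise ValueError("k-fold requires k >= 2")


def _frame(dataset) -> pd.DataFrame:
    if isinstance(dataset, PairDataset):
        return dataset.df
    return dataset


def _wrap(dataset, df: pd.DataFrame):
    if isinstance(dataset, PairDataset):
        return PairDataset(df[["tcr", "peptide", "label"]], provenance=dict(dataset.provenance))
    return df.reset_index(drop=True)


def grouped_split(dataset, r: float, seed: int = 0):
    """Split rows into (train, val) with no peptide overlap.

    Permutes the unique peptides, accumulates them into the validation group
    ``S`` until the covered row count ``n(S)`` first satisfies
    ``n >= ceil(r * N)``, then assigns every row whose peptide is in ``S`` to
    validation and the rest to training.
    """
    if not (0.0 < r < 1.0):
        raise ValueError("validation ratio must lie strictly in (0, 1)")
    df = _frame(dataset)
    peptides = pd.unique(df["peptide_id"]) if "peptide_id" in df else pd.unique(df["peptide"])
    key = "peptide_id" if "peptide_id" in df else "peptide"
    if len(peptides) < 2:
        raise ValueError("need at least 2 distinct peptides to form disjoint groups")

    rng = np.random.default_rng(seed)
    order = rng.permutation(peptides)
    counts = df[key].value_counts()
    target = math.ceil(r * len(df))

    selected: list = []
    covered = 0
    for pep in order:
        selected.append(pep)
        covered += int(counts[pep])
        if covered >= target:
            break
    sel = set(selected)
    val_mask = df[key].isin(sel)
    if val_mask.all():
        raise ValueError("validation group swallowed every row; lower r or add peptides")
    return _wrap(dataset, df.loc[~val_mask]), _wrap(dataset, df.loc[val_mask])


def grouped_kfold(dataset, k: int, seed: int = 0):
    """Partition rows into k peptide-disjoint (train, val) folds.

    Peptides are assigned to fold blocks by greedy bin-packing: after a
    seeded shuffle they are ordered by descending row count and each is
    placed in the currently lightest block, balancing fold sizes.  Every row
    appears in exactly one validation fold.
    """
    if k < 2:
        raise ValueError("k-fold requires k >= 2")
    df = _frame(dataset)
    key = "peptide_id" if "peptide_id" in df else "peptide"
    peptides = pd.unique(df[key])
    if len(peptides) < k:
        raise ValueError(f"need at least k={k} distinct peptides, have {len(peptides)}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(peptides)
    counts = df[key].value_counts()
    # stable sort keeps the seeded shuffle as the tie-break among equal counts
    order = sorted(order, key=lambda p: -int(counts[p]))

    loads = np.zeros(k, dtype=int)
    assignment: dict = {}
    for pep in order:
        j = int(np.argmin(loads))
        assignment[pep] = j
        loads[j] += int(counts[pep])

    folds = []
    fold_of = df[key].map(assignment)
    for j in range(k):
        val_mask = fold_of == j
        folds.append((_wrap(dataset, df.loc[~val_mask]), _wrap(dataset, df.loc[val_mask])))
    return folds


def few_shot_subset(train, seen_ratio: float, pairs_per_peptide: int | None, seed: int = 0):
    """Reduce the training side to the few-shot regime.

    Keeps a seeded random fraction ``seen_ratio`` of the unique training
    peptides, and for each kept peptide at most ``pairs_per_peptide`` rows
    (uniform choice without replacement).  ``pairs_per_peptide=None`` keeps
    all rows of the kept peptides.
    """
    if not (0.0 < seen_ratio <= 1.0):
        raise ValueError("seen_ratio must lie in (0, 1]; an empty training set is not usable")
    if pairs_per_peptide is not None and pairs_per_peptide < 1:
        raise ValueError("pairs_per_peptide must be a positive integer")
    df = _frame(train)
    key = "peptide_id" if "peptide_id" in df else "peptide"
    peptides = pd.unique(df[key])
    rng = np.random.default_rng(seed)

    n_keep = int(round(seen_ratio * len(peptides)))
    if n_keep == 0:
        raise ValueError("seen_ratio keeps zero peptides for this dataset")
    kept = set(rng.choice(peptides, size=n_keep, replace=False))

    sub = df.loc[df[key].isin(kept)]
    if pairs_per_peptide is not None:
        picks = []
        for pep, grp in sub.groupby(key, sort=True):
            idx = grp.index.to_numpy()
            if len(idx) > pairs_per_peptide:
                idx = rng.choice(idx, size=pairs_per_peptide, replace=False)
            picks.append(np.sort(idx))
        sub = df.loc[np.concatenate(picks)]
    return _wrap(train, sub)


def assert_peptide_disjoint(*datasets) -> None:
    """Raise if any peptide appears in more than one of the given datasets."""
    seen: dict[str, int] = {}
    for i, ds in enumerate(datasets):
        df = _frame(ds)
        key = "peptide_id" if "peptide_id" in df else "peptide"
        for pep in pd.unique(df[key]):
            if pep in seen and seen[pep] != i:
                raise ValueError(
                    f"peptide {pep!r} appears in datasets {seen[pep]} and {i}; "
                    "hard peptide-level separation is violated"
                )
            seen.setdefault(pep, i)
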