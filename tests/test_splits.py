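"""Peptide-grouped splitting, k-fold CV and few-shot subsampling."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import GroupKFold

from crossbind.splits import (
    SplitSpec,
    assert_peptide_disjoint,
    few_shot_subset,
    grouped_kfold,
    grouped_split,
)


def random_pairs(rng, n_pep=None, rows_per_pep=None):
    n_pep = n_pep or int(rng.integers(3, 12))
    rows = []
    for j in range(n_pep):
        pep = f"PEP{j:03d}"
        count = rows_per_pep or int(rng.integers(1, 15))
        for i in range(count):
            rows.append({"tcr": f"CT{i}F", "peptide": pep, "label": int(rng.integers(2))})
    return pd.DataFrame(rows)


def simple_pairs(counts: dict) -> pd.DataFrame:
    rows = [{"tcr": f"CT{i}F", "peptide": pep, "label": i % 2}
            for pep, c in counts.items() for i in range(c)]
    return pd.DataFrame(rows)


def test_two_peptides_val_gets_exactly_one_group():
    df = simple_pairs({"AAAA": 5, "CCCC": 5})
    for seed in range(10):  # both permutation orders occur across seeds
        train, val = grouped_split(df, r=0.2, seed=seed)
        assert len(val) == 5 and len(train) == 5
        assert val["peptide"].nunique() == 1


def test_single_peptide_cannot_split():
    df = simple_pairs({"AAAA": 10})
    with pytest.raises(ValueError, match="2 distinct peptides"):
        grouped_split(df, r=0.2, seed=0)


@pytest.mark.parametrize("r", [0.1, 0.2, 0.5])
def test_grouped_split_guarantees_on_random_datasets(r):
    rng = np.random.default_rng(17)
    for _ in range(34):
        df = random_pairs(rng)
        if df["peptide"].nunique() < 2:
            continue
        try:
            train, val = grouped_split(df, r=r, seed=int(rng.integers(1000)))
        except ValueError:
            # the permutation needed every peptide to reach the target;
            # an empty training side is rejected rather than returned
            continue
        target = math.ceil(r * len(df))
        # peptide-disjoint by construction
        assert not set(train["peptide"]) & set(val["peptide"])
        assert len(train) + len(val) == len(df)
        # stopping rule: covered >= ceil(rN) ...
        assert len(val) >= target
        # ... and minimal: dropping some (the last-added) val peptide
        # takes the count back below the target
        counts = val["peptide"].value_counts()
        assert any(len(val) - c < target for c in counts.values)


def test_grouped_split_deterministic_under_seed():
    df = random_pairs(np.random.default_rng(1), n_pep=8, rows_per_pep=4)
    a = grouped_split(df, r=0.3, seed=5)
    b = grouped_split(df, r=0.3, seed=5)
    assert a[0].equals(b[0]) and a[1].equals(b[1])


def test_validation_target_respected_at_n_100():
    df = simple_pairs({f"PEP{c}": 10 for c in "ACDEFGHIKL"})  # 100 rows
    _, val = grouped_split(df, r=0.2, seed=0)
    assert len(val) >= 20


# -- k-fold -------------------------------------------------------------------

def test_kfold_leave_one_peptide_out():
    df = simple_pairs({"AAAA": 3, "CCCC": 4, "GGGG": 5})
    folds = grouped_kfold(df, k=3, seed=0)
    val_peps = [set(v["peptide"]) for _, v in folds]
    assert all(len(s) == 1 for s in val_peps)
    assert set.union(*val_peps) == {"AAAA", "CCCC", "GGGG"}


def test_kfold_validation_folds_partition_the_dataset():
    rng = np.random.default_rng(23)
    df = random_pairs(rng, n_pep=11)
    folds = grouped_kfold(df, k=4, seed=3)
    idx_union = []
    for train, val in folds:
        assert not set(train["peptide"]) & set(val["peptide"])
        assert len(train) + len(val) == len(df)
        idx_union.extend(map(tuple, val[["tcr", "peptide"]].itertuples(index=False)))
    assert len(idx_union) == len(df)


def test_kfold_balancing_spread_bounded_by_largest_peptide():
    rng = np.random.default_rng(29)
    for _ in range(10):
        df = random_pairs(rng, n_pep=int(rng.integers(6, 15)))
        k = 3
        if df["peptide"].nunique() < k:
            continue
        folds = grouped_kfold(df, k=k, seed=int(rng.integers(100)))
        sizes = [len(v) for _, v in folds]
        max_pep = df["peptide"].value_counts().max()
        assert max(sizes) - min(sizes) <= max_pep


def test_kfold_matches_sklearn_group_kfold_disjointness_semantics():
    """Independent cross-check: sklearn's GroupKFold enforces the same
    peptide-level exclusivity on identical data."""
    df = random_pairs(np.random.default_rng(31), n_pep=9, rows_per_pep=6)
    ours = grouped_kfold(df, k=3, seed=0)
    gkf = GroupKFold(n_splits=3)
    theirs = list(gkf.split(df, groups=df["peptide"]))
    for (tr, va), (tr_idx, va_idx) in zip(ours, theirs):
        assert not set(va["peptide"]) & set(tr["peptide"])
        assert not set(df.iloc[va_idx]["peptide"]) & set(df.iloc[tr_idx]["peptide"])


def test_kfold_requires_enough_peptides():
    df = simple_pairs({"AAAA": 3, "CCCC": 3})
    with pytest.raises(ValueError, match="at least k=3"):
        grouped_kfold(df, k=3, seed=0)


# -- few-shot -----------------------------------------------------------------

def test_few_shot_identity_when_everything_kept():
    df = random_pairs(np.random.default_rng(2), n_pep=6, rows_per_pep=5)
    out = few_shot_subset(df, seen_ratio=1.0, pairs_per_peptide=None, seed=0)
    assert len(out) == len(df)


def test_few_shot_seen_ratio_counts_peptides():
    df = simple_pairs({f"PEP{c}": 4 for c in "ACDEFGHIKL"})  # 10 peptides
    out = few_shot_subset(df, seen_ratio=0.2, pairs_per_peptide=None, seed=1)
    assert out["peptide"].nunique() == 2


def test_few_shot_caps_rows_per_peptide():
    df = simple_pairs({"AAAA": 40, "CCCC": 40, "GGGG": 40})
    out = few_shot_subset(df, seen_ratio=1.0, pairs_per_peptide=5, seed=2)
    assert (out["peptide"].value_counts() == 5).all()


def test_few_shot_zero_ratio_rejected():
    df = simple_pairs({"AAAA": 4, "CCCC": 4})
    with pytest.raises(ValueError, match="seen_ratio"):
        few_shot_subset(df, seen_ratio=0.0, pairs_per_peptide=5, seed=0)


def test_few_shot_deterministic():
    df = random_pairs(np.random.default_rng(3), n_pep=10, rows_per_pep=8)
    a = few_shot_subset(df, seen_ratio=0.5, pairs_per_peptide=3, seed=9)
    b = few_shot_subset(df, seen_ratio=0.5, pairs_per_peptide=3, seed=9)
    assert a.equals(b)


# -- hard separation helper ---------------------------------------------------

def test_assert_peptide_disjoint_flags_leakage():
    a = simple_pairs({"AAAA": 2})
    b = simple_pairs({"AAAA": 2, "CCCC": 2})
    with pytest.raises(ValueError, match="AAAA"):
        assert_peptide_disjoint(a, b)
    assert_peptide_disjoint(simple_pairs({"AAAA": 2}), simple_pairs({"CCCC": 2}))


def test_split_spec_invariants():
    with pytest.raises(ValueError):
        SplitSpec(r=0.0)
    with pytest.raises(ValueError):
        SplitSpec(k=1)
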