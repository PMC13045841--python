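"""Synthetic TCR/peptide universes with a planted, recoverable binding rule.

Real TCR-epitope pair collections cannot ship with the package, so every
downstream stage (SMILES conversion, encoders, fusion, sampling, splitting,
training) is exercised on synthetic data generated here.  The generator
emulates the surface statistics of the real inputs - CDR3-like beta-chain
sequences that begin with C and end with F at 10-20 residues, and short
epitope peptides of 8-11 residues - and plants a deterministic binding rule:

    label(tcr, pep) = 1  iff  the hidden motif ``m`` is a substring of the
    TCR and its residue-wise complement ``comp(m)`` is a substring of the
    peptide,

optionally flipped with probability ``noise_rate``.  The complement is taken
under a fixed involution of the 20-letter amino-acid alphabet (the i-th
letter pairs with the (19-i)-th); any deterministic pairing suffices for
signal-recovery tests, and the table is arbitrary by design.

The motif is planted so that *neither modality alone* separates the classes:
half the peptides carry ``comp(m)`` ("bindable"), and motif-bearing TCRs are
paired with bindable and non-bindable peptides in equal measure.  A model
must therefore read both the TCR and the peptide to recover the rule, while
an additive combination of the two modality signals is sufficient - matching
what the pooled cross-attention architecture can express.
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Fixed involution over the alphabet: A<->Y, C<->W, D<->V, E<->T, F<->S,
# G<->R, H<->Q, I<->P, K<->N, L<->M.  Applying it twice is the identity.
RESIDUE_PAIRING = {a: b for a, b in zip(AMINO_ACIDS, AMINO_ACIDS[::-1])}

__all__ = [
    "AMINO_ACIDS",
    "RESIDUE_PAIRING",
    "SyntheticConfig",
    "PairDataset",
    "BindingRule",
    "complement",
    "generate_universe",
    "plant_binding_rule",
    "make_dataset",
]


def complement(seq: str) -> str:
    """Residue-wise complement under the fixed pairing involution."""
    return "".join(RESIDUE_PAIRING[c] for c in seq)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic universe.

    Parameters
    ----------
    n_tcr, n_pep : pool sizes (unique sequences).
    tcr_len_range, pep_len_range : inclusive length bounds in residues.
    motif_k : length of the hidden binding motif.
    noise_rate : probability that a pair's label is flipped.
    seed : master seed; identical configs yield byte-identical datasets.
    bindable_fraction : fraction of peptides carrying the complement motif.
    """

    n_tcr: int = 1200
    n_pep: int = 60
    tcr_len_range: tuple[int, int] = (10, 20)
    pep_len_range: tuple[int, int] = (8, 11)
    motif_k: int = 3
    noise_rate: float = 0.0
    seed: int = 0
    bindable_fraction: float = 0.5

    def __post_init__(self):
        if self.n_tcr < 0 or self.n_pep < 0:
            raise ValueError("pool sizes must be non-negative")
        if not (0.0 <= self.noise_rate < 1.0):
            raise ValueError("noise_rate must be in [0, 1)")
        lo, hi = self.tcr_len_range
        if lo < self.motif_k + 2 or lo > hi:
            raise ValueError("tcr_len_range must fit the C...F frame and the motif")
        lo, hi = self.pep_len_range
        if lo < self.motif_k or lo > hi:
            raise ValueError("pep_len_range must be able to hold the motif")
        if not (0.0 <= self.bindable_fraction <= 1.0):
            raise ValueError("bindable_fraction must be in [0, 1]")


@dataclass
class PairDataset:
    """Labeled (TCR, peptide) records - the unit of splitting and training.

    ``peptide_id`` is the peptide string itself: splits are grouped by
    peptide identity, and the string is its own canonical identifier.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    COLUMNS = ("tcr", "peptide", "label")

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        for col in self.COLUMNS:
            if col not in df.columns:
                raise ValueError(f"PairDataset requires column {col!r}")
        if not df.empty:
            bad = df.loc[~df["label"].isin([0, 1])]
            if len(bad):
                raise ValueError("labels must be binary 0/1")
            alphabet = set(AMINO_ACIDS)
            for col in ("tcr", "peptide"):
                seqs = df[col].astype(str)
                offending = seqs[~seqs.map(lambda s: bool(s) and set(s) <= alphabet)]
                if len(offending):
                    raise ValueError(
                        f"non amino-acid sequence in column {col!r}: {offending.iloc[0]!r}"
                    )
        df = df.assign(peptide_id=df["peptide"].astype(str))
        self.df = df

    # -- container protocol --------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def records(self) -> list[tuple[str, str, int, str]]:
        return list(
            self.df[["tcr", "peptide", "label", "peptide_id"]].itertuples(index=False, name=None)
        )

    @property
    def peptides(self) -> list[str]:
        return list(pd.unique(self.df["peptide_id"]))

    # -- construction / IO ---------------------------------------------------
    @classmethod
    def from_records(cls, records, provenance: dict | None = None) -> "PairDataset":
        df = pd.DataFrame(records, columns=["tcr", "peptide", "label"])
        return cls(df, provenance=dict(provenance or {}))

    @classmethod
    def read_tsv(cls, path, provenance: dict | None = None) -> "PairDataset":
        df = pd.read_csv(path, sep="\t", dtype={"tcr": str, "peptide": str})
        if df.empty and list(df.columns) != list(cls.COLUMNS):
            df = pd.DataFrame(columns=list(cls.COLUMNS))
        return cls(df[list(cls.COLUMNS)], provenance=dict(provenance or {}))

    def to_tsv(self, path) -> None:
        self.df[list(self.COLUMNS)].to_csv(path, sep="\t", index=False)

    def subset(self, mask) -> "PairDataset":
        return PairDataset(self.df.loc[mask, list(self.COLUMNS)], provenance=dict(self.provenance))


@dataclass(frozen=True)
class BindingRule:
    """The planted ground truth: hidden motif and its peptide complement."""

    motif: str
    motif_k: int

    @property
    def peptide_motif(self) -> str:
        return complement(self.motif)

    def truth(self, tcr: str, peptide: str) -> int:
        """Noise-free binding label for an arbitrary pair."""
        return int(self.motif in tcr and self.peptide_motif in peptide)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _unique_pool(rng: np.random.Generator, n: int, make) -> list[str]:
    pool: list[str] = []
    seen: set[str] = set()
    attempts = 0
    limit = 200 * max(n, 1) + 1000
    while len(pool) < n:
        if attempts > limit:
            raise RuntimeError(
                f"could not draw {n} unique sequences after {attempts} attempts; "
                "the requested pool exceeds the available sequence space"
            )
        s = make(rng)
        attempts += 1
        if s not in seen:
            seen.add(s)
            pool.append(s)
    return pool


def generate_universe(cfg: SyntheticConfig) -> tuple[list[str], list[str]]:
    """Draw pools of unique CDR3-like TCRs and short peptides.

    TCRs carry the cosmetic C...F frame of real beta-chain CDR3 loops; the
    frame plays no role in the binding rule.  Deterministic under cfg.seed.
    """
    rng = np.random.default_rng([101, cfg.seed])

    def make_tcr(r):
        length = int(r.integers(cfg.tcr_len_range[0], cfg.tcr_len_range[1] + 1))
        return "C" + _random_seq(r, length - 2) + "F"

    def make_pep(r):
        length = int(r.integers(cfg.pep_len_range[0], cfg.pep_len_range[1] + 1))
        return _random_seq(r, length)

    tcr_pool = _unique_pool(rng, cfg.n_tcr, make_tcr)
    pep_pool = _unique_pool(rng, cfg.n_pep, make_pep)
    return tcr_pool, pep_pool


def _implant(rng: np.random.Generator, seq: str, motif: str, lo: int, hi: int) -> str:
    """Overwrite a random window of seq[lo:hi] with the motif."""
    k = len(motif)
    pos = int(rng.integers(lo, hi - k + 1))
    return seq[:pos] + motif + seq[pos + k:]


def plant_binding_rule(
    tcr_pool: list[str], pep_pool: list[str], cfg: SyntheticConfig
) -> tuple[PairDataset, BindingRule]:
    """Plant the hidden motif into the pools and enumerate the positive pairs.

    Returns the set of noise-free positive pairs over the (implanted) cross
    product together with the :class:`BindingRule` ground truth, so oracle
    tests can interrogate the rule directly.  The input pools are not
    modified; implanted copies are reachable through the returned positives
    and through :func:`make_dataset`.
    """
    if not tcr_pool or not pep_pool:
        raise ValueError("pools must be non-empty")
    rng = np.random.default_rng([202, cfg.seed])
    motif = _random_seq(rng, cfg.motif_k)
    rule = BindingRule(motif=motif, motif_k=cfg.motif_k)

    tcrs, peps = _implanted_pools(tcr_pool, pep_pool, cfg, rule, rng)
    records = [
        (t, p, 1)
        for t in tcrs
        for p in peps
        if rule.truth(t, p)
    ]
    positives = PairDataset.from_records(
        records, provenance={"seed": cfg.seed, "generator": "plant_binding_rule"}
    )
    return positives, rule


def _implanted_pools(tcr_pool, pep_pool, cfg, rule, rng):
    """Implant the motif into half the TCRs and `bindable_fraction` peptides."""
    k = cfg.motif_k
    tcrs = list(tcr_pool)
    n_carrier = len(tcrs) // 2
    carrier_idx = rng.choice(len(tcrs), size=n_carrier, replace=False)
    for i in carrier_idx:
        # keep the C prefix / F suffix intact
        tcrs[i] = _implant(rng, tcrs[i], rule.motif, 1, len(tcrs[i]) - 1)

    peps = list(pep_pool)
    n_bind = int(round(cfg.bindable_fraction * len(peps)))
    bind_idx = rng.choice(len(peps), size=n_bind, replace=False)
    for i in bind_idx:
        peps[i] = _implant(rng, peps[i], rule.peptide_motif, 0, len(peps[i]))
    return tcrs, peps


def make_dataset(
    cfg: SyntheticConfig, pairs_per_peptide: int = 40
) -> tuple[PairDataset, BindingRule]:
    """Build a labeled pair table with `pairs_per_peptide` rows per peptide.

    For each bindable peptide, half of its TCR partners carry the motif
    (positives) and half do not; non-bindable peptides receive the same
    half/half TCR mix but all their rows are negative.  Motif carriage in the
    TCR is therefore uncorrelated with the label marginally over peptides,
    and peptide bindability alone leaves within-peptide labels unexplained -
    the rule is recoverable only from both modalities together.  Labels are
    the rule's truth, then flipped with probability ``noise_rate``.
    """
    tcr_pool, pep_pool = generate_universe(cfg)
    rng = np.random.default_rng([202, cfg.seed])
    motif = _random_seq(rng, cfg.motif_k)
    rule = BindingRule(motif=motif, motif_k=cfg.motif_k)
    tcrs, peps = _implanted_pools(tcr_pool, pep_pool, cfg, rule, rng)

    carriers = [t for t in tcrs if rule.motif in t]
    noncarriers = [t for t in tcrs if rule.motif not in t]
    if not carriers or not noncarriers:
        raise RuntimeError("degenerate universe: need both motif-bearing and plain TCRs")

    rows = []
    n_half = pairs_per_peptide // 2
    for pep in peps:
        chosen = list(rng.choice(carriers, size=n_half, replace=len(carriers) < n_half))
        chosen += list(
            rng.choice(noncarriers, size=pairs_per_peptide - n_half,
                       replace=len(noncarriers) < pairs_per_peptide - n_half)
        )
        for t in chosen:
            rows.append((t, pep, rule.truth(t, pep)))

    labels = np.array([r[2] for r in rows])
    if cfg.noise_rate > 0:
        flip = rng.random(len(labels)) < cfg.noise_rate
        labels = np.where(flip, 1 - labels, labels)
    rows = [(t, p, int(l)) for (t, p, _), l in zip(rows, labels)]
    dataset = PairDataset.from_records(
        rows,
        provenance={
            "seed": cfg.seed,
            "generator": "make_dataset",
            "config": dataclasses.asdict(cfg),
            "pairs_per_peptide": pairs_per_peptide,
        },
    )
    return dataset, rule
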