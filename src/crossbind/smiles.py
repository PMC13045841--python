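"""Peptide-to-SMILES conversion and character/SMILES tokenisation.

Short epitope peptides (8-11 residues) carry little context for a sequence
model; serialising the peptide's molecular graph as a SMILES string yields a
longer input that encodes connectivity and functional groups explicitly.
The conversion walks the backbone N- to C-terminus, condensing per-residue
units through amide bonds and keeping the terminal carboxyl, which is one
valid depth-first serialisation of the linear peptide graph (all such
serialisations denote the same molecule up to canonicalisation).

With ``stereo=True`` (the default) the alpha carbons are written in the
L-configuration, and side-chain stereocentres (Thr, Ile) follow the common
biological isomers.  Non-canonical residue letters (B, J, O, U, X, Z) are
rejected rather than guessed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .simulate import AMINO_ACIDS

__all__ = [
    "SmilesString",
    "TokenSequence",
    "peptide_to_smiles",
    "tokenize_protein",
    "tokenize_smiles",
    "SMILES_TOKEN_RE",
]

# Side chains as written from the alpha carbon, L-isomers.  Glycine and
# proline are handled specially (no side chain / backbone ring).
_SIDE_CHAINS = {
    "A": "C",
    "R": "CCCNC(=N)N",
    "N": "CC(N)=O",
    "D": "CC(=O)O",
    "C": "CS",
    "E": "CCC(=O)O",
    "Q": "CCC(N)=O",
    "H": "Cc1c[nH]cn1",
    "I": "[C@@H](C)CC",
    "L": "CC(C)C",
    "K": "CCCCN",
    "M": "CCSC",
    "F": "Cc1ccccc1",
    "S": "CO",
    "T": "[C@H](O)C",
    "W": "Cc1c[nH]c2ccccc12",
    "V": "C(C)C",
    "Y": "Cc1ccc(O)cc1",
}


@dataclass(frozen=True)
class SmilesString:
    """A SMILES line notation plus the peptide it was derived from."""

    text: str
    source_peptide: str

    def __post_init__(self):
        if not self.text:
            raise ValueError("SMILES text must be non-empty")

    def __str__(self) -> str:
        return self.text


@dataclass(frozen=True)
class TokenSequence:
    """An ordered token list for one input modality."""

    tokens: tuple[str, ...]
    modality: str  # "protein" | "smiles"

    def __post_init__(self):
        if self.modality not in ("protein", "smiles"):
            raise ValueError(f"unknown modality {self.modality!r}")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    @property
    def text(self) -> str:
        return "".join(self.tokens)


def _residue_unit(residue: str, stereo: bool) -> str:
    """SMILES for one residue, N to carbonyl, ready for amide condensation."""
    if residue == "G":
        return "NCC(=O)"
    if residue == "P":
        alpha = "[C@H]" if stereo else "C"  # ring-closure order flips the symbol
        return f"N1CCC{alpha}1C(=O)"
    side = _SIDE_CHAINS[residue]
    if not stereo:
        side = side.replace("[C@@H]", "C").replace("[C@H]", "C")
    alpha = "[C@@H]" if stereo else "C"
    return f"N{alpha}({side})C(=O)"


def peptide_to_smiles(peptide: str, stereo: bool = True) -> SmilesString:
    """Convert an amino-acid sequence to the linear peptide's SMILES.

    Residue units are emitted N- to C-terminus and condensed through amide
    bonds; the terminal carboxyl oxygen is retained, so e.g. ``"G"`` gives
    ``"NCC(=O)O"`` (glycine, C2H5NO2) and ``"GG"`` gives
    ``"NCC(=O)NCC(=O)O"`` (2 x Gly - 1 x H2O).  Deterministic.

    Raises
    ------
    ValueError
        If the peptide is empty or contains a non-canonical residue letter
        (the error names the offending character and its position).
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    for i, ch in enumerate(peptide):
        if ch not in AMINO_ACIDS:
            raise ValueError(
                f"unknown residue {ch!r} at position {i} in peptide {peptide!r}"
            )
    body = "".join(_residue_unit(ch, stereo) for ch in peptide)
    return SmilesString(text=body + "O", source_peptide=peptide)


def tokenize_protein(seq: str) -> TokenSequence:
    """One token per residue character, order preserved."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    for i, ch in enumerate(seq):
        if ch not in AMINO_ACIDS:
            raise ValueError(f"non amino-acid character {ch!r} at position {i}")
    return TokenSequence(tokens=tuple(seq), modality="protein")


# The widely used SMILES tokenisation regex: bracket atoms as single tokens,
# two-letter organic-subset halogens (Cl, Br) as single tokens, ring-bond
# digits, bonds and parentheses as individual tokens.
SMILES_TOKEN_RE = re.compile(
    r"(\[[^\[\]]*\]|Br|Cl|%\d{2}|[BCNOSPFI]|[bcnosp]|[()=#\-+.\\/:~@*$]|\d)"
)


def tokenize_smiles(s: SmilesString | str) -> TokenSequence:
    """Tokenise a SMILES string following the standard regex convention.

    Joining the tokens reconstructs the input exactly.  Unmatched square
    brackets or parentheses raise ``ValueError``.
    """
    text = s.text if isinstance(s, SmilesString) else s
    if not text:
        raise ValueError("SMILES must be non-empty")
    depth = 0
    in_bracket = False
    for ch in text:
        if ch == "[":
            if in_bracket:
                raise ValueError("nested '[' in SMILES")
            in_bracket = True
        elif ch == "]":
            if not in_bracket:
                raise ValueError("unmatched ']' in SMILES")
            in_bracket = False
        elif ch == "(" and not in_bracket:
            depth += 1
        elif ch == ")" and not in_bracket:
            depth -= 1
            if depth < 0:
                raise ValueError("unmatched ')' in SMILES")
    if in_bracket:
        raise ValueError("unmatched '[' in SMILES")
    if depth != 0:
        raise ValueError("unmatched '(' in SMILES")

    tokens = SMILES_TOKEN_RE.findall(text)
    if "".join(tokens) != text:
        leftover = re.sub(SMILES_TOKEN_RE, "", text)
        raise ValueError(f"untokenisable SMILES characters: {leftover!r}")
    return TokenSequence(tokens=tuple(tokens), modality="smiles")
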