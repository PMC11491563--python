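"""Nucleotide alphabet primitives.

IUPAC degeneracy, complementation, strand operations and bisulfite
conversion.  Every other module builds on the primitives defined here, so
the semantics are deliberately narrow: DNA only (U is normalised to T on
input), no gaps, no quality information.

Each IUPAC symbol denotes a non-empty subset of {A, C, G, T}.  Two symbols
*match* when their base subsets intersect; this is the single notion of
base compatibility used throughout the package, for concrete and
degenerate characters alike.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Literal

__all__ = [
    "IUPAC_SETS",
    "CODE_BITS",
    "COMPLEMENT",
    "CONCRETE",
    "Sequence",
    "SequenceParseError",
    "iupac_match",
    "is_stable_g_mismatch",
    "reverse_complement",
    "bisulfite_convert",
    "clean_primer_sequence",
    "clean_template_sequence",
    "expand_degenerate",
]

#: IUPAC nucleotide codes and the concrete bases each denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "M": frozenset("AC"),
    "R": frozenset("AG"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "V": frozenset("ACG"),
    "H": frozenset("ACT"),
    "D": frozenset("AGT"),
    "B": frozenset("CGT"),
    "N": frozenset("ACGT"),
}

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

#: Bitmask encoding of each code (bit per concrete base); two codes match
#: iff the bitwise AND of their masks is non-zero.
CODE_BITS: dict[str, int] = {
    sym: sum(_BASE_BIT[b] for b in bases) for sym, bases in IUPAC_SETS.items()
}

_BITS_TO_CODE = {bits: sym for sym, bits in CODE_BITS.items()}

#: Complement of each code, defined element-wise on its base subset
#: (R = {A,G} -> {T,C} = Y, and so on).  An involution by construction.
COMPLEMENT: dict[str, str] = {
    sym: _BITS_TO_CODE[
        sum(_BASE_BIT[{"A": "T", "T": "A", "C": "G", "G": "C"}[b]] for b in bases)
    ]
    for sym, bases in IUPAC_SETS.items()
}

#: The four concrete (non-degenerate) bases.
CONCRETE = frozenset("ACGT")

_COMPLEMENT_TABLE = str.maketrans(COMPLEMENT)

_VALID = set(IUPAC_SETS)


class SequenceParseError(ValueError):
    """Raised when input sequence text contains characters outside the
    IUPAC nucleotide alphabet in a context where they cannot be repaired."""


def iupac_match(a: str, b: str) -> bool:
    """True iff the base subsets of codes ``a`` and ``b`` intersect.

    Symmetric and reflexive over the 15 IUPAC codes; N matches everything.
    Raises :class:`SequenceParseError` for characters outside the alphabet.
    """
    try:
        return (CODE_BITS[a] & CODE_BITS[b]) != 0
    except KeyError:
        bad = a if a not in CODE_BITS else b
        raise SequenceParseError(f"invalid nucleotide code {bad!r}") from None


def is_stable_g_mismatch(primer_base: str, template_base: str) -> bool:
    """Whether a primer/template duplex opposition is a stable guanine
    mismatch (G*G, G*T or G*A).

    ``template_base`` is the base physically opposite the primer base in
    the duplex (not the same-sense template character).  Both bases must be
    concrete; degenerate codes never qualify.  Stable guanine mismatches
    hybridise far better than other mispairs and are down-weighted in hit
    scoring.
    """
    return (
        primer_base == "G"
        and template_base in ("G", "T", "A")
        and template_base in CONCRETE
    )


@dataclass
class Sequence:
    """A named DNA sequence with an explicit topology."""

    id: str
    residues: str
    topology: Literal["linear", "circular"] = "linear"

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.residues)


def clean_primer_sequence(text: str, name: str = "primer") -> str:
    """Uppercase, normalise U->T and validate a primer/probe sequence.

    Primers must be clean: any character outside the IUPAC alphabet is an
    error naming the offending character and its 1-based position.
    """
    s = text.strip().upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in _VALID:
            raise SequenceParseError(
                f"{name}: invalid character {ch!r} at position {i + 1}"
            )
    return s


def clean_template_sequence(text: str) -> tuple[str, int]:
    """Uppercase and normalise a template sequence, repairing stray
    characters.

    Genome files occasionally contain gaps or other stray characters;
    anything outside the IUPAC alphabet is replaced by N.  Returns the
    cleaned sequence and the number of replacements (callers log a warning
    when non-zero).
    """
    s = text.upper().replace("U", "T")
    out = []
    replaced = 0
    for ch in s:
        if ch in _VALID:
            out.append(ch)
        else:
            out.append("N")
            replaced += 1
    return "".join(out), replaced


def reverse_complement(s: str) -> str:
    """Reverse complement, with degenerate codes complemented subset-wise
    (R<->Y, M<->K, S<->S, W<->W, N<->N).  An involution."""
    return s.translate(_COMPLEMENT_TABLE)[::-1]


def bisulfite_convert(s: str, strand: Literal["plus", "minus"]) -> str:
    """Image of a fully bisulfite-converted template strand, assuming all
    CpG cytosines are methylated (hence retained) and all other cytosines
    are converted.

    ``plus``: every C not immediately followed by G becomes T.
    ``minus``: the plus-strand image of converting the complementary
    strand, i.e. every G not immediately preceded by C becomes A.

    Output length equals input length.  Only literal C/G take part;
    degenerate characters pass through unchanged.
    """
    if strand == "plus":
        return re.sub(r"C(?!G)", "T", s)
    if strand == "minus":
        return re.sub(r"(?<!C)G", "A", s)
    raise ValueError(f"strand must be 'plus' or 'minus', got {strand!r}")


def expand_degenerate(s: str, cap: int | None = None) -> list[str] | None:
    """All concrete sequences denoted by ``s``.

    Returns ``None`` (instead of exploding) when the expansion count would
    exceed ``cap``.  Expansion order is deterministic (alphabetical per
    position, leftmost position slowest).
    """
    count = 1
    sets = []
    for ch in s:
        bases = sorted(IUPAC_SETS[ch])
        sets.append(bases)
        count *= len(bases)
        if cap is not None and count > cap:
            return None
    out = [""]
    for bases in sets:
        out = [prefix + b for prefix in out for b in bases]
    return out
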