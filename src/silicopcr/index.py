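"""Hash index of primer k-mers with one-mismatch-tolerant lookup.

The index stores every overlapping k-mer window of every primer *and* of
every primer's reverse complement, so a single pass over the template finds
binding sites on both strands.  One mismatch per k-mer is tolerated through
a pigeonhole split: each window is keyed by its two halves, and a query
word matching either half exactly is verified against the full window.
Degenerate windows are expanded into the concrete half-words they denote.

k may be 9 or 12.  The longer word is faster on large templates; the
one-mismatch tolerance means it costs no sensitivity as long as hits carry
at most one mismatch per k-mer span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

from .seqcore import (
    CODE_BITS,
    clean_primer_sequence,
    expand_degenerate,
    reverse_complement,
)

__all__ = [
    "PRIMER_MIN_LEN",
    "PRIMER_MAX_LEN",
    "ALLOWED_K",
    "Primer",
    "make_primer",
    "KmerIndex",
    "build_index",
    "query",
    "default_k",
]

logger = logging.getLogger(__name__)

PRIMER_MIN_LEN = 12
PRIMER_MAX_LEN = 500
ALLOWED_K = (9, 12)

#: Hard cap on concrete expansions indexed per window.  Windows more
#: degenerate than this (e.g. N-runs) are indexed under their
#: least-degenerate half only.
WINDOW_EXPANSION_CAP = 4**6

#: A posting locates one indexed window: (primer index, offset of the
#: window start within the oriented primer, orientation).  Orientation '+'
#: means the window was taken from the primer as written (a match is a
#: plus-strand binding site); '-' means it came from the primer's reverse
#: complement.
Posting = tuple[int, int, str]


@dataclass(frozen=True)
class Primer:
    """One oligonucleotide, possibly degenerate."""

    id: str
    residues: str
    role: Literal["primer", "probe"] = "primer"

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.residues)


def make_primer(
    id: str, residues: str, role: Literal["primer", "probe"] = "primer"
) -> Primer:
    """Validate and normalise one primer/probe (length 12..500, IUPAC
    alphabet only)."""
    seq = clean_primer_sequence(residues, name=id)
    if not PRIMER_MIN_LEN <= len(seq) <= PRIMER_MAX_LEN:
        raise ValueError(
            f"{id}: primer length {len(seq)} outside allowed range "
            f"{PRIMER_MIN_LEN}..{PRIMER_MAX_LEN}"
        )
    return Primer(id=id, residues=seq, role=role)


def default_k(primers: list[Primer]) -> int:
    """12 when the shortest primer is at least 16 nt, else 9.

    Longer words scan faster; the shorter word keeps short primers findable
    (a 12-mer primer has a single 12-mer window, which leaves the pigeonhole
    guarantee no room)."""
    shortest = min(len(p.residues) for p in primers)
    return 12 if shortest >= 16 else 9


class KmerIndex:
    """Pigeonhole hash of all oriented primer windows.

    Attributes
    ----------
    k : word length (9 or 12)
    primers : the indexed primer list (order defines posting primer indices)
    capped_primers : indices of primers with at least one window too
        degenerate to index in full; lookups for these are not guaranteed
        to tolerate a mismatch in every window.
    """

    def __init__(self, primers: list[Primer], k: int):
        if k not in ALLOWED_K:
            raise ValueError(f"k must be one of {ALLOWED_K}, got {k}")
        if not primers:
            raise ValueError("cannot build an index from an empty primer list")
        shortest = min(len(p.residues) for p in primers)
        if k > shortest:
            raise ValueError(
                f"k={k} exceeds the shortest primer length ({shortest})"
            )
        self.k = k
        self.h = (k + 1) // 2  # left-half length (right half is k - h)
        self.primers = list(primers)
        self.capped_primers: set[int] = set()
        self._oriented: dict[tuple[int, str], str] = {}
        self._left: dict[str, list[Posting]] = {}
        self._right: dict[str, list[Posting]] = {}
        self._build()

    def _build(self) -> None:
        for pix, primer in enumerate(self.primers):
            for orient in ("+", "-"):
                seq = (
                    primer.residues
                    if orient == "+"
                    else reverse_complement(primer.residues)
                )
                self._oriented[(pix, orient)] = seq
                for off in range(len(seq) - self.k + 1):
                    self._add_window(pix, orient, off, seq[off : off + self.k])

    def _add_window(self, pix: int, orient: str, off: int, window: str) -> None:
        posting: Posting = (pix, off, orient)
        lh, rh = window[: self.h], window[self.h :]
        le = expand_degenerate(lh, WINDOW_EXPANSION_CAP)
        re_ = expand_degenerate(rh, WINDOW_EXPANSION_CAP)
        n_l = len(le) if le is not None else WINDOW_EXPANSION_CAP + 1
        n_r = len(re_) if re_ is not None else WINDOW_EXPANSION_CAP + 1
        if n_l + n_r <= WINDOW_EXPANSION_CAP:
            for key in le:
                self._left.setdefault(key, []).append(posting)
            for key in re_:
                self._right.setdefault(key, []).append(posting)
            return
        # Too degenerate: index the least-degenerate half only.  Lookups can
        # then miss a mismatch falling in the indexed half, so flag the
        # primer; the search layer compensates (see search.scan_template).
        if pix not in self.capped_primers:
            logger.warning(
                "primer %s: window at offset %d (%s) too degenerate to index "
                "in full; one-mismatch lookup guarantee lost for this primer",
                self.primers[pix].id,
                off,
                orient,
            )
        self.capped_primers.add(pix)
        if n_l <= n_r and le is not None:
            for key in le:
                self._left.setdefault(key, []).append(posting)
        elif re_ is not None:
            for key in re_:
                self._right.setdefault(key, []).append(posting)

    def window(self, posting: Posting) -> str:
        """The stored (possibly degenerate) window a posting refers to."""
        pix, off, orient = posting
        return self._oriented[(pix, orient)][off : off + self.k]

    def lookup(self, word: str, max_half_expansion: int = 4096) -> list[Posting]:
        """All postings whose stored window is within Hamming distance 1 of
        ``word`` under subset-intersection matching.

        ``word`` is normally a concrete template k-mer; degenerate
        characters are expanded for the half-word lookups (capped at
        ``max_half_expansion`` concrete half-words per half — halves more
        degenerate than that are not looked up).
        """
        h = self.h
        lh, rh = word[:h], word[h:]
        candidates: set[Posting] = set()
        for half, table in ((lh, self._left), (rh, self._right)):
            exp = expand_degenerate(half, max_half_expansion)
            if exp is None:
                continue
            for key in exp:
                postings = table.get(key)
                if postings:
                    candidates.update(postings)
        if not candidates:
            return []
        bits = CODE_BITS
        out = []
        for posting in candidates:
            stored = self.window(posting)
            d = 0
            for a, b in zip(stored, word):
                if not (bits[a] & bits[b]):
                    d += 1
                    if d > 1:
                        break
            if d <= 1:
                out.append(posting)
        out.sort()
        return out


def build_index(primers: list[Primer], k: int | None = None) -> KmerIndex:
    """Build the primer k-mer index; k defaults to :func:`default_k`."""
    if not primers:
        raise ValueError("cannot build an index from an empty primer list")
    if k is None:
        k = default_k(primers)
    return KmerIndex(primers, k)


def query(index: KmerIndex, word: str) -> list[Posting]:
    """Postings within Hamming distance 1 of ``word`` (see
    :meth:`KmerIndex.lookup`)."""
    return index.lookup(word)
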