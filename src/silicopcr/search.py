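"""Sliding-window template scan: seed, verify, extend.

The template is traversed at one-nucleotide intervals; each k-mer is looked
up in the primer index and every candidate posting is verified by a
gap-free alignment of the whole primer around the seed.  Mismatches are
counted position by position under subset-intersection matching, with three
refinements drawn from PCR practice:

* the 3' end of the primer is held to a stricter standard: at most
  ``number3errors`` mismatches (default 1) in the last
  ``three_prime_window`` bases (default 7), because 3'-terminal mispairs
  block polymerase extension;
* stable guanine mismatches (duplex G*G, G*T, G*A — the primer's G opposite
  a purine or thymine) hybridise well and are charged only half a mismatch
  toward the whole-primer budget, except inside the 3' window where they
  count in full;
* template N (assembly gaps, masked regions) matches everything but is
  charged half a mismatch, so N-runs do not produce wall-to-wall hits.

Circular templates are scanned as the doubled sequence, keeping hits whose
start lies in the first copy.  Bisulfite mode scans both fully-converted
strand images of the template.  In probe mode the 3'-end rule is disabled
(hybridisation probes need no extensible 3' terminus).

Seed completeness.  A one-mismatch-per-k-mer seed cannot guarantee finding
every site the scoring rules accept when the primer is short relative to k
or when half-weighted guanine mismatches let the raw mismatch count exceed
the k-mer tolerance.  Each primer is therefore checked analytically: if an
acceptable site could defeat every seed window, that primer is searched by
exhaustive per-diagonal verification instead.  Output is identical either
way; only speed differs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal

from . import thermo
from .index import KmerIndex, Primer
from .seqcore import (
    CODE_BITS,
    CONCRETE,
    Sequence,
    bisulfite_convert,
    reverse_complement,
)

__all__ = ["SearchConfig", "PrimerHit", "scan_template", "verify_at", "seed_complete"]

logger = logging.getLogger(__name__)

_EPS = 1e-9
_N_BITS = CODE_BITS["N"]


@dataclass
class SearchConfig:
    """All search tunables.

    ``max_mismatches`` is a *weighted* budget over the whole primer
    (ordinary mismatch 1, stable guanine mismatch or template N 0.5);
    ``number3errors`` caps the mismatches inside the 3'-terminal
    ``three_prime_window`` of the primer.
    """

    k: int | None = None  # index word length; None = choose from primer set
    max_mismatches: float = 2.0
    three_prime_window: int = 7
    number3errors: int = 1
    minlen: int = 50
    maxlen: int = 5000
    topology: Literal["linear", "circular"] = "linear"
    bisulfite: bool = False
    probe_mode: bool = False
    extract_sequences: bool = False
    amplicon_cap: int = 100_000
    primer_nm: float = thermo.DEFAULT_PRIMER_NM
    na_mm: float = thermo.DEFAULT_NA_MM

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.number3errors < 0 or self.three_prime_window < 0:
            raise ValueError("3'-rule parameters must be >= 0")
        if not self.probe_mode and self.number3errors > self.max_mismatches:
            raise ValueError("number3errors cannot exceed max_mismatches")
        if self.minlen > self.maxlen:
            raise ValueError("minlen must not exceed maxlen")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def validate_against_primers(self, primers: list[Primer]) -> None:
        shortest = min(len(p.residues) for p in primers)
        if self.three_prime_window > shortest:
            raise ValueError(
                f"three_prime_window ({self.three_prime_window}) exceeds the "
                f"shortest primer length ({shortest})"
            )


@dataclass(frozen=True)
class PrimerHit:
    """One accepted primer-template binding site.

    Coordinates are 0-based half-open on the template plus strand (on
    circular templates ``end`` may exceed the template length when the
    footprint wraps the origin; ``start`` is always within the first copy).
    ``mismatch_positions`` are primer-relative offsets (0 = 5' end).
    """

    primer_id: str
    template_id: str
    strand: Literal["+", "-"]
    start: int
    end: int
    mismatch_positions: tuple[int, ...]
    n_mismatches_total: int
    n_mismatches_3prime: int
    weighted_mismatches: float
    tm_celsius: float
    bisulfite_image: str | None = None


def _score_site(
    primer_res: str, site: str, cfg: SearchConfig
) -> tuple[tuple[int, ...], int, float] | None:
    """Score a primer against a same-sense site of equal length.

    Returns (mismatch positions, 3'-window mismatch count, weighted total)
    or None when a budget is exceeded.  A template N is charged 0.5 toward
    the weighted total but is not a mismatch (it never counts toward the
    3'-window limit).
    """
    bits = CODE_BITS
    L = len(primer_res)
    w = 0 if cfg.probe_mode else cfg.three_prime_window
    limit = cfg.max_mismatches + _EPS
    three_limit = cfg.number3errors
    weighted = 0.0
    n3 = 0
    positions: list[int] = []
    for j in range(L):
        p = primer_res[j]
        s = site[j]
        sb = bits[s]
        if sb == _N_BITS:
            weighted += 0.5
            if weighted > limit:
                return None
            continue
        if bits[p] & sb:
            continue
        positions.append(j)
        in3 = j >= L - w
        if in3:
            n3 += 1
            if n3 > three_limit:
                return None
            weighted += 1.0
        elif p == "G" and s in CONCRETE:
            # duplex opposition G*(complement of s): any concrete
            # mismatch of a primer G is a stable guanine mismatch
            weighted += 0.5
        else:
            weighted += 1.0
        if weighted > limit:
            return None
    return tuple(positions), n3, weighted


def verify_at(
    primer: Primer,
    orient: str,
    work: str,
    start: int,
    template_id: str,
    cfg: SearchConfig,
    image: str | None = None,
) -> PrimerHit | None:
    """Align the whole primer gap-free at ``start`` on the working sequence
    and build a hit if the mismatch rules accept it.

    ``work`` is the scanned sequence (template, converted image, or the
    doubled circle); a footprint extending past its end is a rejection, not
    an error.
    """
    L = len(primer.residues)
    if start < 0 or start + L > len(work):
        return None
    segment = work[start : start + L]
    site = segment if orient == "+" else reverse_complement(segment)
    scored = _score_site(primer.residues, site, cfg)
    if scored is None:
        return None
    positions, n3, weighted = scored
    tm = thermo.nn_tm(
        primer.residues, site, primer_nm=cfg.primer_nm, na_mm=cfg.na_mm
    )
    return PrimerHit(
        primer_id=primer.id,
        template_id=template_id,
        strand="+" if orient == "+" else "-",
        start=start,
        end=start + L,
        mismatch_positions=positions,
        n_mismatches_total=len(positions),
        n_mismatches_3prime=n3,
        weighted_mismatches=weighted,
        tm_celsius=tm,
        bisulfite_image=image,
    )


def _min_defeating_mismatches(L: int, k: int) -> int:
    """Minimum number of mismatch positions that put >= 2 mismatches in
    every length-k window of a length-L primer (i.e. that defeat a
    one-mismatch-per-k-mer seed).  Greedy interval covering with demand 2,
    placing points as far right as possible."""
    chosen: list[int] = []
    for o in range(L - k + 1):
        inside = sum(1 for c in chosen if o <= c < o + k)
        need = 2 - inside
        pos = o + k - 1
        while need > 0:
            while pos in chosen:
                pos -= 1
            chosen.append(pos)
            pos -= 1
            need -= 1
    return len(chosen)


def _max_raw_mismatches(primer: Primer, cfg: SearchConfig) -> int:
    """Upper bound on the number of mismatch *positions* an acceptable site
    for this primer can carry (half-weighted guanine mismatches stretch the
    weighted budget over more positions)."""
    L = len(primer.residues)
    w = 0 if cfg.probe_mode else cfg.three_prime_window
    g_out = sum(
        1 for j, ch in enumerate(primer.residues) if ch == "G" and j < L - w
    )
    n_half = min(g_out, int(cfg.max_mismatches / 0.5))
    rem = cfg.max_mismatches - 0.5 * n_half
    return n_half + int(rem + _EPS)


def seed_complete(primer: Primer, cfg: SearchConfig, index: KmerIndex) -> bool:
    """Whether the seeded scan is guaranteed to find every acceptable site
    of this primer."""
    pix = index.primers.index(primer)
    if pix in index.capped_primers:
        return False
    L = len(primer.residues)
    if L < index.k:
        return False
    return _max_raw_mismatches(primer, cfg) < _min_defeating_mismatches(L, index.k)


def _template_images(
    residues: str, circular: bool, bisulfite: bool
) -> list[tuple[str | None, str]]:
    """Working sequences to scan: the doubled sequence for circles, and the
    two fully-converted strand images in bisulfite mode (conversion is
    applied after doubling so CpG context is correct across the origin)."""
    work = residues + residues if circular else residues
    if not bisulfite:
        return [(None, work)]
    return [
        ("C2T", bisulfite_convert(work, "plus")),
        ("G2A", bisulfite_convert(work, "minus")),
    ]


def scan_template(
    template: Sequence, index: KmerIndex, cfg: SearchConfig
) -> list[PrimerHit]:
    """All accepted binding sites of the indexed primers on one template.

    Hits are reported for both strands, deduplicated on
    (primer, strand, start, image), and sorted by position.  On circular
    templates only starts within the first copy are kept (sites past the
    origin are duplicates of those).
    """
    k = index.k
    L0 = len(template.residues)
    if L0 < k:
        logger.warning(
            "template %s (%d nt) shorter than k=%d; skipped", template.id, L0, k
        )
        return []
    circular = cfg.topology == "circular" or template.topology == "circular"
    max_half_deg = max(1, int(cfg.max_mismatches / 0.5))
    complete = {
        pix: seed_complete(p, cfg, index) for pix, p in enumerate(index.primers)
    }
    hits: list[PrimerHit] = []
    for image, work in _template_images(template.residues, circular, cfg.bisulfite):
        seen: set[tuple[int, str, int]] = set()
        n = len(work)
        if any(complete.values()):
            for i in range(n - k + 1):
                word = work[i : i + k]
                postings = index.lookup(word, max_half_expansion=4**max_half_deg)
                for pix, off, orient in postings:
                    if not complete[pix]:
                        continue
                    start = i - off
                    if start < 0 or start >= L0:
                        continue
                    key = (pix, orient, start)
                    if key in seen:
                        continue
                    seen.add(key)
                    hit = verify_at(
                        index.primers[pix], orient, work, start, template.id, cfg, image
                    )
                    if hit is not None:
                        hits.append(hit)
        for pix, primer in enumerate(index.primers):
            if complete[pix]:
                continue
            Lp = len(primer.residues)
            last = min(L0, n - Lp + 1)
            for orient in ("+", "-"):
                for start in range(last):
                    hit = verify_at(
                        primer, orient, work, start, template.id, cfg, image
                    )
                    if hit is not None:
                        hits.append(hit)
    hits.sort(
        key=lambda h: (
            h.bisulfite_image or "",
            h.start,
            h.strand,
            h.primer_id,
            h.end,
        )
    )
    return hits
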