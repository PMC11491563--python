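"""Exhaustive reference search: every offset x every primer x both strands.

A deliberately direct O(template x primer) implementation of the binding
and pairing rules, written against the rule definitions rather than the
seeded search machinery.  It scores every diagonal with a dense vectorised
mismatch matrix — no seeding, no hashing, no early exit — so it serves as
an independent check of the production scan and as the certifier the
synthetic-instance generator uses to prove an instance contains exactly its
planted sites.

Hits and amplicons are returned as plain tuples (see ``hit_key`` /
``amp_key``) so outputs from either implementation compare as sets.
"""

from __future__ import annotations

import numpy as np

from .index import Primer
from .search import PrimerHit, SearchConfig
from .amplicon import Amplicon
from .seqcore import CODE_BITS, Sequence, bisulfite_convert, reverse_complement

__all__ = ["naive_hits", "naive_amplicons", "hit_key", "amp_key"]

#: A hit as a comparable tuple:
#: (image, primer id, strand, start, end, n_mismatches, n_3prime, weighted).
HitKey = tuple

#: An amplicon as a comparable tuple:
#: (image, start, length, sorted (forward, reverse) primer-id pairs).
AmpKey = tuple


def hit_key(h: PrimerHit) -> HitKey:
    return (
        h.bisulfite_image,
        h.primer_id,
        h.strand,
        h.start,
        h.end,
        h.n_mismatches_total,
        h.n_mismatches_3prime,
        round(h.weighted_mismatches, 6),
    )


def amp_key(a: Amplicon) -> AmpKey:
    return (a.bisulfite_image, a.start, a.length, a.primer_pairs)


def _encode(s: str) -> np.ndarray:
    return np.array([CODE_BITS[c] for c in s], dtype=np.uint8)


def _images(residues: str, circular: bool, bisulfite: bool):
    work = residues + residues if circular else residues
    if not bisulfite:
        return [(None, work)]
    return [
        ("C2T", bisulfite_convert(work, "plus")),
        ("G2A", bisulfite_convert(work, "minus")),
    ]


def naive_hits(
    template: Sequence, primers: list[Primer], cfg: SearchConfig
) -> set[HitKey]:
    """All acceptable binding sites, by dense scoring of every diagonal."""
    circular = cfg.topology == "circular" or template.topology == "circular"
    L0 = len(template.residues)
    w3 = 0 if cfg.probe_mode else cfg.three_prime_window
    out: set[HitKey] = set()
    for image, work in _images(template.residues, circular, cfg.bisulfite):
        tenc = _encode(work)
        n = len(tenc)
        for primer in primers:
            L = len(primer.residues)
            if n < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(tenc, L)
            for strand in ("+", "-"):
                oriented = (
                    primer.residues
                    if strand == "+"
                    else reverse_complement(primer.residues)
                )
                pm = _encode(oriented)
                # primer-relative position of each window column
                prel = (
                    np.arange(L) if strand == "+" else (L - 1 - np.arange(L))
                )
                p_is_g = np.array(
                    [primer.residues[j] == "G" for j in prel], dtype=bool
                )
                in3 = prel >= (L - w3)
                match = (windows & pm) != 0
                is_n = windows == CODE_BITS["N"]
                t_conc = np.isin(windows, (1, 2, 4, 8))
                mm = ~match
                stable = mm & p_is_g & t_conc & ~in3
                weight = np.where(mm, np.where(stable, 0.5, 1.0), 0.0)
                weight = weight + np.where(is_n, 0.5, 0.0)
                total = weight.sum(axis=1)
                n3 = (mm & in3).sum(axis=1)
                nmm = mm.sum(axis=1)
                ok = total <= cfg.max_mismatches + 1e-9
                if not cfg.probe_mode:
                    ok &= n3 <= cfg.number3errors
                starts = np.nonzero(ok)[0]
                for s in starts:
                    s = int(s)
                    if s >= L0:
                        continue
                    out.add(
                        (
                            image,
                            primer.id,
                            strand,
                            s,
                            s + L,
                            int(nmm[s]),
                            int(n3[s]),
                            round(float(total[s]), 6),
                        )
                    )
    return out


def naive_amplicons(
    template: Sequence, primers: list[Primer], cfg: SearchConfig
) -> set[AmpKey]:
    """All size-bounded convergent pairs over the naive hit set, merged by
    locus exactly as the production pairing does."""
    if cfg.probe_mode:
        return set()
    hits = naive_hits(template, primers, cfg)
    circular = cfg.topology == "circular" or template.topology == "circular"
    L0 = len(template.residues)
    shifts = (0, L0) if circular else (0,)
    loci: dict[tuple, set] = {}
    for image in {h[0] for h in hits}:
        plus = [h for h in hits if h[0] == image and h[2] == "+"]
        minus = [h for h in hits if h[0] == image and h[2] == "-"]
        for f in plus:
            for r in minus:
                for shift in shifts:
                    rs, re_ = r[3] + shift, r[4] + shift
                    if rs < f[4]:
                        continue
                    length = re_ - f[3]
                    if length < cfg.minlen or length > cfg.maxlen:
                        continue
                    if circular and length > L0:
                        continue
                    loci.setdefault((image, f[3], length), set()).add(
                        (f[1], r[1])
                    )
    return {
        (image, start, length, tuple(sorted(pairs)))
        for (image, start, length), pairs in loci.items()
    }
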