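"""Pairing accepted primer hits into predicted PCR products.

A product is any convergent pair — a plus-strand hit with a minus-strand
hit lying 3'-ward of it (the minus footprint starting at or after the plus
footprint's end) — whose span, measured 5' end to 5' end and therefore
including both primer footprints, lies within the configured size bounds.
Any primer may serve as forward or reverse: multiplex is the general case
and single-primer inter-repeat amplification (IRAP/ISSR/RAPD-style
fingerprinting) is its degenerate case.  On circular templates, pairs
spanning the origin are additionally enumerated (inverse PCR); a product
cannot be longer than the circle.

Distinct primer pairs producing identical coordinates are merged into one
amplicon row (the contributing pairs are all listed but the locus counts
once).  Nested products are all reported — fingerprinting visualises every
band.  The annealing temperature of each product is the lower of the two
hit Tm values plus ln(product length).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .search import PrimerHit, SearchConfig, _template_images
from .seqcore import Sequence
from .thermo import annealing_temperature

__all__ = ["Amplicon", "pair_hits", "extract_sequence", "probe_report"]

logger = logging.getLogger(__name__)


@dataclass
class Amplicon:
    """One predicted PCR product.

    ``start``/``end`` are 0-based half-open template coordinates spanning
    the outermost primer 5' ends; on circular templates ``end`` may exceed
    the template length when the product wraps the origin.  ``primer_pairs``
    lists every (forward id, reverse id) combination mapping to these
    coordinates; ``forward``/``reverse`` are the representative hits (the
    lexicographically first pair).
    """

    template_id: str
    forward: PrimerHit
    reverse: PrimerHit
    start: int
    end: int
    length: int
    ta_celsius: float
    wraps_origin: bool = False
    bisulfite_image: str | None = None
    primer_pairs: tuple[tuple[str, str], ...] = ()
    sequence: str | None = None


def pair_hits(
    hits: list[PrimerHit], template: Sequence, cfg: SearchConfig
) -> list[Amplicon]:
    """Enumerate all size-bounded convergent hit pairs on one template.

    In probe mode no pairing is performed (use :func:`probe_report`).
    Results are sorted by start coordinate then length; identical
    coordinates from different primer pairs collapse to one amplicon.
    """
    if cfg.probe_mode or not hits:
        return []
    circular = cfg.topology == "circular" or template.topology == "circular"
    L0 = len(template.residues)
    shifts = (0, L0) if circular else (0,)
    by_image: dict[str | None, list[PrimerHit]] = {}
    for h in hits:
        by_image.setdefault(h.bisulfite_image, []).append(h)

    # keyed by (image, start, length) -> [representative fwd, rev, pairs set]
    loci: dict[tuple, list] = {}
    for image, image_hits in by_image.items():
        plus = [h for h in image_hits if h.strand == "+"]
        minus = [h for h in image_hits if h.strand == "-"]
        for f in plus:
            for r in minus:
                for shift in shifts:
                    rs, re_ = r.start + shift, r.end + shift
                    if rs < f.end:
                        continue
                    length = re_ - f.start
                    if length < cfg.minlen or length > cfg.maxlen:
                        continue
                    if circular and length > L0:
                        continue
                    key = (image, f.start, length)
                    pair = (f.primer_id, r.primer_id)
                    entry = loci.get(key)
                    if entry is None:
                        loci[key] = [f, r, {pair}]
                    else:
                        entry[2].add(pair)
                        if pair < (entry[0].primer_id, entry[1].primer_id):
                            entry[0], entry[1] = f, r

    out: list[Amplicon] = []
    for (image, start, length), (f, r, pairs) in sorted(
        loci.items(), key=lambda kv: (kv[0][0] or "", kv[0][1], kv[0][2])
    ):
        end = start + length
        out.append(
            Amplicon(
                template_id=template.id,
                forward=f,
                reverse=r,
                start=start,
                end=end,
                length=length,
                ta_celsius=annealing_temperature(
                    min(f.tm_celsius, r.tm_celsius), length
                ),
                wraps_origin=bool(circular and end > L0),
                bisulfite_image=image,
                primer_pairs=tuple(sorted(pairs)),
            )
        )
    if len(out) > cfg.amplicon_cap:
        logger.warning(
            "template %s: %d amplicons exceed the cap (%d); output truncated",
            template.id,
            len(out),
            cfg.amplicon_cap,
        )
        out = out[: cfg.amplicon_cap]
    if cfg.extract_sequences:
        for a in out:
            a.sequence = extract_sequence(template, a, cfg)
    return out


def extract_sequence(template: Sequence, a: Amplicon, cfg: SearchConfig) -> str:
    """Plus-strand residues spanned by an amplicon (of its bisulfite image
    in bisulfite mode), wrapping the origin when flagged.  The returned
    length always equals the amplicon length."""
    circular = cfg.topology == "circular" or template.topology == "circular"
    L0 = len(template.residues)
    for image, work in _template_images(template.residues, circular, cfg.bisulfite):
        if image == a.bisulfite_image:
            if a.start < 0 or a.end > len(work) or a.end - a.start != a.length:
                raise RuntimeError(
                    f"amplicon coordinates [{a.start}, {a.end}) inconsistent "
                    f"with template {template.id} (length {L0})"
                )
            return work[a.start : a.end]
    raise RuntimeError(
        f"amplicon image {a.bisulfite_image!r} not derivable from template "
        f"{template.id} under the given configuration"
    )


def probe_report(hits: list[PrimerHit]) -> list[dict]:
    """Per-hit report rows for probe mode: no pairing, no size filter.

    Coordinates are 1-based inclusive; Tm is reported to one decimal."""
    rows = []
    for h in hits:
        rows.append(
            {
                "probe": h.primer_id,
                "template": h.template_id,
                "strand": h.strand,
                "start_1based": h.start + 1,
                "end_1based": h.end,
                "mismatches": h.n_mismatches_total,
                "tm": round(h.tm_celsius, 1),
                "bisulfite_image": h.bisulfite_image or "",
            }
        )
    return rows
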