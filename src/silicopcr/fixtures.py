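"""Synthetic templates with planted, ground-truth-annotated primer sites.

Every test surface of the package can be exercised without external data:
the generators here build uniform-random backgrounds, implant primer
binding sites with exactly specified mismatch placements (including
3'-window placements and stable guanine mismatches on demand), and record
the expected hits and amplicons.  Each instance is certified against the
exhaustive reference search before being returned, so its truth is exact —
an instance whose random background happens to contain an unplanned
near-match is regenerated deterministically from the next attempt counter.

All randomness sits behind a single integer seed; draws happen in a fixed
order (primers first, then background, then per-site placements left to
right), so regeneration with the same seed is byte-identical.

The background is uniform A/C/G/T — no repeat families, GC skew or
compositional structure.  That isolates algorithmic correctness; it does
not emulate the repeat-rich genomes the tool targets, beyond the explicit
inverted-repeat mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import reference
from .index import Primer, make_primer
from .search import SearchConfig
from .seqcore import IUPAC_SETS, Sequence, bisulfite_convert, reverse_complement

__all__ = [
    "PlantedInstance",
    "plant_sites",
    "plant_inverted_repeats",
    "degenerate_stress",
]

_BASES = "ACGT"
_MAX_ATTEMPTS = 40


@dataclass
class PlantedInstance:
    """A template + primer set whose complete hit and amplicon sets are
    known exactly (reference-certified)."""

    template: Sequence
    primers: list[Primer]
    config: SearchConfig
    truth_hits: set[tuple]
    truth_amplicons: set[tuple]
    seed: int


def _rand_seq(rng: np.random.Generator, n: int) -> list[str]:
    return [_BASES[i] for i in rng.integers(0, 4, size=n)]


def _pair_rule(
    truth_hits: set[tuple], L0: int, circular: bool, minlen: int, maxlen: int
) -> set[tuple]:
    """The convergent-pair enumeration rule applied to a known hit set
    (brute force over all pairs; locus-merged like the production pairing)."""
    shifts = (0, L0) if circular else (0,)
    loci: dict[tuple, set] = {}
    for f in truth_hits:
        if f[2] != "+":
            continue
        for r in truth_hits:
            if r[2] != "-" or r[0] != f[0]:
                continue
            for shift in shifts:
                rs, re_ = r[3] + shift, r[4] + shift
                if rs < f[4]:
                    continue
                length = re_ - f[3]
                if length < minlen or length > maxlen:
                    continue
                if circular and length > L0:
                    continue
                loci.setdefault((f[0], f[3], length), set()).add((f[1], r[1]))
    return {
        (image, start, length, tuple(sorted(pairs)))
        for (image, start, length), pairs in loci.items()
    }


def _certified(instance: PlantedInstance) -> bool:
    got_hits = reference.naive_hits(
        instance.template, instance.primers, instance.config
    )
    if got_hits != instance.truth_hits:
        return False
    got_amps = reference.naive_amplicons(
        instance.template, instance.primers, instance.config
    )
    return got_amps == instance.truth_amplicons


def _mutate_site(
    rng: np.random.Generator,
    primer_res: str,
    n_mismatches: int,
    n_three_prime: int,
    n_g_mismatches: int,
    three_prime_window: int,
) -> tuple[list[str], int, int, float]:
    """Return a mutated copy of the primer (as the template site content)
    carrying exactly the requested mismatch profile, plus its expected
    (n_total, n_3prime, weighted) accounting."""
    L = len(primer_res)
    site = list(primer_res)
    w = three_prime_window
    body = [j for j in range(L - w)]
    g_body = [j for j in body if primer_res[j] == "G"]
    plain_body = [j for j in body if primer_res[j] != "G"]
    tail = list(range(L - w, L))
    if n_g_mismatches > len(g_body):
        raise ValueError("not enough guanines outside the 3' window to plant on")
    if n_mismatches > len(plain_body):
        raise ValueError("not enough non-G body positions for plain mismatches")
    if n_three_prime > len(tail):
        raise ValueError("3'-window mismatches exceed the window size")
    g_pos = sorted(rng.choice(g_body, size=n_g_mismatches, replace=False)) if n_g_mismatches else []
    p_pos = sorted(rng.choice(plain_body, size=n_mismatches, replace=False)) if n_mismatches else []
    t_pos = sorted(rng.choice(tail, size=n_three_prime, replace=False)) if n_three_prime else []
    for j in list(g_pos) + list(p_pos) + list(t_pos):
        others = [b for b in _BASES if b not in IUPAC_SETS[primer_res[j]]]
        site[j] = others[rng.integers(0, len(others))]
    n_total = n_mismatches + n_three_prime + n_g_mismatches
    weighted = n_mismatches + n_three_prime + 0.5 * n_g_mismatches
    return site, n_total, n_three_prime, round(float(weighted), 6)


def plant_sites(
    length: int = 10_000,
    n_pairs: int = 3,
    primer_length: int = 18,
    n_mismatches: int = 0,
    n_three_prime: int = 0,
    n_g_mismatches: int = 0,
    topology: str = "linear",
    bisulfite: bool = False,
    seed: int = 0,
    config: SearchConfig | None = None,
) -> PlantedInstance:
    """Plant ``n_pairs`` convergent forward/reverse site pairs.

    Each planted site carries exactly ``n_mismatches`` plain mismatches and
    ``n_g_mismatches`` stable guanine mismatches outside the 3' window plus
    ``n_three_prime`` mismatches inside it.  In bisulfite mode the primers
    are read off the converted template image (no mismatch injection), so a
    bisulfite-aware search must recover them at the planted coordinates.
    """
    if config is None:
        config = SearchConfig(topology=topology, bisulfite=bisulfite)
    if bisulfite and (n_mismatches or n_three_prime or n_g_mismatches):
        raise ValueError("bisulfite instances are generated mismatch-free")
    pl = primer_length
    block = length // n_pairs
    lo = max(config.minlen, 2 * pl)
    hi = min(config.maxlen, block - 2 * pl - 4)
    if hi < lo or block < lo + 4 * pl:
        raise ValueError("infeasible packing: sites do not fit in the template")
    if n_three_prime > config.three_prime_window:
        raise ValueError("3'-window mismatches exceed the window size")
    if n_mismatches + n_g_mismatches > pl - config.three_prime_window:
        raise ValueError("more body mismatches requested than body positions")
    circular = topology == "circular"

    for attempt in range(_MAX_ATTEMPTS):
        rng = np.random.default_rng([seed, attempt])
        tpl = _rand_seq(rng, length)
        try:
            if bisulfite:
                primers, truth_hits = _plant_bisulfite(
                    rng, tpl, length, n_pairs, pl, block, lo, hi, circular
                )
            else:
                primers, truth_hits = _plant_plain(
                    rng,
                    tpl,
                    n_pairs,
                    pl,
                    block,
                    lo,
                    hi,
                    n_mismatches,
                    n_three_prime,
                    n_g_mismatches,
                    config,
                )
        except ValueError:
            # e.g. the random primer lacks enough guanines for the requested
            # stable-mismatch profile: draw a fresh one deterministically
            continue
        template = Sequence(id="planted", residues="".join(tpl), topology=topology)
        truth_amps = _pair_rule(
            truth_hits, length, circular, config.minlen, config.maxlen
        )
        instance = PlantedInstance(
            template=template,
            primers=primers,
            config=config,
            truth_hits=truth_hits,
            truth_amplicons=truth_amps,
            seed=seed,
        )
        if _certified(instance):
            return instance
    raise RuntimeError(
        f"could not generate a clean instance in {_MAX_ATTEMPTS} attempts "
        f"(seed {seed})"
    )


def _plant_plain(
    rng,
    tpl: list[str],
    n_pairs: int,
    pl: int,
    block: int,
    lo: int,
    hi: int,
    n_mismatches: int,
    n_three_prime: int,
    n_g_mismatches: int,
    config: SearchConfig,
) -> tuple[list[Primer], set[tuple]]:
    fwd = make_primer("F1", "".join(_rand_seq(rng, pl)))
    rev = make_primer("R1", "".join(_rand_seq(rng, pl)))
    truth_hits: set[tuple] = set()
    for i in range(n_pairs):
        d = int(rng.integers(lo, hi + 1))
        a = i * block + int(rng.integers(0, block - d - 1))
        b = a + d - pl  # reverse-site start so that span end - start = d
        f_site, f_n, f_n3, f_w = _mutate_site(
            rng, fwd.residues, n_mismatches, n_three_prime, n_g_mismatches,
            config.three_prime_window,
        )
        r_site, r_n, r_n3, r_w = _mutate_site(
            rng, rev.residues, n_mismatches, n_three_prime, n_g_mismatches,
            config.three_prime_window,
        )
        tpl[a : a + pl] = f_site
        tpl[b : b + pl] = list(reverse_complement("".join(r_site)))
        truth_hits.add((None, "F1", "+", a, a + pl, f_n, f_n3, f_w))
        truth_hits.add((None, "R1", "-", b, b + pl, r_n, r_n3, r_w))
    return [fwd, rev], truth_hits


def _plant_bisulfite(
    rng,
    tpl: list[str],
    length: int,
    n_pairs: int,
    pl: int,
    block: int,
    lo: int,
    hi: int,
    circular: bool,
) -> tuple[list[Primer], set[tuple]]:
    placements = []
    for i in range(n_pairs):
        d = int(rng.integers(lo, hi + 1))
        a = i * block + int(rng.integers(0, block - d - 1))
        placements.append((a, a + d - pl))
    work = "".join(tpl) + ("".join(tpl) if circular else "")
    image = bisulfite_convert(work, "plus")
    primers = []
    truth_hits: set[tuple] = set()
    for i, (a, b) in enumerate(placements):
        f = make_primer(f"F{i + 1}", image[a : a + pl])
        r = make_primer(f"R{i + 1}", reverse_complement(image[b : b + pl]))
        primers.extend([f, r])
        truth_hits.add(("C2T", f.id, "+", a, a + pl, 0, 0, 0.0))
        truth_hits.add(("C2T", r.id, "-", b, b + pl, 0, 0, 0.0))
    return primers, truth_hits


def plant_inverted_repeats(
    length: int = 20_000,
    n_repeats: int = 4,
    primer_length: int = 18,
    seed: int = 0,
    config: SearchConfig | None = None,
) -> PlantedInstance:
    """One primer, several exact copies of its site planted in inverted
    orientations: the single-primer inter-repeat scenario.  Truth amplicons
    are every convergent copy pair within the size bounds."""
    if config is None:
        config = SearchConfig()
    pl = primer_length
    gap = length // (n_repeats + 1)
    if gap <= 2 * pl + 4:
        raise ValueError("infeasible packing: repeats do not fit")
    for attempt in range(_MAX_ATTEMPTS):
        rng = np.random.default_rng([seed, attempt])
        tpl = _rand_seq(rng, length)
        primer = make_primer("P1", "".join(_rand_seq(rng, pl)))
        truth_hits: set[tuple] = set()
        for i in range(n_repeats):
            pos = (i + 1) * gap + int(rng.integers(-gap // 4, gap // 4 + 1))
            # alternate orientations so convergent pairs exist
            strand = "+" if i % 2 == 0 else "-"
            content = (
                primer.residues
                if strand == "+"
                else reverse_complement(primer.residues)
            )
            tpl[pos : pos + pl] = list(content)
            truth_hits.add((None, "P1", strand, pos, pos + pl, 0, 0, 0.0))
        template = Sequence(id="irap", residues="".join(tpl))
        truth_amps = _pair_rule(
            truth_hits, length, False, config.minlen, config.maxlen
        )
        instance = PlantedInstance(
            template=template,
            primers=[primer],
            config=config,
            truth_hits=truth_hits,
            truth_amplicons=truth_amps,
            seed=seed,
        )
        if _certified(instance):
            return instance
    raise RuntimeError(
        f"could not generate a clean inverted-repeat instance (seed {seed})"
    )


def degenerate_stress(seed: int = 0) -> PlantedInstance:
    """Degenerate-code exercise: a primer with R/Y/N positions (N at the 3'
    terminus) planted as member and non-member expansions, plus a template
    N inside one site.

    Sites (left to right on a 6 kb template, paired with an exact
    reverse-complement site so amplicons form):

    * member expansion of every degenerate position -> 0 mismatches;
    * non-member base at the R position -> 1 plain mismatch;
    * template N at a concrete position -> 0 mismatches, 0.5 weighted.
    """
    cfg = SearchConfig(minlen=50, maxlen=1200, number3errors=0)
    for attempt in range(_MAX_ATTEMPTS):
        rng = np.random.default_rng([seed, attempt])
        base = _rand_seq(rng, 18)
        base[5], base[9], base[17] = "R", "Y", "N"
        primer = make_primer("DG1", "".join(base))
        res = primer.residues

        def member(r_base: str) -> list[str]:
            s = list(res)
            s[5] = r_base
            s[9] = "C"
            s[17] = "G"
            return s

        tpl = _rand_seq(rng, 6000)
        truth_hits: set[tuple] = set()
        # site 1: pure member expansion
        s1 = member("A")
        tpl[500:518] = s1
        truth_hits.add((None, "DG1", "+", 500, 518, 0, 0, 0.0))
        # its reverse partner (member expansion, minus strand)
        s1r = member("G")
        tpl[1300:1318] = list(reverse_complement("".join(s1r)))
        truth_hits.add((None, "DG1", "-", 1300, 1318, 0, 0, 0.0))
        # site 2: non-member base at the R={A,G} position (plain mismatch)
        s2 = member("A")
        s2[5] = "C"
        tpl[2500:2518] = s2
        truth_hits.add((None, "DG1", "+", 2500, 2518, 1, 0, 1.0))
        # site 3: template N at a concrete position (half weight, no mismatch)
        s3 = member("G")
        s3[2] = "N"
        tpl[4000:4018] = s3
        truth_hits.add((None, "DG1", "+", 4000, 4018, 0, 0, 0.5))
        template = Sequence(id="degenerate", residues="".join(tpl))
        truth_amps = _pair_rule(truth_hits, 6000, False, cfg.minlen, cfg.maxlen)
        instance = PlantedInstance(
            template=template,
            primers=[primer],
            config=cfg,
            truth_hits=truth_hits,
            truth_amplicons=truth_amps,
            seed=seed,
        )
        if _certified(instance):
            return instance
    raise RuntimeError(f"could not generate a clean degenerate instance (seed {seed})")
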