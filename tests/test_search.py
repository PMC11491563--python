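"""Sliding-window scan: seeding, extension, mismatch rules, strands,
topology."""

import numpy as np
import pytest

from silicopcr import (
    SearchConfig,
    Sequence,
    build_index,
    make_primer,
    reverse_complement,
    scan_template,
)
from silicopcr import reference


def background(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def implant(template, pos, content):
    return template[:pos] + content + template[pos + len(content) :]


@pytest.fixture
def primer20(rng):
    return make_primer("P1", background(rng, 20))


def scan(template_res, primers, cfg, topology="linear"):
    tpl = Sequence(id="t", residues=template_res, topology=topology)
    idx = build_index(primers, cfg.k)
    return scan_template(tpl, idx, cfg)


def test_exact_implant_gives_single_plus_hit(rng, primer20):
    t = implant(background(rng, 2000), 100, primer20.residues)
    hits = scan(t, [primer20], SearchConfig())
    assert len(hits) == 1
    h = hits[0]
    assert (h.strand, h.start, h.end, h.n_mismatches_total) == ("+", 100, 120, 0)


def test_reverse_complement_implant_gives_minus_hit(rng, primer20):
    t = implant(background(rng, 2000), 700, reverse_complement(primer20.residues))
    hits = scan(t, [primer20], SearchConfig())
    assert len(hits) == 1
    assert (hits[0].strand, hits[0].start) == ("-", 700)


def test_three_prime_terminal_mismatch_rule_toggle(rng, primer20):
    site = list(primer20.residues)
    site[-1] = next(b for b in "ACGT" if b != site[-1])
    t = implant(background(rng, 2000), 500, "".join(site))
    strict = scan(t, [primer20], SearchConfig(number3errors=0))
    lenient = scan(t, [primer20], SearchConfig(number3errors=1))
    assert strict == []
    assert len(lenient) == 1 and lenient[0].n_mismatches_3prime == 1


def test_stable_guanine_mismatches_count_half(rng):
    # primer with guanines in the body: three G mismatches weigh 1.5 <= 2
    primer = make_primer("PG", "AGTGACGTGGACCTGATTCA")
    body_g = [j for j, c in enumerate(primer.residues[:-7]) if c == "G"]
    assert len(body_g) >= 3
    site = list(primer.residues)
    for j in body_g[:3]:
        site[j] = "A" if primer.residues[j] != "A" else "C"
    t = implant(background(rng, 1500), 400, "".join(site))
    hits = scan(t, [primer], SearchConfig())
    assert len(hits) == 1
    assert hits[0].weighted_mismatches == pytest.approx(1.5)
    assert hits[0].n_mismatches_total == 3
    # three plain (non-G) mismatches weigh 3 > 2: rejected
    plain = [j for j, c in enumerate(primer.residues[:-7]) if c != "G"][:3]
    site2 = list(primer.residues)
    for j in plain:
        site2[j] = "G" if primer.residues[j] != "G" else "C"
    # avoid creating stable pairs: mutate template to a base that is not a
    # concrete mismatch of a primer G (primer base is not G here), weight 1
    t2 = implant(background(rng, 1500), 400, "".join(site2))
    assert scan(t2, [primer], SearchConfig()) == []


def test_guanine_mismatch_counts_full_inside_three_prime_window(rng):
    primer = make_primer("PG", "ACTACTACTACTAAAGGGTG")
    # two G mismatches inside the last 7 nt: n3 = 2 > number3errors=1
    site = list(primer.residues)
    g_tail = [j for j in range(13, 20) if primer.residues[j] == "G"]
    for j in g_tail[:2]:
        site[j] = "A"
    t = implant(background(rng, 1500), 300, "".join(site))
    assert scan(t, [primer], SearchConfig(number3errors=1)) == []


def test_template_n_weighs_half_and_never_trips_3prime_rule(rng, primer20):
    site = list(primer20.residues)
    for j in (2, 5, 8, 19):  # includes the 3'-terminal base
        site[j] = "N"
    t = implant(background(rng, 1500), 600, "".join(site))
    hits = scan(t, [primer20], SearchConfig(number3errors=0))
    assert len(hits) == 1
    h = hits[0]
    assert h.weighted_mismatches == pytest.approx(2.0)
    assert h.n_mismatches_total == 0 and h.n_mismatches_3prime == 0
    site[11] = "N"  # fifth N: weighted 2.5 > 2
    t2 = implant(background(rng, 1500), 600, "".join(site))
    assert scan(t2, [primer20], SearchConfig(number3errors=0)) == []


def test_probe_mode_disables_three_prime_rule(rng, primer20):
    site = list(primer20.residues)
    for j in (18, 19):
        site[j] = next(b for b in "ACGT" if b != primer20.residues[j])
    t = implant(background(rng, 1500), 600, "".join(site))
    assert scan(t, [primer20], SearchConfig(number3errors=1)) == []
    probe_hits = scan(t, [primer20], SearchConfig(probe_mode=True))
    assert len(probe_hits) == 1 and probe_hits[0].n_mismatches_total == 2


def test_mismatch_budget_monotonicity(rng):
    for trial in range(25):
        trng = np.random.default_rng([7, trial])
        primer = make_primer("P", background(trng, int(trng.integers(14, 26))))
        t = background(trng, 1200)
        # noisy implants
        for pos in (200, 600):
            noisy = list(primer.residues)
            for _ in range(int(trng.integers(0, 4))):
                noisy[int(trng.integers(0, len(noisy)))] = "ACGT"[int(trng.integers(0, 4))]
            t = implant(t, pos, "".join(noisy))
        keysets = []
        for mm, n3 in ((1.0, 0), (2.0, 1), (3.0, 1), (3.0, 2)):
            hits = scan(t, [primer], SearchConfig(max_mismatches=mm, number3errors=n3))
            keysets.append({reference.hit_key(h) for h in hits})
        assert keysets[0] <= keysets[1] <= keysets[2] <= keysets[3]


def test_strand_symmetry(rng, primer20):
    t = background(rng, 1500)
    t = implant(t, 150, primer20.residues)
    noisy = list(reverse_complement(primer20.residues))
    noisy[3] = "A" if noisy[3] != "A" else "T"
    t = implant(t, 900, "".join(noisy))
    cfg = SearchConfig()
    fwd = scan(t, [primer20], cfg)
    rev = scan(reverse_complement(t), [primer20], cfg)
    L = len(t)
    mirrored = {("+" if h.strand == "-" else "-", L - h.end, L - h.start) for h in rev}
    assert {(h.strand, h.start, h.end) for h in fwd} == mirrored


def test_circular_hits_equal_doubled_linear_scan(rng, primer20):
    t = background(rng, 800)
    # footprint straddling the origin
    t = t[: 800 - 10] + primer20.residues[:10]
    t = primer20.residues[10:] + t[10:]
    # the site wraps: last 10 nt of template + first 10 nt
    tpl_circ = Sequence(id="c", residues=t, topology="circular")
    idx = build_index([primer20])
    cfg = SearchConfig(topology="circular")
    circ = scan_template(tpl_circ, idx, cfg)
    doubled = scan(t + t, [primer20], SearchConfig())
    expected = {
        (h.strand, h.start, h.end) for h in doubled if h.start < len(t)
    }
    assert {(h.strand, h.start, h.end) for h in circ} == expected
    assert any(h.end > len(t) for h in circ)  # the wrapped footprint is found


def test_template_shorter_than_k_yields_empty(rng, primer20):
    hits = scan("ACGTACG", [primer20], SearchConfig())
    assert hits == []
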