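"""Pairing hits into products: orientation, size bounds, topology,
extraction, probe rows."""

import numpy as np
import pytest

from silicopcr import (
    SearchConfig,
    Sequence,
    build_index,
    extract_sequence,
    make_primer,
    pair_hits,
    probe_report,
    reverse_complement,
    scan_template,
)
from silicopcr.fixtures import plant_inverted_repeats


def background(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def implant(t, pos, content):
    return t[:pos] + content + t[pos + len(content) :]


def run_pipeline(template, primers, cfg):
    idx = build_index(primers, cfg.k)
    hits = scan_template(template, idx, cfg)
    return hits, pair_hits(hits, template, cfg)


def test_convergent_pair_length_spans_both_footprints(rng):
    p = make_primer("P1", background(rng, 20))
    t = background(rng, 1000)
    t = implant(t, 100, p.residues)
    t = implant(t, 400, reverse_complement(p.residues))
    tpl = Sequence(id="t", residues=t)
    _, amps = run_pipeline(tpl, [p], SearchConfig())
    assert len(amps) == 1
    a = amps[0]
    assert (a.start, a.end, a.length) == (100, 420, 320)
    assert a.ta_celsius == pytest.approx(
        min(a.forward.tm_celsius, a.reverse.tm_celsius) + np.log(320)
    )


def test_default_size_bounds_filter_products(rng):
    p = make_primer("P1", background(rng, 20))
    t = background(rng, 8000)
    # back-to-back pair: product 40 < default minlen 50
    t = implant(t, 100, p.residues + reverse_complement(p.residues))
    # 6200 bp pair: > default maxlen 5000
    t = implant(t, 1000, p.residues)
    t = implant(t, 7180, reverse_complement(p.residues))
    tpl = Sequence(id="t", residues=t)
    _, amps = run_pipeline(tpl, [p], SearchConfig())
    assert amps == []
    # widening the bounds recovers both
    _, amps = run_pipeline(tpl, [p], SearchConfig(minlen=40, maxlen=7000))
    assert sorted(a.length for a in amps) == [40, 6200]


def test_divergent_and_overlapping_hits_do_not_pair(rng):
    p = make_primer("P1", background(rng, 20))
    t = background(rng, 1000)
    # reverse site upstream of forward site: divergent, no product
    t = implant(t, 100, reverse_complement(p.residues))
    t = implant(t, 500, p.residues)
    tpl = Sequence(id="t", residues=t)
    _, amps = run_pipeline(tpl, [p], SearchConfig())
    assert amps == []


def test_circular_origin_spanning_product(rng):
    p1 = make_primer("F", background(rng, 20))
    p2 = make_primer("R", background(rng, 20))
    t = background(rng, 1000)
    t = implant(t, 900, p1.residues)  # plus hit [900, 920)
    t = implant(t, 80, reverse_complement(p2.residues))  # minus hit [80, 100)
    circular = Sequence(id="c", residues=t, topology="circular")
    cfg = SearchConfig(topology="circular")
    _, amps = run_pipeline(circular, [p1, p2], cfg)
    wrapped = [a for a in amps if a.wraps_origin]
    assert len(wrapped) == 1
    a = wrapped[0]
    assert (a.start, a.length) == (900, 200)
    seq = extract_sequence(circular, a, cfg)
    assert seq == t[900:] + t[:100]
    assert len(seq) == a.length
    # the same template declared linear yields no product
    linear = Sequence(id="l", residues=t)
    _, amps_lin = run_pipeline(linear, [p1, p2], SearchConfig())
    assert amps_lin == []


def test_extracted_length_always_equals_amplicon_length(rng):
    inst = plant_inverted_repeats(seed=11, length=15_000, n_repeats=5)
    cfg = inst.config
    cfg.extract_sequences = True
    idx = build_index(inst.primers, cfg.k)
    hits = scan_template(inst.template, idx, cfg)
    amps = pair_hits(hits, inst.template, cfg)
    assert amps
    for a in amps:
        assert len(a.sequence) == a.length
        assert a.sequence == inst.template.residues[a.start : a.end]


def test_nested_products_are_all_reported(rng):
    f = make_primer("F", background(rng, 20))
    r = make_primer("R", background(rng, 20))
    t = background(rng, 2000)
    t = implant(t, 100, f.residues)
    t = implant(t, 150, f.residues)
    t = implant(t, 700, reverse_complement(r.residues))
    t = implant(t, 800, reverse_complement(r.residues))
    tpl = Sequence(id="t", residues=t)
    _, amps = run_pipeline(tpl, [f, r], SearchConfig())
    assert {(a.start, a.length) for a in amps} == {
        (100, 620), (100, 720), (150, 570), (150, 670)
    }


def test_identical_coordinates_merge_into_one_locus(rng):
    seq = background(rng, 20)
    p1 = make_primer("A1", seq)
    p2 = make_primer("A2", seq)  # duplicate sequence, distinct identity
    t = background(rng, 1000)
    t = implant(t, 100, seq)
    t = implant(t, 500, reverse_complement(seq))
    tpl = Sequence(id="t", residues=t)
    _, amps = run_pipeline(tpl, [p1, p2], SearchConfig())
    assert len(amps) == 1
    assert amps[0].primer_pairs == (
        ("A1", "A1"), ("A1", "A2"), ("A2", "A1"), ("A2", "A2"),
    )


def test_amplicon_cap_truncates_with_warning(caplog):
    inst = plant_inverted_repeats(seed=4, length=30_000, n_repeats=8)
    cfg = inst.config
    idx = build_index(inst.primers, cfg.k)
    hits = scan_template(inst.template, idx, cfg)
    full = pair_hits(hits, inst.template, cfg)
    assert len(full) == len(inst.truth_amplicons) >= 3
    cfg.amplicon_cap = 2
    capped = pair_hits(hits, inst.template, cfg)
    assert len(capped) == 2


def test_probe_report_rows(rng):
    p = make_primer("PR", background(rng, 20), role="probe")
    t = background(rng, 1500)
    t = implant(t, 200, p.residues)
    t = implant(t, 900, reverse_complement(p.residues))
    tpl = Sequence(id="t", residues=t)
    cfg = SearchConfig(probe_mode=True)
    hits, amps = run_pipeline(tpl, [p], cfg)
    assert amps == []  # no pairing in probe mode
    rows = probe_report(hits)
    assert len(rows) == 2
    strands = {r["strand"] for r in rows}
    assert strands == {"+", "-"}
    plus = next(r for r in rows if r["strand"] == "+")
    assert (plus["start_1based"], plus["end_1based"]) == (201, 220)
    assert probe_report([]) == []
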