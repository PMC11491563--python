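# silicopcr

In silico PCR for molecular biologists and genome miners: given one or more
DNA databases (multi-record FASTA, optionally gzipped; a directory of files
is one genome) and a list of primers or probes — IUPAC degenerate codes
allowed on both sides — `silicopcr` finds every binding site under
PCR-calibrated mismatch rules and predicts the products a reaction would
form, on linear, circular and bisulfite-converted templates, for standard,
inverse, multiplex, single-primer inter-repeat (IRAP/ISSR/RAPD-style
fingerprinting) and probe-hybridisation experiments. Typical uses: checking
primer specificity against a genome, mining transposable elements with
inverted-repeat primers, recovering conserved gene fragments (e.g.
retrotransposon reverse transcriptase) with degenerate primer pairs, and
virtual genome fingerprinting.

## The model in brief

A primer binds a same-length template window gap-free. Compatibility is
IUPAC subset intersection; scoring is a weighted Hamming count with

* whole-primer budget `max_mismatches` (default 2),
* at most `number3errors` (default 1) mismatches in the primer's last 7 nt
  (3'-terminal mispairs block polymerase extension),
* stable guanine mismatches (duplex G·G, G·T, G·A) at half weight,
* template N at half weight (never counted against the 3' rule).

Sites are found by a hash of all overlapping primer k-mers (k ∈ {9, 12})
tolerating one mismatch per k-mer via a pigeonhole half-word split, with
bidirectional verification of the full primer around each seed; primers for
which that seed guarantee is provably insufficient are scanned
exhaustively, so the output always equals a brute-force enumeration.
Convergent plus/minus hit pairs within the product-size bounds (default
50–5,000 bp, both footprints included) become amplicons. Per hit, the
melting temperature Tm comes from unified nearest-neighbor ΔH/ΔS sums
(mismatch parameters where published, degenerate positions averaged
per stack, entropy salt correction; 400 nM primer, 50 mM Na+); per product,
the annealing temperature is

    Ta = Tm_min + ln(product length).

See `docs/methods.md` for the full model, design choices and limitations.

## Worked example

Generate a synthetic inverted-repeat instance (a 12 kb template carrying
four copies of one 18-nt primer site in alternating orientations — the
single-primer fingerprinting scenario), then search it:

```
$ silicopcr fixtures make --seed 11 --mode inverted --length 12000 --pairs 4 \
      --out-dir demo
$ silicopcr search demo/primers.txt demo/template.fasta --out -
template                forward_primer  reverse_primer  start_1based  end_1based  length  fwd_mismatches  rev_mismatches  fwd_tm  rev_tm  ta    wraps_origin
template.fasta:irap     P1              P1              2053          4723        2671    0               0               53.7    53.7    61.6  no
template.fasta:irap     P1              P1              7735          9992        2258    0               0               53.7    53.7    61.4  no
```

Reading the first row: the single primer P1 (here `TTTGCATCTGGTGGAGAG`)
binds the plus strand at 2053–2070 and the minus strand at 4706–4723; the
inter-repeat product spans both footprints, 2,671 bp. Both sites are exact
(0 mismatches), each duplex melts at 53.7 °C, and the recommended annealing
temperature is 53.7 + ln(2671) = 61.6 °C. The two convergent copy pairs out
of four planted copies are exactly the products the generator recorded in
`demo/truth_amplicons.tsv`. Useful flags: `--type probe` reports individual
hybridisation sites without pairing; `--circular` enables origin-spanning
(inverse PCR) products; `--bisulfite` searches both converted strand
images; `--sequence-extract` (or `--fasta-out`) adds the amplicon
sequences; `--number3errors`, `--minlen`, `--maxlen`, `--max-mismatches`
and `--k` tune the rules. For example, recovering reverse-transcriptase
fragments with the degenerate pair `CARATGGAYGTNAARAC` / `CATRTCRTCNACRTA`
uses `--number3errors 1 --minlen 200 --maxlen 500 --sequence-extract`
against genome FASTA files or directories.

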