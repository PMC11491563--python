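# Methods

## The problem

In silico PCR predicts where a set of oligonucleotide primers or probes
would bind a DNA database and which PCR products (amplicons) a reaction
would form. The computational core is a mismatch- and degeneracy-tolerant
string search: a primer binds wherever the template carries a site similar
enough, under rules calibrated to what a polymerase actually tolerates, and
two binding sites on opposite strands in convergent orientation within a
size window define a product. `silicopcr` implements this search for
linear, circular and bisulfite-converted templates, with standard, inverse,
multiplex, single-primer inter-repeat (IRAP/ISSR/RAPD-style) and
probe-hybridisation modes.

## Binding model

A primer of length L aligns gap-free against a template window of the same
length (no bulges: primer-template duplexes with indels are outside the
model). Base compatibility is subset intersection over IUPAC codes — both
primer and template may be degenerate; N matches everything. Scoring of a
candidate site:

* an ordinary mismatch costs 1 toward the whole-primer budget
  `max_mismatches` (default 2);
* a **stable guanine mismatch** — the primer's G opposite template G, T or
  A in the duplex; equivalently, any concrete mismatch at a primer G —
  costs 0.5, because G·G/G·T/G·A mispairs hybridise far better than other
  mismatches. We apply this only when both opposed bases are concrete.
* a template **N** matches but costs 0.5, so assembly gaps do not produce
  wall-to-wall hits;
* the last `three_prime_window` bases (default 7) of the primer tolerate at
  most `number3errors` mismatches (default 1), each at full weight
  regardless of guanine status, because 3'-terminal mispairs block
  extension. Template Ns never count toward this limit (an unknown base is
  not evidence of a 3' mispair). In probe mode the 3' rule is disabled
  entirely: hybridisation probes (molecular beacons) need no extensible
  3' terminus.

The whole-primer budget default of 2 follows the e-PCR convention; it is a
weighted budget, so e.g. four guanine mismatches outside the 3' window
still bind.

## Search algorithm

A hash table stores every overlapping k-mer (k = 9 or 12; default 12 when
every primer is at least 16 nt, else 9) of every primer *and* of every
primer's reverse complement, so one pass over the template finds both
orientations. One mismatch per k-mer is tolerated by a pigeonhole split:
each window is keyed under its two halves, and a word matching either half
exactly (degenerate halves are expanded to their concrete half-words,
capped at 4^6 per window; beyond the cap only the less degenerate half is
indexed, with a warning) is verified against the full window. The template
is traversed at one-nucleotide steps; each candidate posting fixes a
diagonal, and the whole primer is verified there under the scoring rules
above. No template index is built; templates stream record by record, so
memory follows the largest record plus the primer index.

**Completeness.** A one-mismatch-per-k-mer seed is not sufficient for every
site the weighted rules accept: a short primer (L < 2k) can carry two
mismatches that fall inside every window, and guanine half-weighting can
stretch the raw mismatch count to 2x the budget. Rather than accept silent
false negatives, each primer is classified analytically before the scan: we
compute (i) the minimum number of mismatch positions that would put two or
more mismatches in every window (greedy demand-2 interval covering — exact)
and (ii) an upper bound on the mismatch positions an acceptable site can
carry given the primer's guanine content and the configured budgets. When
(ii) < (i) the seeded scan is provably exhaustive and is used; otherwise
that primer is searched by direct verification of every diagonal. Results
are identical either way — the randomized equivalence suite compares the
full pipeline against a dense every-offset enumeration — only speed
differs. Primers whose windows exceeded the degeneracy cap are always
scanned exhaustively.

## Topologies and bisulfite mode

Circular templates are scanned as the doubled sequence; hits whose start
falls in the second copy are duplicates and are dropped, while footprints
and products may extend past the origin (inverse PCR). A product on a
circle cannot exceed the circle length. Bisulfite mode scans the two
fully-converted strand images of the template — plus strand: every C
outside CpG becomes T; minus strand (represented on plus-strand
coordinates): every G outside CpG becomes A — under the assumption of
complete conversion with all CpG cytosines methylated and retained; partial
methylation (Y at CpG) is not modelled. Conversion is applied after
doubling so CpG context is correct across a circular origin. Forward and
reverse hits pair within the same image only: a bisulfite product derives
from one converted strand.

## Pairing rules

Any plus-strand hit pairs with any minus-strand hit whose footprint starts
at or after the plus footprint's end (convergent, non-overlapping;
back-to-back is allowed). Product length runs 5' end to 5' end and so
includes both primer footprints — the gel-observable size; bounds default
to 50–5,000 bp. Any primer may act as forward or reverse, which makes
multiplex the general case and single-primer inter-repeat amplification its
degenerate case. Nested products are all reported. Distinct primer pairs
mapping to identical coordinates collapse to a single amplicon row that
lists every contributing pair — with panels of near-identical primers over
repeat families, locus-level counting is the only stable count. A
configurable cap (default 100,000 products per template) guards
repeat-by-repeat blowups, with a truncation warning.

## Thermodynamics

Duplex melting temperatures use unified nearest-neighbor ΔH/ΔS increments
with published single-mismatch and terminal-mismatch parameters (tables
taken from Biopython's MeltingTemp module), the entropy-term monovalent
salt correction ΔS + 0.368·(N−1)·ln[Na+], and the two-state expression
Tm = 1000·ΔH / (ΔS + R·ln c) − 273.15 with c the primer concentration
(primer in excess over template). Defaults: 400 nM primer, 50 mM
monovalent salt — the reaction this tool models. Degenerate positions
contribute the arithmetic mean of ΔH and ΔS over the concrete expansions
at each stack (equivalently, the mean over full-duplex expansions, by
linearity): the Tm of a degenerate primer is the pool-average duplex, so a
heavily degenerate primer reports a much lower Tm against any single site
than its best-matching expansion would — deliberate, since the pool is what
goes into the tube. Mismatch stacks without published parameters contribute
(0, 0): the duplex loses that stack's stabilisation, which keeps the model
conservative and monotone for internal mismatches. A documented edge: under
the published terminal-mismatch parameters a 5'-terminal mispair can
compute marginally *above* the perfect duplex; internal mismatches always
destabilise, and the property tests assert exactly that. Duplexes shorter
than 8 nt are refused (two-state NN model invalid). Reported precision is
0.1 °C.

The recommended annealing temperature of a product is
Ta = Tm_min + ln(length), where Tm_min is the lower of the two hit Tm
values.

## Synthetic instances

`silicopcr.fixtures` generates ground-truth-annotated instances on uniform
A/C/G/T backgrounds: convergent site pairs with exact mismatch placements
(plain, 3'-window, stable-guanine), inverted-repeat layouts for the
single-primer mode, bisulfite instances whose primers are read off the
converted image, and a degenerate-code stress layout. Every instance is
certified against `silicopcr.reference` — a dense, vectorised every-offset
scorer written independently of the seeded search — and regenerated
deterministically from an attempt counter if the random background happens
to contain an unplanned near-match, so the recorded truth is always exact.
All draws sit behind one integer seed in a fixed order; the same seed
reproduces the same instance byte for byte. Uniform backgrounds isolate
algorithmic correctness; they do not emulate repeat-family structure, GC
skew or real mutation spectra, so exact recovery here demonstrates rule
fidelity, not biological sensitivity on real genomes.

## Problem sizes and numerical choices

The randomized equivalence suite runs 1,000 instances with templates of
0.3–1.8 kb, one to three primers of 12–36 nt (degenerate codes included),
both topologies and varying budgets; the acceptance script repeats the same
measurement at 400 instances plus 27 planted instances across all modes, a
40 kb inter-repeat fingerprint, and a 6 kb reverse-transcriptase fragment
recovery with the degenerate RT+/RT− primer pair at number3errors=1,
minlen=200, maxlen=500. These sizes keep a full run in well under a minute
on one core while exercising every code path; the algorithms themselves
stream arbitrarily large FASTA databases. Weighted-budget comparisons use
an epsilon of 1e-9; coordinates are 0-based half-open internally and
1-based inclusive in reports; ties between overlapping hits are never
broken — all are reported, deduplicated only on identical
(primer, strand, start, image).

## Known limitations

* No indels in the primer-template alignment; thermodynamic (ΔG-based)
  site selection and extension kinetics are out of scope.
* The whole-primer mismatch ceiling and locus-dedup semantics are modelling
  choices (documented above); absolute per-genome product counts on real
  genomes depend on both.
* Divalent-cation and dNTP salt corrections, hairpin/self-dimer screening
  and primer design are not provided: this tool searches, it does not
  design.
* Genome-scale databases are supported by streaming, but the scan is pure
  Python; expect roughly a minute per tens of megabases per primer,
  slower for primers that require the exhaustive fallback.
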