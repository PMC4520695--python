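# Methods

This note documents the models behind each `midgemito` module, the tunable
parameters and their defaults, what the synthetic-data generator does and
does not emulate, and the design choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and strand conventions

All internal coordinates are 0-based, half-open, on the linearized major (J)
strand; the J strand is defined as the strand carrying the majority of
annotated genes. On circular records a feature's `end` may exceed the
sequence length (origin-spanning span, interpreted modulo length). GFF3
output converts to 1-based inclusive with J/N mapped to `+`/`-`. Overlapping
features are legal and never trimmed: real gall-midge annotations overlap by
2–31 nt at 15 boundaries. The shipped reference annotation is loadable
as-is: the circle is cut at the first base of trnQ so the published row
order reproduces, with the control region closing the circle.

## Composition and codon statistics

Strand asymmetry uses AT skew = (A−T)/(A+T) and GC skew = (G−C)/(G+C).
Percentages are reported to one decimal and skews to two, rounding half away
from zero — the precision of the published composition table. `N` bases are
excluded from every denominator; a skew whose denominator is zero is
reported as undefined (`None`), never fabricated.

Several published skew cells are not reproducible from their own printed
percentages (e.g. the 16S and ND4 rows); the reference table records which
rows are self-consistent and only those are asserted in tests. Similarly,
the published "41.3%" combined share of the four most frequent codons does
not equal the sum of its own four printed values (41.1) and is not used.

RSCU uses the invertebrate mitochondrial code (NCBI translation table 5; 62
sense codons, AGN = Ser, stops TAA/TAG): RSCU_c = count_c × family_size /
family_total within each synonymous family. Stop codons are excluded from
counts; a coding sequence whose length is not divisible by 3 has its
trailing remainder dropped with a warning.

## Tandem-repeat detection

For each period p in `[min_period, max_period]` (default 2–20) the detector
scans the self-match profile m_p[i] = (s[i] == s[i−p]). Maximal runs of
matches are perfect arrays; with `max_mismatch_frac` > 0 (default 0.1),
adjacent runs are bridged when the gap is within one period's mismatch
budget (at least 1) and the merged stretch stays within the overall
tolerance. This keeps an array with isolated variant copies — e.g. a 12-mer
array in which two copies carry one substitution — as a single hit, while
the junction between two different-motif arrays (where most of one period
mismatches) is never bridged.

Copies = span/period, reported to one decimal, reproducing the published
"5.4 iterations" notation. The motif is canonicalized to the
lexicographically minimal rotation, and the rotation observed at the array
start is kept as the `phase`: the published pentamer motifs AAATT and TAAAT
are rotations of one another and are only distinguishable when the array
boundary is known, which is why the typing key matches phase motifs first
and rotation classes at half weight. Hits whose consensus motif is a power
of a shorter unit are suppressed (the primitive period emits its own hit),
so homopolymers yield nothing at `min_period=2`. Nested hits are removed,
preferring higher copy number then smaller period. In exact mode
(`max_mismatch_frac=0`) the output provably equals a brute-force oracle
(tested on random 300-mers).

Interrupted arrays: same-motif hits within `max_gap` (default 200 bp) merge
into a composite with "11+5"-style notation; the classifier compares the
segment total against the key.

Inverted repeats are found by k-mer seeding (k = 12) of reverse-complement
matches and greedy two-sided extension with a 10% mismatch budget, then
containment dedup; arms ≥ `min_len` (default 30) with spacer ≤ `max_spacer`
(default 600, zero allowed — the hairpin limit) are reported by arm length.

## Biotype typing

RR-I is the subsequence strictly between trnW and trnA, RR-II between trnI
and COI (the published "universal primer" amplicons are emulated by
anchor-gene boundaries; primer sequences are out of scope). Profiles keep
period-5 motifs at RR-I and period-12 at RR-II. The shipped key encodes the
published iteration counts for seven biotypes and two species; printed
ranges ("30–33", "28–37", "5–7", "52–58") are closed intervals.

Classification is lexicographic: motif presence/absence agreement first
(the assay separates GMB5 and the two non-*oryzae* species purely by
absence), then the fraction of counts matching. A count matches when it
falls inside the key interval after widening both endpoints by the relative
`count_tolerance` (default 15%, reflecting the copy-number heteroplasmy the
assay observes within individuals); point values are degenerate intervals.
Ties yield an ambiguous set — an empty profile deliberately returns
{GMB5, fluvialis, oryzivora}, which is exactly the assay's resolution limit,
and the panel round-trip test counts such a member as recovered when the
true label is in the ambiguous set. GMB6's fractional RR-II count includes
its two variant copies (the key's "5.4*" leaves this unstated; counting them
is the default).

## Gene-order analysis

Orders are circular lists of (gene, orientation); the control region is
included as a positional marker by default (toggleable). Conservation is
counted on canonical oriented adjacencies — (A+, B+) ≡ (B−, A−) — and
breakpoint distance is n − conserved. A gene is *conserved* when at least
one of its two oriented boundaries is in the reference (so genes merely
adjacent to a breakpoint do not count as moved), a *local inversion* when
flipping it in place restores a boundary, otherwise *translocation* or
*remote inversion* by orientation after choosing the query reading direction
that best aligns orientations (exact ties broken by canonical rotation).

Blocks come in two flavours. Oriented blocks are maximal runs appearing
identically or fully reversed with all orientations flipped (a signed
inversion). Unsigned blocks ignore strand labels, and a reversed run counts
as inverted: after heavy rearrangement each genome's major strand is
re-anchored, so the published annotation shows blocks that moved "en masse"
in reversed written order with unchanged J/N labels — only the unsigned
notion fires on the real fixtures (ND3-trnG-COIII-ATP6-ATP8 and
trnF-trnE-trnS1-trnN-trnR). The report carries both, plus oriented and
unsigned boundary counts (1 and 25 for the gall midge vs the ancestral
order). The published counts — "14 conserved boundaries", "20 rearranged
genes (15 tRNA + 5 PCG)" — derive from an author/CREx definition that is not
recoverable from the annotation alone; they are surfaced in reports but
never asserted, and the module's correctness rests on exhaustive agreement
with a brute-force adjacency oracle over all signed circular permutations of
up to six genes. The ancestral insect order ships as a replaceable data
fixture with the standard strand assignment (major strand: ND2, ND3, ND6,
COI–III, ATP6/8, CytB; minor: ND1, ND4, ND4L, ND5, both rRNAs, and the tRNA
set {Q, C, Y, F, H, P, L1, V}).

## Control-region scanning

Element calls are pattern/pairing rules, not thermodynamics (the published
analysis used Mfold; no free-energy model is attempted here):

* poly-T: ≥ 8 T allowing one single-base interruption (no published
  threshold exists; 8 finds the canonical dipteran poly-T), longest run wins;
* [TA(A)]n: maximal `(TA|TAA)+` tract with ≥ 4 TA units, longest wins;
* stem-loop: complement-match hairpin search walking anti-diagonals of the
  pairing matrix (Watson–Crick plus G·T wobble), ranked by paired positions,
  then fewer mismatches, then stem length; `hairpin_search` defaults to
  min_stem 8, loop 3–30, ≤ 2 mismatches, while the whole-region scan uses
  exact stems of ≥ 10 pairs and prefers, among the top candidates, one with
  a TATA within 30 bp upstream;
* TATA: literal, the occurrence closest to the stem within 30 bp upstream;
* G(A)nT: literal G, 2–12 A, then T, within 40 bp downstream of the stem;
* G+A-rich: first downstream cluster of 30-nt windows with purine fraction
  ≥ 0.8, trimmed to its outermost purines.

`orientation="auto"` scans both strands and keeps the richer annotation;
minus-strand results are reported in the re-complemented frame with
`strand="-"`. The published 42 bp stem-loop length is reproduced by the
generator's 16 + 10 + 16 layout; no sequence-level test is possible because
the published stem sequence is not printed.

## tRNA folding

`fold_cloverleaf` searches all arm-boundary placements within canonical size
windows: acceptor stem 6–8 (7 canonical) with an optional 1 nt 3' overhang,
D-stem 3–4 with loop 4–9 (or a 4–12 nt connector when absent), anticodon
stem 4–5 with a fixed 7 nt loop (anticodon at centre), variable region 0–23,
T-stem 3–5 with loop 3–9 (or a single ≤ 25 nt TV loop when absent). Scoring
counts paired positions, G·T wobble equal to Watson–Crick. Two constraints
keep chance pairs in 85% A+T sequence from faking arms: a stem placement is
only admissible when it pairs throughout (`max_arm_mismatch`, default 0),
and declaring a D- or T-arm present costs a 2-point parsimony penalty, so a
marginal 3-pair "arm" cannot outbid the simpler layout. Ties break toward
canonical sizes; an `anticodon_hint` (available whenever the tRNA is
annotated) adds a half-point tie-break. Truncation labels: D-arm missing,
T-arm missing/TV loop, short T-arm (stem+loop ≤ 8), no variable arm (0 nt),
short (≤ 2) and long (≥ 15, the "star-like" class) variable arms. The
module classifies given sequences; it does not discover tRNA genes, and the
criterion separating a "much smaller T-arm" from full TV-loop replacement is
a configurable threshold because the published text does not quantify it.

A cloverleaf's reverse complement is itself a near-perfect cloverleaf
(complementarity is symmetric), so planted directionality is only weakly
detectable: the reverse complement folds strictly better in a minority of
constructs (tested at ≤ 25/100). An absolute "never folds better" claim
would need a thermodynamic asymmetry this model deliberately lacks.

## Synthetic genomes: the stated world

The generator emits the published world and is not tuned per test:

* 37 genes in the published order and strands; PCG sizes and rRNA sizes as
  printed; PCGs start ATN and stop TAA/TAG as printed (start/stop codons for
  ATP6/ATP8 and the ND6 TAG stop follow the composition table, which carries
  codons for all 13 PCGs); PCG interiors are i.i.d. sense codons weighted by
  the marginal base composition — no homology to real genes;
* tRNAs are built arm-by-arm with perfectly pairing stems and the published
  truncations (TV loops in trnW/trnA, D-arms missing in trnV/trnN, shortened
  T-arm in trnQ, variable-arm lengths per the annotation table);
* RR-I/RR-II arrays use the published iteration counts; printed ranges take
  their midpoint, except the panel draws GMB4's TAAAT count uniformly from
  30–33 as described for that biotype; GMB3's arrays are split into
  interrupted segments (11+5, 16+29) with ~25–40 bp spacers; GMB6's RR-II
  carries the ATTTATATCTAA variant in two mid-array copies;
* spacers and repeat-locus flanks are rejection-screened to contain no
  tandem array of ≥ 3 copies at periods 2–12, and every planted array gets
  "guard" edits in the flanking spacer (one period each side forced to
  mismatch the array's register) so the detected boundary is exactly the
  planted one — without guards, chance matches in 85% A+T flanks extend
  arrays by fractional copies;
* the 578 bp control region is assembled element-by-element (poly-T(10),
  TA×n tract, TATA, 16+10+16 stem-loop, GA5T, a 32 nt purine block padded by
  pyrimidines) with C guards and screened fillers, then re-scanned; fillers
  are resampled until the scan recovers exactly the planted spans — the
  stated world is a *clean canonical* control region;
* whole-genome A+T hits the target (default 0.857) by calibration: all
  constrained parts are built first, then the rRNA interiors (the one
  unconstrained reservoir, 1988 bp) are sampled at the solved rate, clamped
  to [0.70, 0.98]. The A:T ratio everywhere follows the published marginal
  (A .474, T .383, C .081, G .062), which reproduces the positive
  whole-genome AT skew. Realized A+T lands within ±1 pp (tested over 20
  seeds);
* `mutate` applies i.i.d. substitutions sparing each array's first and last
  copy, so boundaries and motif phase survive low-rate mutation (typing is
  tested to survive rate 0.005).

What the generator does **not** emulate: sequence homology to real
mitochondrial genes, gene-boundary overlaps, sequencing reads or PCR
chimeras, heteroplasmic mixtures, and thermodynamically realistic folding
energies. A green round-trip test therefore establishes that the detectors
recover exactly what the stated world plants — not that they would annotate
a real genome end-to-end.

## Determinism and numerics

All randomness flows from one `numpy.random.default_rng(seed)` per genome;
equal specs and seeds are byte-identical. Derived seeds stay below 2^31.
Rounding is half away from zero throughout the reporting layer; copy numbers
are compared at 1 decimal; the detector's span/period/copies identity is
exact by construction (|span/period − copies| ≤ 0.05 after rounding).

## Known limitations

* The repeat detector is not the published Tandem Repeats Finder scoring
  model (alignment/probabilistic criteria); its parameters were chosen to
  reproduce the published iteration tables on synthetic arrays and are
  configurable. The published TRF parameters are not stated.
* Biotype typing assumes the anchor genes are annotated; it does not locate
  trnW/trnA/trnI/COI de novo.
* The gene-order classifier's per-gene classes depend on the adjacency
  formalism; genes inside a block that moved en masse keep their boundaries
  and classify as conserved, which is one reason the published "20
  rearranged genes" is not recomputable exactly.
* TDRL/common-interval scenario enumeration, thermodynamic folding,
  BLAST-based gene identification, de novo tRNA finding and phylogenetics
  are out of scope.
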