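# Methods

## Coordinates, strands and the circular molecule

Internally every feature is 0-based half-open on the forward strand of
the deposited sequence; a feature crossing the origin is encoded with
`end > genome length` and interpreted modulo the length, so one
biological gene is always one feature object. GenBank `join()` spans
across the origin are collapsed to this wrap convention on read and
re-expanded on write. All user-facing tables are 1-based inclusive.
Strands are called J (majority, the forward strand) and N (minority);
gene orders carry the strand as a sign.

Unknown gene names never abort a run: they are kept as flagged
`unknown:<raw>` features, excluded from 37-gene logic, and surfaced as
warnings. Plain `tRNA-Leu` / `tRNA-Ser` annotations are ambiguous
between the two isoacceptors and stay flagged unless an anticodon is
available; the disambiguation follows the standard assignment
trnL1 = CUN (anticodon UAG), trnL2 = UUR (UAA), trnS1 = AGN (GCU/UCU),
trnS2 = UCN (UGA).

## Composition and skews

AT skew = (A − T)/(A + T), GC skew = (G − C)/(G + C). Ambiguity codes
are tallied separately and excluded from every denominator, since the
formulas are defined on A, C, G, T only; an empty denominator yields NaN
rather than an exception. Multi-feature composition concatenates the
selected regions in genome-forward orientation by default — the
J-vs-N-strand PCG contrast is meaningless otherwise — with a
`reading` mode that reverse-complements N-strand features first.
Genome-level percentages print at one decimal, control-region
percentages at two, matching the precisions customary in mitogenome
descriptions; full-precision values are kept in the JSON outputs.

## Codon usage

The genetic code is fixed to the invertebrate mitochondrial table
(translation table 5) and is deliberately not configurable: every
operation in scope concerns insect mitogenomes. Synonymous families
split Leu and Ser by isoacceptor (Leu1 = CUN, Leu2 = UUR, Ser1 = AGN
including AGA/AGG, Ser2 = UCN), the convention mitogenomics papers use
for RSCU plots and amino-acid composition tables; family means of RSCU
are exactly 1 whenever the family is used, which the test suite asserts
to machine precision. Codon totals exclude terminal stop codons whether
complete or incomplete (a 1–2 nt remainder is dropped); codons
containing ambiguity codes are skipped and counted separately; in-frame
stops before the annotated end are flagged as premature rather than
counted.

## Start and stop calling

Start identification re-derives the annotated start under the
minimize-intergenic-space principle. Candidates are trinucleotides at
offsets 0..W (default W = 60 bp) downstream of the upstream gene's 3′
boundary, constrained to the reading frame fixed by the annotation and
forbidden from overlapping the upstream gene. The candidate alphabet is
three-tiered: canonical ATN; atypical AAN (AAC/AAT); then
GTC/GTG/TTG/CAA/CGA/AAA/CTA, which are the alternative initiators
reported across insect mitogenomes. Ranking is lexicographic on
(offset, tier): the nearest candidate wins, and tier breaks exact
offset ties only — so an AAC one base after the upstream tRNA defeats a
canonical ATN 34 bp away, the geometry that makes asparagine codons the
accepted COX1 start in many polyphagan beetles. The 60 bp window covers
that observed 34 bp case with ample margin. No candidate in the window
yields an explicit no-call flag.

Stops are read off the annotated span: a terminal in-frame TAA/TAG is
complete; a remainder of T (or TA, flagged distinctly since published
tables usually report only T) abutting the downstream gene is an
incomplete stop completed by polyadenylation.

## Gene orders, breakpoints and event classes

Orders are circular sequences of signed labels, equal iff one is a
rotation of the other; reflections are never identified because the
molecule has a fixed reading strand and reflection would conflate an
inversion with identity. Breakpoint distance counts unsigned reference
adjacencies missing from the observed order, with NCR elements excluded
throughout: NCRs are products of a rearrangement, not markers, so they
annotate the report instead of entering the distance. The moved-gene
computation exhaustively searches removal sets of increasing size until
the remainders are rotation-equal with signs; all minimal sets are
reported (the trnI/trnQ swap genuinely has two optima and asserting one
would be arbitrary). The search is capped at five moved genes — far
beyond any single observed mitogenome event — and classifies as
`complex` beyond that.

Event classes: `none` for signed rotation-equality; `inversion` when
the unsigned orders agree but signs flipped in place (note this has
breakpoint distance zero under unsigned adjacencies — sign changes
surface only through this class); `translocation` when some optimum
moves genes without changing their strand; `complex` otherwise.

## TDRL enumeration

For sign-preserving events the breakpoint-bounded window — the minimal
circular arc of the reference covering all broken adjacencies, matched
to the corresponding arc of the observed order — is searched
exhaustively: every contiguous block of the source window is duplicated
in tandem and every assignment of lost copy (2^block) applied; scenarios
whose result equals the target window are returned. The window is capped
at 12 elements (the observed hotspot, control region–trnI–trnQ–trnM, has
four), keeping the exact search instantaneous. Each scenario records,
per NCR in the target, the lost copies whose flanking kept genes bracket
that NCR — the candidate origins of the non-coding remnant. The
enumeration does not assert which lost copy decayed into the NCR; all
adjacent candidates are reported, since sequence similarity of the
remnant is outside the model. Scenarios are re-applied mechanically in
tests and must reproduce the target; an independent partition-based
brute-force enumerator cross-checks reachability on all small windows.
Strand changes rule a single TDRL out immediately, so enumeration is
only attempted for sign-preserving events.

NCR length classes follow the observed dichotomy: NCR1 below 100 bp,
NCR2 above 400 bp; the unobserved 100–400 bp range is reported as
`intermediate` rather than forced into either class.

## Region scanning

Adjacent-feature records are signed (negative = overlap, 0 = abutting,
positive = intergenic spacer) and include the origin-spanning pair, so
feature lengths plus signed spacer lengths always telescope to the
genome length — an invariant the tests enforce. Features fully nested in
another are excluded from the chain (with a warning) to keep that
conservation meaningful. Every positive spacer ≥ 1 bp is reported, with
a configurable threshold (and a convenience count at ≥ 5 bp) because
published "intergenic space" counts typically apply an unstated minimum.
Motif search honours IUPAC degeneracy and overlapping hits, on the
forward strand by default with a both-strands switch.

The tandem-repeat finder is exact-match only, by design: maximal arrays,
possibly with fractional trailing copies, reported once under their
smallest period (so `AAAA` is a period-1 array, not a 2-mer repeat, and
is excluded when the unit range starts at 2). Mismatch-tolerant
detection in the style of alignment-based repeat finders is explicitly
out of scope. The control region is located structurally — the span from
the end of rrnS to the next annotated gene, circularly (trnI in the
ancestral arrangement, trnQ in the rearranged one) — rather than trusting
a CR annotation; whether flanking micro-spacers belong to the CR is a
boundary convention, and this one is documented and fixed.

## The synthetic generator

The generator emulates the observables of a real insect mitogenome
description: a 37-gene circular molecule of ≈16.4 kb with realistic PCG
lengths (ATP8 156 bp, ND5 1716 bp with a complete stop or 1714 bp with
an incomplete T), 65 bp tRNAs, 780/1280 bp rRNAs, a long AT-rich control
region carrying an exact tandem repeat, an 8 bp trnW/trnC overlap, a
TACTAA or TACTA motif in the trnS2–ND1 spacer, an 11 bp C-stretch in
the trnK–trnD spacer of the rearranged preset, and an NCR of 56 bp
(NCR1) or 412 bp (NCR2) between trnQ and trnI. Defaults: background
AT = 0.72, AT skew = +0.05, GC skew = −0.15, control region AT = 0.85 —
mid-range values for scarab mitogenomes.

Composition control is by construction, not by sampling: background
regions are laid down with largest-remainder-rounded exact base counts
and shuffled; PCG bodies are quota-sampled from sense codons whose base
weights are tilted by a fixed-point iteration so that the stop-free
codon distribution has exactly the target composition (naively
conditioning on "not a stop" would deplete A/T, since TAA/TAG are
A+T-rich). Minority-strand genes are generated against complemented
targets so the genome-forward composition is homogeneous. The recorded
ground-truth expectation for whole-genome AT is the length-weighted
mixture of the background and control-region targets; the measured value
lands within ±0.01 of it, and skews within ±0.02, which the acceptance
tests check at 16 kb.

What the generator does **not** emulate: tRNA/rRNA secondary structure
(bodies are plain background), codon usage shaped by selection (bodies
are composition-driven), control regions with replication-origin
structure, sequencing error, or heteroplasmy. Passing the round-trip
tests therefore demonstrates that the analysis stages are correct on
their own definitions — that annotations, geometry, codon bookkeeping
and rearrangement logic are recovered exactly — not that the pipeline is
robust to mis-annotated or structurally unusual real records.

Spacer content that must carry a planted motif or homopolymer is
resampled (deterministically, from the same seeded generator) until the
planted instance is the unique hit and is maximal, so ground truth is
exact rather than probable. One integer seed drives all draws; fixed
spec + seed is byte-reproducible, and changing only the seed never
changes annotation geometry.

## Numerical and degenerate-input choices

Undefined skews return NaN. Zero-length control regions are flagged, not
errors. `classify_ncr` rejects non-positive lengths. Start-call ties at
equal offset (possible only between candidate classes, not concrete
codons) resolve canonical > AAN > other. The moved-gene search reports
every optimum rather than an arbitrary one. TSV outputs are
deterministically ordered and byte-stable for fixed inputs and
configuration.

## Problem sizes

The default test and acceptance workloads use two full 16.4–16.5 kb
genomes per run, 20 randomized generator specs for the round-trip
property, 200 random permutations (windows ≤ 6) for the TDRL oracle
comparison, and 100 random tables/sequences for the RSCU and composition
properties — sizes at which every exhaustive check is exact and the
whole suite runs in a few seconds.
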