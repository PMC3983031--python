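# Methods

## The mapping policy and its consequences

Reads are mapped in two steps. Step 1 is an exhaustive ungapped scan of both
strands; the score is the mismatch count, any N counts as a mismatch, and
all locations tying the minimum are returned when that minimum is ≤ 4.
Step 2, applied only to reads with no step-1 placement, searches every
(position, split, gap) triple with one gap of 10–20000 nt, ≤ 3 mismatches,
and ≥ 12 nt of aligned sequence on each side of the gap; again all
best-score placements are returned. A read is accepted iff its best score
occurs at ≤ 2 locations; a read kept at 2 locations contributes a count at
both, flagged in a separate ambiguous column so downstream tables stay
auditable. Step precedence is strict: a read with any step-1 placement
within budget never reaches step 2, even if a gapped placement would score
better.

The gapped search is implemented with prefix/suffix cumulative mismatch
tables over a sentinel-padded chromosome and a forward sliding-window
minimum over admissible gap lengths; the test suite checks it bit-for-bit
against a brute-force enumerator organized completely differently.

Three consequences of the 12 nt anchor rule matter for interpretation:

- junction-spanning reads with an overhang ≤ 4 nt are silently absorbed by
  step 1 (≤ 4 mismatches against intronic sequence) and look unspliced;
- overhangs of 5–11 nt usually map nowhere — or, worse, acquire a
  best-scoring *shifted* gapped placement one or a few nt away from the true
  junction, creating low-count artifact junctions;
- only reads with both anchors ≥ 12 nt are reliably recovered, and for
  error-free libraries restricted to such reads recovery is exact (every
  read uniquely placed at its true position).

The artifact class is left visible in output (often as `outside_icg` or
near-annotated `alternative` events with minimal support) rather than
filtered, because a support threshold strong enough to remove it would also
remove genuine low-frequency events. The end-to-end recovery test therefore
scores the pipeline on the reads the policy can see as spliced, subtracting
step-1-absorbable reads identified by an independent oracle.

This aligner is intended for toy genomes (≤ ~50 kb); for genome-scale data
the pipeline ingests external SAM through the same filter semantics
(N-operator gaps, NM/NH tags, indel-containing records rejected).

## Junction classification and splice products

Junctions collapse by identical (chromosome, skipped interval). Status is
decided against the annotation: an exact match to an annotated intron is
`annotated`; containment in an ICG's transcript span without an exact match
is `alternative`; anything else is `outside_icg` and excluded from event
statistics. Because the library protocol is unstranded, an unannotated
junction inherits its containing gene's strand; junctions contained in more
than one gene are assigned to the first and the others recorded, never
silently dropped.

A splice product is the canonical transcript with the single overlapped
annotated intron's excision replaced by the event's excision; events
overlapping zero or two annotated introns are refused (one junction per
read is the observable, so compound patterns are handled one junction at a
time). Translation starts at the annotated start codon mapped through the
new exon structure; if the start itself is excised the product is flagged
`start_lost` and excluded from PTC statistics. `is_ptc` requires the first
in-frame stop strictly upstream of the canonical stop's mapped position —
a frameshift that reads *through* the canonical stop position and
terminates in the 3′ UTR is an extension, not a PTC. Products with no stop
at all are flagged `nonstop`. Stop codons are TAA/TAG/TGA (standard nuclear
code). NMD candidacy defaults to `is_ptc` itself; an optional 3′-UTR length
threshold implements the faux-3′-UTR interpretation under which a PTC with
a short 3′ UTR escapes decay (off by default, since no systematic threshold
is established).

## Statistics

Counts are depth-normalized by total mapped reads (reference = wild type),
which preserves within-sample ratios exactly. Enrichment folds are
normalized mutant / normalized WT, per unit and aggregated by summing raw
counts first. The p-value is the Poisson upper tail P(X ≥ k) with λ = the
WT count scaled to the mutant's depth; the upper tail (not the point
probability, which is non-monotonic) is the reading consistent with testing
*enrichment*. WT zeros take a pseudocount of 0.5 so folds and p-values stay
defined; passing `pseudocount=None` disables this and reports NaN folds.
No multiple-testing correction is applied by default; Benjamini–Hochberg is
available behind a flag. Unique-event counting (one per event per sample,
the unit of Venn-style overlaps) and read-support counting are both
provided; enrichment can be computed on either, and the parameter-recovery
analyses use read support because the decay model predicts read counts.

RPKM is count / (kb × million mapped). Unspliced signal counts a read once
per gene when any aligned block overlaps an intron by ≥ 1 nt, except gapped
reads whose gap exactly equals one of that gene's introns (those are
spliced). Note that reads from intron-*retention* splice products also
overlap intronic bases and are counted as unspliced signal — an inherent
ambiguity of interval-based counting that depresses measured unspliced
enrichment, since retention products are themselves often NMD targets.

Position-frequency matrices weight one sequence per unique event (not per
supporting read). Information content is 2 + Σ f log₂ f bits per position
with 0·log 0 = 0; the small-sample correction 3/(2·ln2·n) is off by default
and available as a flag. Donor windows are 6 nt (covering GUAUGU) and
acceptor windows 8 nt (terminal YAG plus pyrimidine context); both are
configurable, and sub-14 nt introns yield truncated, flagged windows.

## The simulator

Each toy gene has two exons (150–400 nt each), one intron (90–200 nt) with
GTATGT donor, TACTAAC branchpoint 30 nt from the 3′ end, a T-rich
pyrimidine tract and a TAG acceptor; a 20–50 nt 5′ UTR, a 45–90 nt 3′ UTR,
and a CDS with no internal stop whose junction sits ≥ 33 nt inside the
coding region so alternative excisions hit coding sequence. Genes alternate
strands and are separated by 200–400 nt random spacers. Alternative sites
are planted at configured offsets; intron-internal sites carry configurable
degenerate motifs (default GTTTGT donors, AAG acceptors), exonic sites keep
the random sequence that is there (cryptic-site realism). The default
geometry cycle covers the observed event classes: +7 and +17 nt downstream
acceptors (frameshift), a −6 nt upstream acceptor whose retained sequence
ends at the canonical TAG (in-frame PTC when the phase cooperates), +16 and
+9 nt intronic donors, and a −30 nt in-frame exonic donor deletion.

Two generator safeguards are worth knowing. First, junction *wobble*: an
excision whose first base equals the base following it (or last base equals
the base preceding it) can slide at equal alignment score, so such genes
are re-drawn; a few offsets are structurally ambiguous for every draw
(e.g. a 1 nt donor-side retention is sequence-identical to a 1 nt
acceptor-side retention) and are rejected with an error. Second, the
canonical CDS is re-checked after motif planting so its first in-frame stop
is the real stop.

Isoforms per gene are canonical, one per planted event, and unspliced
pre-mRNA, with pre-decay proportions 0.65 / 0.20 (split equally among
events) / 0.15. These are free parameters — per-gene alternative-splicing
rates are not established quantities — chosen once to give every isoform
class useful read support at toy library sizes. Decay is a single
steady-state retention factor r ∈ (0,1] applied to every NMD-target isoform
(planted PTC events and, by default, the unspliced isoform) in NMD-competent
genotypes, followed by renormalization; there are no kinetics because only
steady-state ratios are compared. Expression weights are log-normal
(σ = 1), drawn once per scenario and shared by all genotypes and by the
closed-form calculator. Reads are 75 nt, single-end, uniform over start
positions, with i.i.d. substitution errors (default 0.1%); there is no
positional bias, no quality model, no paired ends, no PCR duplicates.

The closed form for an event's expected read share is
θ_g · q_iso(genotype) · span(j, M, L)/(M−L+1), with span(j, M, L) the exact
count of junction-covering start positions (L−1 when interior); aggregate
expected folds follow by summation, and `solve_retention_for_fold` inverts
the monotone fold–r relationship by Brent's method (tolerance 1e-12).
Because the generator and the calculator share θ and the isoform mixes, the
measured pipeline fold is an unbiased multinomial estimate of the closed
form — which is what the parameter-recovery test checks, using a log-scale
95% CI (√(1/k_mut + 1/k_WT)) from the measured counts.

What passing simulation tests does *not* show about real data: real introns
have heterogeneous signal strengths and branchpoint–acceptor geometries,
real libraries have positional coverage bias and quality-correlated errors,
real NMD efficiency varies per transcript rather than being one global r,
and real annotations contain multi-intron and overlapping genes. The
simulator validates the pipeline's bookkeeping and statistics, not the
biology.

## Problem sizes

Validation runs use sizes chosen to make every check exact or tightly
bounded while remaining desk-scale: the aligner-equivalence check uses 20
random 10 kb genomes × 200 mixed reads against the brute-force enumerator;
PTC calls are checked on 500 randomized planted events against a
full-translation oracle; parameter recovery simulates 4 genotypes × 200k
reads over 50 ICGs; end-to-end truth recovery uses 8 genes × 3500 reads in
two genotypes; the acceptance script's study is 50 ICGs (two in seven
without alternative sites) × 200k reads × 4 genotypes.

## Known limitations

- One gap per read; exon-skipping (multi-intron) events, indels and
  trans-splicing are out of scope.
- First/longest transcript per gene only; no multi-transcript genes.
- Junctions from reads with < 12 nt overhangs are invisible or artifactual
  (see above); real pipelines share this blind spot in kind if not degree.
- Interval-based unspliced counting conflates retention products with
  pre-mRNA.
- The Poisson test ignores biological dispersion; it answers the paper-scale
  question (is this mutant count consistent with the WT rate?) and nothing
  more.
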