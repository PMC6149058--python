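# Methods

## Coordinate model and the genome class partition

All coordinates are 0-based half-open internally (BED-native). HOMER peak
text is 1-based inclusive and is converted on load; UCSC rmsk `genoStart`
is treated as 0-based. Strand is carried through I/O but ignored by every
occupancy and overlap computation — peaks are unstranded, and no analysis
here defines a strand-aware rule.

Class interval sets (promoter, TTS, exon, 5′UTR, 3′UTR, CpG island, small
RNA, tRNA, rRNA, intron) may overlap arbitrarily on input. They are
resolved into a disjoint partition by an explicit priority list — the order
above by default, mirroring the usual annotation hierarchy of
dominant-feature annotators — with earlier classes claiming contested
bases and intergenic defined as the residual complement. This makes the
occupancy baseline exact by construction: per-class bp sums equal the
genome size G (the sum of supplied chromosome lengths; unplaced contigs
count only if supplied), and fractions g_c sum to 1. The partition builder
is implemented as merge/intersect/subtract sweeps on sorted `(start, end)`
pairs and is tested against a per-base painting oracle.

Published occupancy figures can be injected directly via
`GenomeClassPartition.from_occupancy`, which is how the report reproduces
the intergenic share 813,929,088/2,631,564,759 = 30.93% from its printed bp
inputs. (The analogous worked quotient "380/1158" equals 32.82%, not the
41.17% sometimes quoted alongside it; the report always computes the true
quotient.)

## Peak annotation

A peak receives exactly one sequence class. The default `max_overlap` rule
assigns the class with most overlapping bp, breaking exact ties by the
partition priority; the `midpoint` rule assigns the class containing
`floor((start+end)/2)` and is kept for comparability with midpoint-style
annotators. The two rules agree whenever a peak lies wholly within one
class region (property-tested). A peak receives at most one repeat
category: the RepeatMasker instance with greatest bp overlap, ties broken
by category name order. One class and at most one category per peak makes
every tally sum to its total; duplicated or overlapping peaks are all
counted — deduplication, if wanted, is the caller's responsibility.
Tallies count peaks, not bp; the report header states this.

## Differential enrichment

For a candidate region with counts (k_A, k_B) at total depths (d_A, d_B),
direction A>B forms the null expectation λ = max(k_B, c)·d_A/d_B with
pseudocount c = 0.5 (applied to the background count before depth scaling,
so zero-background regions remain testable while large counts are barely
perturbed), and computes the cumulative Poisson tail p = P(X ≥ k_A) via
the survival function (stable to λ ~ 10⁶; k = 0 returns exactly 1). The
fold change FC = (k_A/d_A)/(max(k_B,c)/d_B) = k_A/λ is depth-normalized —
when depths differ, the fold threshold applies to normalized counts. A
region is called iff FC ≥ 2 and p < 10⁻⁴; the reciprocal direction swaps
the roles, and with a fold threshold ≥ 1 the two direction lists are
disjoint. No multiple-testing correction is applied to differential calls;
this is the classic raw-p differential-peak rule, and FDR-style
re-analyses are out of scope.

A calibration note: because λ is estimated from a single noisy background
count, the raw tail p is anticonservative under the null — at any mean
coverage, roughly 0.5% of null regions reach p < 10⁻⁴ on p alone. The
*caller* is nevertheless well behaved because the fold gate binds: at the
synthetic study's default coverage (80 reads/region, typical of
broad-mark candidate regions at ~20 million mapped reads) the per-direction
false-call fraction on 10⁴ null regions is ≤ 5×10⁻⁴, while planted 4-fold
regions at a much lower 20 reads/region are still detected with
sensitivity ≥ 0.95. Users testing very low-coverage regions should expect
the p-value, not the joint rule, to be optimistic.

## Representation statistics

Fold enrichment is observed/expected everywhere: f = (k/n)/(K/N) for
repeat categories and f = (O_c/T)/g_c for sequence classes, so f > 1
always reads "over-represented". (Published analyses of this kind have
used both this and the inverse convention, sometimes inconsistently; the
convention here is fixed and printed in every report header.)

- **Repeat categories** are tested by instance counts (not bp) against the
  catalog universe: p_over = P(X ≥ k) and p_under = P(X ≤ k) for
  X ~ Hypergeometric(N, K, n). The two tails satisfy
  p_over + p_under − P(X = k) = 1 (tested).
- **Sequence classes** use a 1-df chi-square goodness of fit of
  (O_c, T−O_c) against (T·g_c, T·(1−g_c)), two-sided, without continuity
  correction by default (counts are large in this design; a Yates flag
  exists).
- **Transcript class-count tables** use per-class 2×2 Fisher exact tests
  (class vs rest, condition 1 vs 2); the reported fold is the ratio of
  within-condition proportions, 1 = no enrichment relative to random
  distribution. Degenerate tables (a zero margin) return p = 1 with an
  undefined (NaN) odds ratio.

Benjamini–Hochberg adjustment is applied within one family per report:
all repeat categories together, all sequence classes together, all
transcript classes together. p-values are floored at 10⁻³⁰⁰ so extreme
tails print as numbers ("p ~ 0" cases).

## Synthetic data generator

The generator emulates the study design at desk scale: a 2×500 kb toy
genome whose class fractions leave an intergenic residual of ~31% (the
genome-wide intergenic share the occupancy baseline reports) with introns
the largest annotated class; a 2,000-instance repeat catalog whose
category proportions follow the RepeatMasker catalog shape (SINE-heavy,
LINE ≈ 19% of repeats) covering roughly 45% of the toy genome; 2,000
peaks of width 500 bp; region counts at two 20-million-read depths with a
mean of 80 reads/region; and 2×C class-count tables of 10⁵ transcripts
per condition.

Design choices that were genuinely open:

- **Planted enrichment semantics.** A class multiplier m is the planted
  fold: enriched classes get sampling probability exactly m·g_c and only
  unenriched classes are rescaled to fill the remainder. A global
  proportional renormalisation would shrink every planted fold by the
  normalising constant (severely for large classes like intergenic),
  making "recover the planted fold" ill-posed. The same scheme drives the
  class-count shifts.
- **Block layout.** Class bp is laid down as shuffled 1 kb blocks with
  multinomially-sized intergenic gaps along a concatenated coordinate,
  then cut at chromosome boundaries — realized fractions match targets to
  block-size rounding (well inside 2% absolute), and repeat counts are
  exact by construction.
- **Boundary truth.** Peaks are placed wholly inside a single class
  region, so the recorded true class always equals the pipeline's own
  max-overlap assignment; region counts live on a separate synthetic
  contig and are not annotated.
- **Substreams.** Each generator draws from a named substream
  (seed + CRC32 of the generator name), so adding or re-parameterising one
  generator never perturbs another's output and identical configs are
  byte-reproducible.

What the generator does **not** emulate: nucleotide sequence, reads or
alignments; spatial autocorrelation of marks; peak-width variation and
partial class overlap at boundaries; copy-number or mappability artefacts;
biological between-replicate variation (counts are exactly Poisson, class
draws exactly multinomial). Passing recovery tests therefore shows the
statistics and bookkeeping are correct under the stated model, not that
the pipeline is robust to real-data artefacts.

## Numerical and reporting choices

Distribution tails come from scipy (`poisson.sf`, `hypergeom.sf/cdf`,
`fisher_exact`, `chi2.sf`) and BH from statsmodels, each verified in the
test suite against independent oracles: direct pmf summation (all k ≤ 50,
six λ), full hypergeometric enumeration (N ≤ 30), full 2×2 table
enumeration, and a hand-written step-up. Ties in class assignment and
repeat assignment are deterministic (priority order, category name order).
Empty inputs are valid everywhere (empty peak file → empty set; empty
region list → no calls; empty p-value list → empty adjustment). Reports
are TSV with `#` metadata headers recording the package version, config
hash and fold convention; pipeline re-runs on identical inputs are
byte-identical, and the manifest records row counts per table.

The acceptance script (`scripts/acceptance.py`) re-runs the synthetic
study from scratch at the sizes above — 10⁴ null regions for caller
calibration, 100 fold-4 regions at 20 reads/region for sensitivity, 2,000
peaks with a planted 2-fold intergenic enrichment, a 10-fold LINE
class-count shift at 10⁵ transcripts, and 2,000 null hypergeometric
replicates across 8 categories for type-I error — all driven by a single
seed.

## Known limitations

- Whether peak-class proportions should count peaks or bp is ambiguous in
  published figures of this kind; counts are implemented and stated in the
  report header.
- The chi-square class test treats classes marginally (one test per class
  against its own baseline), not as a joint multinomial test.
- The priority hierarchy is a documented choice, not a reconstruction of
  any particular annotator version.
- The GTF→class-BED path is out of scope: class interval sets are inputs.
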