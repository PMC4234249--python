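# Methods

## Overview

smvkit quantifies somatic microsatellite variation (SMV): the presence of
low-frequency, non-haplotype ("minor") alleles at short-tandem-repeat loci
inside a single sequencing sample, without a matched normal. The pipeline
has four stages — catalogue, call, classify, profile — plus a read
simulator used to characterize how sequencing error masquerades as minor
alleles and to set the read-support rules that suppress it.

## Microsatellite catalogue

A microsatellite locus is a tandem repetition of a 1–6 nt motif. The
scanner locates, for each motif length k, every maximal exact period-k run
of at least two units, then extends each run across interruptions of at
most k mismatching bases as long as the *purity* of the window stays at or
above the threshold. Purity is defined as the fraction of window positions
matching a perfect ungapped tandem tiling of the motif, maximized over
motif rotations. This detector is deliberately simple and fully
reproducible; it is not an attempt to re-implement alignment-score-based
repeat finders, whose wraparound dynamic programming uses weights that
cannot be recovered from their parameter strings. Consequences of the
definition:

- purity is 1 exactly when the window is a perfect tandem repetition of
  some rotation of the motif;
- a window whose best-fitting motif is shorter than k is suppressed and
  reported at its own period (so `AAAA` is a mononucleotide run, never a
  dimer run);
- ambiguity codes (N) terminate runs and never appear inside a locus.

Catalogue filters (defaults): locus length >= 8 nt, motif copies >= 3,
purity >= 0.85. Overlapping candidates are resolved by higher purity, then
greater length, then leftmost start, then shortest motif — a total order,
so cataloguing is deterministic. Coordinates are 0-based half-open
everywhere; the catalogue TSV doubles as BED3+.

Control ("non-MST") loci are fixed-length segments (15 nt) sampled
uniformly from the reference, rejecting segments containing N or
intersecting any catalogue locus.

## Allele calling

For each catalogue locus, a read contributes one observation when it

1. fully spans the repeat plus a fixed-length anchor on each side
   (`flank_length`, default 5 nt; 7 supported);
2. has mapping quality >= 10;
3. has base quality >= 28 at every base inside the repeat;
4. matches both flank anchors exactly (a one-mismatch tolerance exists but
   is off by default).

The allele is the read substring strictly between the anchors, so
insertions and deletions inside the repeat change allele length. Distinct
allele sequences are tallied with strand-aware support. An allele is
*called* when it has >= `min_reads_per_allele` supporting reads (default
3; 2 and 4 supported) including at least one read on each strand. The
both-strand rule reads "verified in both directions" as strand duality —
the standard sequencing-artifact filter — rather than mate-pair duality; a
`require_both_strands` toggle exposes the alternative.

Zygosity (depth = all retained observations, the denominator the
heterozygote fractions refer to; loci below depth 15 are not genotyped):

- the most common allele is haplotype allele 1;
- the second most common allele joins the haplotype (heterozygous call)
  when its support exceeds 25% of depth, or, failing that, 50% of the
  major allele's support;
- every other called allele — and a runner-up failing the heterozygote
  test — is a minor allele.

Ties in support are broken by longer allele, then lexicographically;
inequalities are strict. These conventions make calling a pure function
of the pileup.

## Classification

Each minor allele (optionally also the second haplotype allele) is classed
against the major allele by length difference alone: equal length with a
different sequence is one SNP-class allele (however many positions
differ); longer is an expansion; shorter a contraction. A length change
that is an exact multiple of the motif length is flagged *in phase* — the
polymerase-slippage signature. An allele differing both in length and in
content is classed by its length delta; the package does not align alleles
to localize changes.

## Simulator

The simulator builds the study conditions for error characterization:

- **Reference.** `n_loci` perfect tandem repeats (primitive units; motif
  lengths 1–6 weighted 40/25/15/10/5/5; locus lengths 8–44 nt) separated
  by 500 nt non-repetitive flanks. Flanks are verified by the catalogue
  scanner itself: a flank is redrawn until it contains no catalogue-grade
  repeat, and its first/last 2k bases are drawn from bases mismatching the
  neighbouring repeat's continuation so no candidate can extend across a
  junction (a local scan verifies every junction). Unit draws that scan to
  anything other than their own interval (units with internal
  near-periodicity such as ACACAG) are rejected, which slightly biases the
  unit distribution toward self-dissimilar motifs.
- **Truth.** A configurable fraction of loci (default 5%) is heterozygous,
  the second allele an in-phase change of ±1–2 repeat units. A
  configurable fraction receives one planted subclonal minor allele (±1
  unit) at a read fraction drawn from (0.06, 0.18), below the heterozygote
  threshold.
- **Reads.** 2x100 bp pairs. Per-locus spanning depth is Poisson with a
  gamma-distributed mean (shape 8, mean 50) — the overdispersed,
  exome-like mode — or plain Poisson in "uniform" mode. One mate of each
  pair spans the repeat plus 7 nt anchors; the other lands at fragment
  distance (300 nt) and never spans a neighbouring locus (flank length is
  chosen to guarantee this). Errors are injected per base: substitutions
  and single-nucleotide indels in a 90:10 mix by default (an SNP-dominated
  error spectrum). Alignments are emitted pre-positioned with exact
  CIGARs, so mapping error is out of scope by construction. Base
  qualities are 35 everywhere; error positions can optionally be given
  low quality, but by default are not, so quality filtering and
  read-threshold effects can be studied independently.
- **Read-to-allele allocation.** Planted minors draw their read counts
  Binomial(depth, f), so minor-allele recovery follows a binomial support
  model. The remaining reads are split between the haplotype alleles in
  exact proportion rather than multinomially. This is a deliberate
  variance-reduction choice: with multinomial sampling, roughly 1–3% of
  heterozygous loci at depth 15–30 randomly fail the heterozygote support
  rule even with zero sequencing error, which would make "error-free
  calls equal planted truth" unattainable and conflate sampling noise
  with caller behavior.

What the generator does not emulate: mapping/alignment error, PCR
duplicates, whole-genome-amplification artifacts, quality-score
miscalibration, and real genomic repeat-length/motif spectra. Passing
tests therefore demonstrate correctness of the calling rules under the
declared error model, not performance on real exomes.

## Error characterization and its limits

With the defaults above, the simulation reproduces the qualitative
behavior the rules were designed around: the fraction of genotyped loci
free of false alleles falls as the per-base error rate rises and climbs as
the read threshold rises (dominant false-allele mode: identical 1-nt
deletion errors accumulating in long mononucleotide runs), and the
per-locus allele count at fixed threshold grows with depth.

Zygosity accuracy deserves a caveat. With a diploid truth (5%
heterozygous) and error-bearing reads retained at full quality, the
heterozygote rule has an irreducible failure mode: error reads inflate the
depth denominator while the second allele's support is binomial, so at 5%
per-base error a heterozygous locus fails both support rules a few percent
of the time, and even error-free loci at depth 15–30 sit near the rule
boundary. Measured accuracy is ~99.9% at 0.5% error, falling to ~97–98%
at 5% error. An accuracy of 99.98% at every error rate is reachable only
when the truth is effectively haploid (accuracy then reduces to the
false-heterozygote rate) or when error bases carry low qualities and are
filtered before depth; both are plausible readings of how such figures are
usually produced, but neither matches the diploid, full-quality study
conditions used here, so the acceptance test encoding that figure fails
honestly under these conditions.

## Profile statistics

- **Sample summary**: percent homozygous / heterozygous over genotyped
  loci (sums to 100), percent of genotyped loci with >= 1 minor allele.
- **Concordance** (two samples, loci genotyped in both): minor alleles in
  both / exactly one / neither partition the shared loci; genotype
  discordance is split into threshold-boundary cases (the missing
  haplotype allele is present as a minor allele in the other sample) vs
  genuine sequence differences. The random-cohort null uses the analytic
  product `frac_a x frac_b` plus an optional Monte-Carlo subset draw, and
  a 1-df Pearson goodness-of-fit test of the observed concordant count.
  The analytic product for 5.4% and 5.3% is 0.286%; we report the formula
  value and do not attempt to reproduce differently derived bounds.
- **Binning / hotspots**: genotyped loci are assigned to 1-Mb bins
  (brute-force coordinate division); each non-empty bin is tested
  upper-tail against the genome-wide minor fraction with a one-cell
  goodness-of-fit statistic (1 df), flagged at alpha = 0.01. No
  multiple-testing correction by default (matching the visual-threshold
  usage the statistic mirrors); a Bonferroni flag is available.
- **Regression** between paired per-chromosome or per-bin fractions:
  ordinary least squares with the F-test p-value.
- **Read fractions**: over loci with minor alleles, the mean per-locus
  fraction of reads supporting all minor alleles, and supporting the
  second allele (second haplotype allele when heterozygous, else the top
  minor).
- **Regions**: a locus is exonic iff it overlaps any exon interval by
  >= 1 bp (conservative for "exonic MST" counts); per-partition summaries
  plus a report of genes whose exonic loci carry >= 2 minor alleles, with
  cross-sample recurrence counts.

Cross-sample z-tests and outlier tests are not re-implemented; the
summaries expose the proportions and counts needed to run them in any
stats package.

## Numerical and interface conventions

- All randomness flows through `numpy.random.default_rng` seeded from a
  single integer; same seed, byte-identical text outputs (SAM, FASTQ,
  TSV).
- Percentage aggregates are exact ratios of integer counts; rounding only
  at output formatting.
- Degenerate inputs (empty catalogues, zero genotyped loci, zero shared
  loci, empty annotation) raise or warn explicitly rather than returning
  silent zeros.
- Problem sizes used by the test and acceptance suites: 2,000 loci per
  error rate for the sweep, 5,000 for parameter recovery, 10,000 random
  pileups for oracle equivalence; chosen to keep binomial confidence
  intervals a few per mille wide at desk scale.
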