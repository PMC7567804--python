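# Methods

This note documents the models and procedures implemented in
`tumorcomplexity`, the assumptions behind them, the parameters that matter,
and what the synthetic-data generator does and does not emulate.

## Coordinates, formats and segment handling

All in-memory coordinates are 1-based inclusive; BED/BEDPE files are
converted at the I/O boundary (positions are the 0-based interval starts
plus one).  Chromosome names are stored without a `chr` prefix.  Segment
tables carry `#ploidy=` / `#purity=` headers; rearrangements are
10-column BEDPE with an `sv_type` column (DEL, DUP, INV, TRA); SNVs are
VCF 4.2 read through cyvcf2 (indels and multi-allelic records are skipped
— they are outside this package's types); reference sequence is FASTA via
pyfaidx.

Arms are derived from a chromosome/centromere table as p = [1, cen_start]
and q = [cen_end, length].  Segments that cross the centromere are split
on load into a p part, an intra-centromeric part and a q part with
inherited copy numbers.  The intra-centromeric part belongs to neither arm
(it is excluded from arm-level sums but counted in genome-wide fractions).
Upstream callers differ in how they emit such segments, so the split is a
package convention, not an inherited one.

## WGD, arm events, aneuploidy, altered fraction

* **WGD**: major copy number (total − minor) ≥ 2 over strictly more than
  50% of the autosomal covered length.  Boundary values are negative
  (a fraction of exactly 0.5 is not WGD).
* **Arm calls**: a segment is gained / lost / neutral by comparing its
  integer total copy number with the *unrounded* sample ploidy; exact ties
  are neutral.  An arm is called when strictly more than 80% of its
  covered length is altered in one direction.  Uncovered arm territory
  enters neither numerator nor denominator; an arm with zero covered
  length is neutral with a warning.
* **Aneuploidy score**: count of non-neutral counted arms.  Counted arms
  are both arms of every autosome minus the short arms of the acrocentric
  chromosomes 13, 14, 15, 21, 22 — 39 arms on GRCh37.  X and Y are parsed
  and retained but excluded from every WGD/aneuploidy computation.
* **Altered genome fraction**: length share of the autosomal genome in
  amplification (total ≥ 6), single-copy loss (total 1), homozygous
  deletion (total 0) or copy-neutral LOH (total 2, minor 0).  The LOH
  state is defined in absolute copy numbers, not relative to ploidy; for
  genome-doubled tumors a 4+0 segment is therefore *not* counted as
  copy-neutral LOH.  This matches the absolute CN labels the statistic is
  usually reported with, and is the main open interpretation choice here.

## Feature catalogs

* **SBS96**: pyrimidine-centred trinucleotide classes in COSMIC order
  (substitution class major, flanks alphabetical).  Purine-reference
  variants are reverse-complemented; contexts containing N go to an
  excluded tally, never to a class.
* **SV32**: 2 (clustered / non-clustered) × [3 types × 5 size bins + 1
  translocation class] = 32.  Size bins are 1–10 kb, 10–100 kb,
  100 kb–1 Mb, 1–10 Mb, > 10 Mb, half-open [low, high); events below 1 kb
  share the smallest bin (the scheme has no sub-kb bin).  Breakpoint
  clustering is single-linkage over individual breakpoint ends along each
  chromosome with merge distance `d` (default 1 Mb); an event is clustered
  iff either end sits in a cluster of ≥ `min_cluster_size` ends (default
  10).  Both parameters are config keys: the clustering tool used upstream
  of the original analysis does not document its thresholds, so these
  defaults are package choices, recorded in run provenance.  Clustering is
  per sample.
* **CN40**: zygosity (het / LOH / homozygous deletion) × total-CN class
  (0–1 deleted, 2 neutral, 3–4 duplicated, > 4 amplified) × 5 size bins
  (0–0.01, 0.01–0.1, 0.1–1, 1–10, > 10 Mb, half-open, size =
  (end − start + 1)/10⁶).  Impossible combinations are excluded: het
  requires total ≥ 2, homozygous deletion is total 0 only, total 1 is
  LOH/deleted — leaving 15 + 20 + 5 = 40 categories.

Conservation holds by construction: each SNV/event/segment lands in
exactly one category, so column sums equal input counts.

## Signature inference

NMF minimizes the generalized Kullback–Leibler divergence with
multiplicative updates (1,000 iterations or relative objective change
< 10⁻⁸).  The update rule is monotone; the implementation asserts
non-increase of the objective every 10 iterations as a self-check.

Rank selection scans ranks 2–12 (configurable).  For each rank, random
restarts (default 100) are summarized by a sample × sample consensus
matrix of dominant-signature co-assignment; stability is measured by the
cophenetic correlation of average-linkage clustering of 1 − consensus and
by the mean silhouette width of the rank-k cut.  The same diagnostics are
computed on a *randomized* matrix in which each category row is
independently permuted across samples (destroying inter-category
structure while preserving row marginals), with its own restarts.  The
chosen rank is the **largest** rank with cophenetic ≥ 0.95, silhouette
≥ 0.8 and both strictly above the randomized baseline; if none qualifies,
the rank with the highest cophenetic coefficient is used.  The tie policy
is not stated by the diagnostics themselves, so the combination rule is
explicit and recorded in provenance.  Signatures are taken from the
best-objective restart at the chosen rank, columns normalized to sum 1.

Matching to a reference set is by argmax cosine similarity on identically
ordered category vectors; matches below 0.85 are flagged novel.

Exposure refitting solves a nonnegative least-squares problem on the
normalized catalog (hence scale invariant).  Samples with ≤ 50 mutations
are entirely unassigned.  Fitted proportions below 0.15 — and, when a
`max_signatures` cap is set, any beyond the top contributors — are not
assigned; their weight plus the fit residual is reported as
unassigned/other, and retained weights are reported as fitted, **not**
re-inflated to sum to one.

## Kataegis

Inter-mutation distances (IMDs) are computed within chromosomes on sorted
positions and segmented on the log10 scale by *exact* penalized
least-squares piecewise-constant fitting (O(n²) dynamic programming,
per-segment penalty γ, default 25).  A kataegis locus is a run of ≥ 6
consecutive mutations inside one fitted segment whose raw IMDs average
≤ 1,000 bp.  The run may be a proper sub-run of its segment: the optimal
segmentation often absorbs a single long flanking IMD into a hypermutated
segment, because isolating one point costs a full penalty γ while
absorbing it costs roughly n/(n+1) · Δ² < γ.  Requiring the entire
segment to pass the mean-IMD filter would therefore systematically miss
genuine clusters; searching qualifying runs within segments does not
(at realistic background densities a ≥ 6-mutation run with mean spacing
≤ 1 kb arising by chance is vanishingly rare — none observed in 50
background-only simulated genomes).

## Complex chromosomes

Candidate chromosomes fire on any of: (A) a one-sample exact
Kolmogorov–Smirnov test of breakpoint positions against a uniform
distribution over the chromosome at p < 10⁻⁵ (a chi-square alternative is
available by config); (B) a breakpoints-per-Mb rate above Q75 + 1.5·IQR of
the sample's own per-chromosome rates (zero-breakpoint chromosomes
included at rate 0) with ≥ 35 breakpoints; (C) ≥ 10 translocations.

Candidates are classified from explicit, configurable evidence — the
original analysis resolved this step by manual review, which is codified
here so the rule is executable and the raw evidence columns are emitted
for a human to overrule:

* `telomeric_loss`: a terminal segment (first or last on the chromosome)
  with total CN strictly below sample ploidy.  With integer copy numbers
  and an estimated (non-integer) ploidy this strict rule is fragile;
  profiles whose header ploidy is the tumor's base level (as the simulator
  emits) behave exactly.
* `foldback_count`: inversion-type events whose ends lie within 30 kb.
* `cn_switches` / `cn_states`: transitions between distinct total-CN
  values, and the smallest number of CN values covering ≥ 80% of the
  breakpoint region's length.
* `het_retention_fraction`: length fraction of above-minimum-CN-state
  segments in the region that retain a minor allele.

Chromothripsis evidence = cn_switches ≥ 10 ∧ cn_states ≤ 3 ∧
het_retention ≥ 0.5.  BFB evidence = telomeric loss ∧ (≥ 3 fold-backs ∨
inversion+translocation fraction ≥ 0.4).  Both → BFB/chromothripsis; one →
that class; neither → localized complex.  The thresholds for "loss of
telomeres" and "high number of inversions" have no published values; the
defaults above are package choices, stated here and in provenance.

## Locus annotations

TMB = (SNV + DNV + TNV + indel count) / genome size in Mb; the default
denominator is the sum of reference chromosome lengths (no callable-genome
correction).  A TMB-high label at ≥ 20 mutations/Mb is provided as a
constant.  Gene status: amplified if any overlapping segment has total
≥ 6, homozygously deleted if any has total 0; a gene spanning both reports
both.  TERT-upstream annotation is strand-aware: the window is the 20 kb
5′ of the gene start on its coding strand (for the minus-strand TERT,
coordinates above the gene end); partner super-enhancer distance is the
unsigned gap (0 if overlapping), proximal at ≤ 100 kb.  Telomere length is
log2 of coverage-normalized telomeric read counts, tumor over matched
normal.  Breakpoint recurrence tiles the genome half-open from position 1
into 1-Mb bins and counts distinct samples per bin.

## Synthetic cohorts

The generator emits, per sample, an integer-CN segment profile,
rearrangements, SNVs and a shared random reference sequence, all
deterministic given `(seed, sample_index)` (one independent stream per
sample, so cohorts are reproducible under any generation order).

Structure planted per sample: WGD by coin flip (base state 2+1 or 4+2;
the emitted header ploidy is the base total, which is what arm calling
compares against); whole-arm gains/losses (Poisson count, default mean 4);
focal amplifications to CN 8 and homozygous deletions (Poisson, default 2
each); one chromothripsis chromosome (44 clustered breakpoints in a
window, copy number alternating between two states one copy apart with
the minor allele retained on the higher state) and one BFB chromosome
(terminal q-arm loss plus 8 fold-back inversions); background
rearrangements at 0.18 breakpoint ends/Mb drawn from a configurable
32-category mixture (non-clustered categories); kataegis loci of ≥ 6
TpC→T/G mutations with exponential spacing (mean 300 bp); and background
SNVs drawn from a configurable SBS96 signature mixture.  SNV positions are
chosen by rejection so that each variant's reference trinucleotide matches
its sampled category (on either strand), so catalogs built from the
emitted FASTA reproduce the planted mixture exactly.  The default SNV
count (650 on the ~310-Mb mini genome) corresponds to ~2.1 mutations/Mb,
a typical median burden for this tumor type.

Defaults are the study conditions; the packaged mini genome (GRCh37
scaled 1:10) keeps a 10-sample cohort under a minute, and the full GRCh37
table is selectable.  A separate catalog-level simulator draws count
matrices directly from planted signatures and exposures (Poisson or
multinomial noise) for signature-inference studies; the
`cn_category_targets` configuration field feeds this catalog-level route —
planted CN40 target counts are not realized as genomic segments.

Not emulated: subclonal copy number, purity/contamination effects on
observed CN, read-level data, sequence composition bias (the reference is
i.i.d. uniform over A/C/G/T), replication-timing or chromatin covariates
of mutation density, and derivative-chromosome adjacency.  Passing
recovery tests on these cohorts therefore demonstrates correctness of the
decision rules away from their boundaries, not robustness to caller noise
in real data.

## Numerical choices and scales

Strict inequalities at the 50% and 80% thresholds; half-open size bins;
NMF epsilon guard 10⁻¹²; exposure accounting checked to 10⁻⁹; PCF is the
exact DP optimum (verified against exhaustive enumeration in tests).  Test
and acceptance runs use scaled problem sizes chosen to exercise each rule
well away from its decision boundary: ~7-Mb builds for per-basepair oracle
comparisons (100 instances), 50-sample catalogs for rank-selection
recovery, 200 samples for exposure recovery, 10,000 null chromosomes for
calibration of the uniformity flag, and 50-sample micro-genome cohorts
(100 planted complex chromosomes) for classification recovery.
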