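# Methods

## Scope and data model

The package analyses a two-group (treatment vs control) design measured at
one or two developmental ages with two assays: RRBS-style per-CpG
methylation counts (methylated, unmethylated per sample) and gene-level
RNA-seq counts. Internally all coordinates are 0-based half-open;
bismark-coverage and GTF files are converted from their 1-based
conventions at the I/O boundary. The repo-wide sign convention is
Δme = treatment − control; "hypo" always means loss of methylation in the
treatment group.

## Differential methylation

Per site, the effect estimate is the difference of group means of
per-sample methylation fractions m/(m+u), taken over samples with any
coverage ("mean of fractions"; a pooled-count variant is available via
`delta_method="pooled"`). The significance test is a two-sided Fisher
exact test on the 2×2 table of counts pooled within each group. Pooling
discards replicate-level variance: the test is exact under a binomial
within-group model and anti-conservative when biological replicates are
overdispersed (beta-binomial ρ > 0). This is a deliberate trade-off for a
deterministic, exact, desk-scale test; a beta-binomial likelihood-ratio
test is the documented extension point for overdispersed data.

DMC gates (all conjunctive, all configurable): raw p < 0.001 (no multiple-
testing correction at the site level — the threshold is an operating
point, not an error-rate claim), |Δme| ≥ 0.10, and ≥ 10 pooled reads per
group. Sites where a group has zero counts are untestable, not errors.

DMR aggregation: maximal runs of same-chromosome, same-sign DMCs with
inter-CpG gap ≤ 250 bp, with no minimum run length by default (min_dmcs=1)
so isolated strong DMCs are retained. The interval spans the first to last
member CpG; a single-CpG DMR gets the 2 bp dinucleotide interval
[pos, pos+2). DMR Δme is the unweighted mean of member Δme; direction is
hypo iff Δme < 0. Hypo/hyper imbalance of a DMR set is tested with a
two-sided exact binomial test of the hypo count against 0.5.

## Regulatory annotation

cCRE categories follow the ENCODE registry scheme. The classifier anchors
each element at its midpoint (lower-median coordinate for even lengths)
and measures the distance to the nearest annotated TSS: promoter-like
signal within 200 bp → PLS, farther → other-H3K4me3; enhancer-like within
2 kb → pELS, beyond → dELS; CTCF signal only → CTCF-only. Boundary
distances (exactly 200 or 2000 bp) resolve to the proximal class.
Promoter-like signal takes precedence when multiple flags are set.
Overlap tables count a DMR once per category it touches but once in the
overlapped total, so the total never exceeds the number of DMRs.

## TSS-distance enrichment

Region–gene association assigns each region (midpoint anchor) to the
single nearest gene TSS within 1 Mb. Orientation is upstream/downstream in
the gene's reading direction; a midpoint exactly at the TSS counts as
distance 0, downstream. Equidistant ties prefer the candidate for which
the region is upstream, then the lower TSS coordinate — deterministic and
documented rather than meaningful. Distance bins are half-open on the
right: [0, 5 kb), [5, 50 kb), [50, 500 kb), [500 kb, 1 Mb]; regions with
no TSS within 1 Mb are reported in a "none" row so the bins partition the
region set.

The background is a seeded, without-replacement uniform sample (default
2%) of the measured-CpG universe of the dataset under analysis — not of
the whole genome — mirroring how a background of measured sites behaves
under the same assay bias. Per-bin foreground-vs-background occupancy is
tested with a Pearson χ² (1 df) without continuity correction; the
uncorrected form reproduces published worked examples of this test family
better than the Yates-corrected one. A zero margin yields an undefined-
statistic flag, not an exception.

## Differential expression

Size factors are DESeq-style median-of-ratios over genes with all-positive
counts, rescaled to geometric mean 1; with no usable reference genes the
code falls back to total-count scaling with a warning. Per gene, the NB
dispersion α is estimated by method of moments from the within-group
pooled mean and variance of normalized counts, floored at 1e-8. The Wald
statistic is the natural-log fold change of pseudocounted group means
(pseudocount 0.5) over its delta-method standard error
sqrt((1/μ₁+α)/n₁ + (1/μ₀+α)/n₀). The statistic is referred to a Student-t
distribution with n₁+n₂−2 degrees of freedom rather than the normal:
with plug-in moment dispersions at n = 5 per group the normal reference is
visibly anti-conservative (null KS ≈ 0.056 on 2,000 genes in our
calibration runs) while the t reference is near-uniform (KS ≈ 0.024).
All-zero genes get (log2fc = 0, p = 1). Calling applies Benjamini–Hochberg
across all tested genes and requires FDR < 0.05 and |log₂FC| > 1
(both configurable); no independent expression filter is applied by
default.

## Integration

DMR–DEG links pair every DMR whose midpoint lies within 25 kb of a called
DEG's TSS (gene-body-edge anchoring available via `anchor="body"`); a DMR
may link to several DEGs and counts are reported both as links and as
unique DMRs. A link is canonical iff sign(Δme)·sign(log₂FC) = −1, the
textbook negative methylation–expression association; zero effects are
non-canonical. Shared DMRs between two comparisons are ≥ 1 bp interval
overlaps, reported as Venn counts from both sides (the overlap relation is
symmetric; the per-side counts need not be equal because one interval can
absorb several).

## Synthetic-study generator

The generator emulates the *structure* of a genome-wide RRBS + RNA-seq
study at desk scale: one 10 Mb chromosome, 20,000 CpGs and 200 genes stand
in for ~2 M measured CpGs per sample and a full transcriptome. Defaults
encode the study conditions the pipeline is meant to operate under:
5 samples per group, 71% of planted DMRs hypomethylated, mean planted
|Δme| 0.18 (per-region magnitudes ~N(0.18, 0.04), symmetrically clipped),
84% of planted DMRs > 5 kb from any TSS, 30 planted DEGs at |log₂FC| = 2,
NB coverage with mean 30 and dispersion 0.1 truncated at ≥ 1 read, and
RNA-seq NB dispersion 0.05 with log-normal gene means (median ≈ 100) and
log-normal size factors (σ = 0.15, geometric mean 1).

Design choices worth knowing:

- **CpGs come in MspI-fragment-like clusters** (3–12 CpGs within
  100–600 bp, ~30% of fragments within 2 kb of a TSS), matching RRBS's
  fragment-based, promoter-biased coverage and guaranteeing multi-CpG
  windows for planting. Fragments are kept mutually disjoint.
- **Baseline methylation is bimodal**: TSS-proximal CpGs (≤ 2 kb) draw
  π ~ Beta(1,10), distal CpGs π ~ Beta(10,1), so regulatory regions are
  hypomethylated as in real somatic methylomes and the TSS-distance
  analyses are non-trivial.
- **Planted DMRs occupy whole fragments**, with baselines drawn
  direction-compatibly (hypo: π ∈ [|Δme|+0.05, 0.97]; hyper:
  π ∈ [0.03, 0.95−|Δme|]) so the planted shift is realized without
  clipping; clipping of user-forced extremes is counted and warned, never
  silent.
- **Methylated counts are binomial given coverage by default**
  (beta-binomial ρ = 0). This matches the within-group model of the
  pooled-Fisher DMC test; ρ > 0 is an explicit robustness knob, and under
  it the DMC caller is expected to be anti-conservative (see above).
  Null-calibration checks therefore run at ρ = 0, the test's own null.
- **One RNG stream per artifact** (annotation, cCREs, RRBS, RNA-seq),
  derived from the master seed by fixed labels, so adding an output never
  perturbs existing ones; a fixed seed fixes every output file
  byte-for-byte.
- `simulate_two_age_study` runs two comparisons (e.g. birth and weaning)
  over one shared annotation, cCRE catalog and CpG layout, which is what
  the full pipeline's shared-DMR Venn consumes.

What the generator does **not** emulate: reads and bisulfite chemistry,
alignment artifacts, litter/dam hierarchical structure, sex chromosomes,
cell-type composition shifts between ages, or genome-scale CpG counts.
Passing recovery tests therefore demonstrates the pipeline's correctness
and calibration under its own model assumptions at reduced scale — not
performance on real libraries, where overdispersion, coverage bias and
confounding are harsher.

## Numerical and reporting conventions

Printed percentages are round-half-up to one decimal (Decimal arithmetic,
so 0.15 → 0.2, never banker's rounding), with denominators carried
alongside; a zero denominator renders as NA. Fisher p-values come from
scipy's exact routine and are verified in the test suite against a direct
hypergeometric tail enumeration on all 2×2 tables with total ≤ 40. The χ²
statistic is computed from the Pearson formula and checked against both
the squared two-proportion z statistic (algebraic identity) and scipy's
uncorrected contingency test. The pipeline report is a single JSON
validated against an in-package structural schema, plus TSV tables;
re-running with the same seed reproduces the report byte-for-byte.

## Problem sizes used in validation

The test-suite and acceptance runs use the generator at its default scale
(20,000 CpGs, 200 genes, 5v5) for methylation recovery and null
calibration, a 2,000-gene variant for expression calibration and recovery,
and ~10³-element random fixtures for the brute-force interval and
nearest-TSS oracles. These sizes were chosen as the smallest at which the
binomial/KS tolerances of the calibration checks are informative.

## Known limitations

- The pooled Fisher DMC test ignores replicate variance (see above); its
  raw-p threshold is an operating point, not a genome-wide error rate.
- Method-of-moments dispersion at n = 5 per group is noisy; the t
  reference compensates on average but individual genes' p-values remain
  approximate.
- The DMC→DMR aggregation rule (gap 250 bp, same direction, min 1 DMC) is
  one reasonable convention among several; published DMR counts from other
  pipelines are not comparable without knowing their rule.
- cCRE classification uses geometric rules on provided signal flags; the
  package does not derive regulatory elements from signal tracks.
- GO/pathway enrichment and chromatin-interaction-based (Hi-C) region-gene
  assignment are out of scope; only distance-based association is
  implemented.
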