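# Methods

## Scope and model

`hypoblocks` analyzes the *global DNA hypomethylation* phenotype of tumor
methylomes: coordinated, multi-hundred-kb regions of methylation loss
("hypomethylated blocks") in a case group relative to a reference
(normal-epithelium) group, together with the spatial, copy-number and
expression correlates of those blocks. All genomic coordinates are 0-based
half-open (BED convention); interval sets are normalized (sorted, with
overlapping and touching intervals merged) before any base-pair
arithmetic, so intersection/union/complement are exact set algebra rather
than approximations.

## Block calling

Per tile (default 5 kb, last tile truncated at the chromosome end) and per
sample, the tile summary is the mean methylation fraction of the CpGs that
sample observed in the tile; a CpG observed in at least one sample counts
toward the tile's CpG total. Tiles with at least `min_tile_cpgs` (default
1) observed CpGs are testable. The per-tile p-value is a Welch two-sample
t on the per-sample tile means; Benjamini–Hochberg adjustment is computed
over testable tiles only, since tiles with no observed CpGs carry no
evidence. Tiles passing q ≤ `fdr_threshold` (0.05) and
Δ ≤ −`min_delta` (−0.35) are merged per chromosome whenever the gap from
one tile's end to the next tile's start is ≤ `merge_gap` (250 kb); the
resulting block spans first-start to last-end, gaps included, which is what
produces multi-hundred-kb blocks from scattered significant tiles. Blocks
whose member tiles hold fewer than `min_block_cpgs` (5) CpGs are dropped;
block Δ is the CpG-count-weighted mean of member-tile deltas.

Conventions worth flagging: the original tiled analyses of this phenotype
were run through a methylation suite whose internal hierarchical test is
not reproduced here — the Welch t on tile means is a deliberate, simpler
choice that is easy to calibrate and to check against oracles. Cohorts
with two samples per group (common for methylome sequencing) should use
`delta_only=True`, which keeps tiles by methylation decrease alone; with
n = 2 per group the t-test is technically defined but nearly powerless,
so requesting p-values with fewer than two samples per group is an error
rather than a silent degradation. Tiles whose groups are constant get
p = 1 (no evidence) rather than NaN.

DMRs are maximal runs of consecutive CpGs with inter-CpG gap ≤ 1 kb and a
consistent sign of the group difference (zero differences break runs),
emitted when the run has ≥ 3 CpGs of which ≥ 1 has |Δ| > 0.20 at
p ≤ 0.05. DMCs are counted per genomic context (genes, CpG islands,
shores, shelves, open seas — any named track), with BH adjustment within
each context; a CpG may belong to several contexts.

## Spatial enrichment

Feature-in-block assignment uses the feature midpoint,
floor((start+end)/2): each feature gets exactly one unambiguous
assignment, so counts partition. Any-overlap counting is available but is
not the default because it inflates counts for long features straddling
block edges. Fold enrichment divides the unrounded in-block fraction by
the supplied genome fraction; display rounds to two decimals. When
reproducing published tables from printed integer percentages, small
discrepancies (one unit in the second decimal) can arise between
rounded-percent and unrounded arithmetic; this implementation standardizes
on unrounded inputs.

The projection test is an exact two-sided binomial test of k in-block
midpoints among n at success probability p₀ = block coverage fraction.
The Jaccard permutation test relocates each query interval uniformly
within its own chromosome, preserving lengths and allowing overlap among
relocated intervals — a simple exchangeable null in the spirit of
relocation nulls used by interval-correlation packages. The add-one
estimate p = (1 + #{J\* ≥ J_obs})/(N + 1) is reported on the tail of the
observed direction by default; for calibration studies the fixed
`alternative="enrichment"` tail should be used, because the
direction-adaptive p is concentrated below 0.5 under the null by
construction. Direction labels ("Direct"/"Indirect") in the enrichment
table come from the fold-enrichment point estimate, with fold exactly 1
labeled "Neutral".

## CNA

The CNA index pools gains and losses ("altered") and is the fraction of
the genome covered by their union, so overlapping gain and loss never
double-count. Same-sample overlapping input segments with conflicting
calls are resolved deterministically — the latest-read call wins and
earlier segments are trimmed around it, with a warning — because upstream
segmenters emit disjoint segments and conflicts indicate user error.
Coverage-normalized density is CNA bp per compartment bp, computed inside
blocks and on the block complement; the headline densities are the mean of
per-sample densities, and significance is a Wilcoxon signed-rank on the
per-sample (inside, outside) pairs. A paired-t ("anova") option gives the
parametric equivalent of a two-way layout with sample as the blocking
factor; the exact factor structure of published two-way analyses of this
contrast is generally unstated, so it is configuration here, not a claim.
Blocks covering 0% or 100% of the genome make one density undefined and
raise.

## Expression statistics

The regularized t follows the Baldi–Long form: the pooled per-gene
variance s²_gene (n − 2 df) is shrunk toward a background s²_bg, the mean
pooled variance of the `window` (default 101) genes nearest in average
intensity (intensity-ranked sliding window, clipped at the ends), with
prior weight `prior_df` (default 10) pseudo-observations:
s²_reg = (ν₀ s²_bg + (n−2) s²_gene)/(ν₀ + n − 2), t on s²_reg with
ν₀ + n − 2 df. `prior_df = 0` reduces exactly to the pooled two-sample t,
which is the oracle identity the tests enforce to 1e-10. The exact
windowing details of the original Bayesian-regularization software are not
published; this is a reimplementation of the documented formula with the
two knobs exposed.

Inputs are assumed log2; matrices with values above 30 are rejected as
linear-scale rather than silently transformed. Proliferation-normalized
expression on log2 data is a per-sample difference gene − marker, compared
between groups by Mann–Whitney. The MAD contrast uses the raw
median-absolute-deviation (no 1.4826 consistency factor) across case
samples; in-block and out-block gene MAD distributions are compared by
Mann–Whitney by default. A paired mode matching genes by mean-expression
rank (Wilcoxon signed-rank on the pairs) is provided because published
versions of this contrast cite a paired test without defining the pairing;
the pairing here is configuration, not a claim about the original. The
CIN25 score is the mean case-vs-reference log2 fold change over the
signature genes present, with per-gene p from the regularized t over the
full matrix; the gene list is an input file, never hard-coded. The
repeat-element summary joins per-family expression and methylation changes
and reports the count of (Δexpr > 0, Δmeth < 0) families plus a Spearman
trend.

## Synthetic data

The generators emulate the structure such a study assumes, with every
parameter planted and recoverable:

- **Genome / CpGs**: configurable chromosomes (default 2 × 25 Mb);
  CpG positions at exponential spacing (mean 500 bp, ~15% the density of a
  real CpG map — enough for ≥ 50 CpGs per 5-kb tile in expectation).
- **Methylome**: per-CpG baseline β ~ N(0.8, 0.05) shared across samples;
  per-sample noise N(0, 0.05), clipped to [0,1] (a bounded truncated-normal
  choice; a beta-distributed option was considered and rejected to keep
  planted deltas exact). Case samples are decreased by `block_delta`
  (default 0.40, within the 0.35–0.50 range characteristic of the
  phenotype) inside planted blocks of 300–900 kb covering
  `block_fraction` (default 0.15) of the genome, kept ≥ 600 kb apart so
  the caller should report them as distinct. Default four samples per
  group gives the t-test reasonable power while remaining cohort-realistic;
  two-per-group designs are the delta-only mode's territory.
- **Tracks**: the enrichment factor is the target midpoint fold
  enrichment — a feature midpoint falls in blocks with probability f·B —
  so the enrichment statistics recover f directly (requires f·B ≤ 1).
- **CNA**: segments (default 200 kb) are placed wholly inside or wholly
  outside blocks with odds c·B : (1−B), non-overlapping within a sample,
  so the expected in/out density ratio equals the concentration c exactly.
- **Expression**: log2 values N(7, 1) baseline; proliferation markers
  shifted +1.5 in the case group while maintenance-methylation genes stay
  flat (so marker-normalized ratios drop); 25 signature genes shifted by
  N(0.8, 0.1); in-block genes get case-sample noise scaled by the
  variability multiplier (default 2×).

What passing tests on this synthetic data do *not* show: the generators
have no read-coverage structure, no beta-value heteroscedasticity, no
correlated CpGs beyond the block indicator, no purity/stromal mixture, no
chromosome-arm-scale CNA events, and uniform feature placement outside
blocks. Recovery results demonstrate correctness of the computations, not
expected performance on tumor cohorts.

## Problem sizes, tolerances, determinism

Recovery studies use 20–50-Mb genomes with 20 seeds (block
precision/recall ≥ 0.9), 100-run null simulations for block-rate control,
500 simulations for projection-test calibration and 200 runs for Jaccard
p uniformity (KS at α = 0.01) — sizes chosen so each study finishes in
tens of seconds while leaving comfortable statistical margins. All
randomness flows through numpy Generators seeded explicitly; the pipeline
expands one top-level seed into per-stage seeds via `SeedSequence.spawn`,
and a rerun with the same config and seed is byte-identical (reports carry
no timestamps or absolute paths). Permutation p-values use the add-one
estimator, so the attainable floor is 1/(N+1).

## Known limitations

- The tile test treats per-sample tile means as exchangeable, ignoring
  differing CpG counts per tile (no coverage weighting).
- Blocks are unstranded and ungapped once merged; nested or overlapping
  block structure is not represented.
- The enrichment table reports per-track p-values without multiplicity
  adjustment across tracks, matching how such tables are usually printed.
- `call_dmc` needs ≥ 2 samples per group for p-values; there is no
  delta-only DMC mode.
- The Jaccard relocation null preserves interval lengths but not
  inter-interval spacing; strongly clustered query tracks are therefore
  tested against a somewhat more dispersed null.
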