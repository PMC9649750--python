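# Methods

This note documents the models, conventions and design choices behind
`cervstrat`, in the order the pipeline runs.

## Quality control and normalization

A cell is removed when **any** of: total UMI < `min_umi` (200), detected
genes < `min_genes` (200), mitochondrial UMI fraction > `max_mito_frac`
(0.10). Removal uses strict inequalities, so a cell exactly at a
threshold is kept. The QC report tallies each criterion non-exclusively;
a cell failing several is still removed once. Filtering is idempotent.

Normalization is per-cell total-count scaling to `scale_factor`
(default 10,000) followed by the natural log1p:
`value(g,c) = ln(1 + count(g,c)·sf/total(c))`. Zeros map to zeros and
sparsity is preserved; consequently `Σ_g expm1(value) = sf` exactly for
every cell, which the tests assert. Natural log was chosen for the
log-transform (the upstream convention this emulates is "LogNormalize");
the CNA caller accounts for the base explicitly (below).

Highly variable genes are ranked by **binned dispersion**: the
variance/mean ratio of the normalized values, z-scored within 20
equal-frequency mean bins, ties broken by gene order. This is simpler
and fully deterministic compared to loess-based variance stabilization
and suffices to recover planted high-dispersion genes. Zero-variance
genes are never selected.

Where downstream steps need a cell grouping, `cluster_cells` runs
k-means (fixed seed, 10 restarts) on the top 20 principal components of
z-scaled HVG expression. Graph-based clustering was deliberately not
reproduced: cluster identity here is only a grouping input for marker
and CNA comparisons, not a deliverable.

## Differential markers

Two-group comparisons use the two-sided Wilcoxon rank-sum test with the
tie-corrected normal approximation and no continuity correction (the
default of the single-cell toolkits this emulates). Genes enter testing
only if expressed (nonzero) in at least `min_pct` (0.20) of cells in one
group; Benjamini–Hochberg adjustment runs over tested genes only, i.e.
filtering precedes testing. The fold change is computed on de-logged
normalized means with a +1 pseudocount on both sides:
`log2fc = log2((mean(expm1 x)₁+1)/(mean(expm1 x)₂+1))` — stable for
sparse genes, at the cost of attenuating fold changes of low-expressed
genes toward zero. Default marker filters are |log2fc| > 0.585
(= log₂ 1.5, i.e. a 1.5-fold change) at adjusted p < 0.01. Genes whose
values are identical across cells get p = 1 (no evidence) rather than a
NaN from the degenerate normal approximation. Groups with fewer than 3
cells trigger a warning, not an error.

## Copy-number inference

The caller follows the established expression-based CNA recipe:

1. **Ordering.** Genes are sorted by (karyotype chromosome order, start);
   genes without positions or outside the analysis karyotype are dropped
   and counted. Sex chromosomes are excluded by default. At least one
   chromosome must hold a full smoothing window.
2. **Relative expression.** Per gene, the mean over a designated diploid
   reference population is subtracted from the normalized values. The
   default reference is all NAT (normal adjacent tissue) cells excluding
   epithelium — stromal/immune populations treated as diploid anchors.
   Residuals are clipped to ±3 **pooled** reference standard deviations;
   a single pooled SD is used rather than per-gene SDs, which are noisy
   and degenerate for near-constant genes.
3. **Smoothing.** A centered 100-gene moving average within each
   chromosome. Near chromosome edges the window is truncated (it always
   pools at least ⌊window/2⌋+1 genes). A symmetric shrink was evaluated
   and rejected: it degenerates to single-gene windows at chromosome
   ends, inflating edge-bin variance far beyond the neutral-call margin.
   Chromosomes shorter than the window are averaged whole, with a
   warning. Each cell's track is then median-centered, which also
   absorbs the small global depression that per-cell normalization
   induces in cells carrying net gains.
4. **Integer calls.** Non-overlapping 30-gene bins within chromosomes; a
   trailing remainder of ≥ 10 genes forms its own bin, smaller remainders
   merge into the previous bin. The bin mean m (natural-log units) is
   converted to log2 and mapped to copy number `CN = round(2·2^m2)`,
   clamped to [0, 6]; rounding in copy-number space keeps neutral at 2
   (rounding raw near-zero log ratios would collapse to 0), and exact
   half-integers round away from neutral. The explicit base conversion
   matters: treating natural-log means as log2 ratios attenuates every
   dosage signal by ln 2 and systematically under-calls gains.
5. **Burden.** Per cell, mean |CN − 2| over bins. The burden statistic of
   the published figure this emulates is not further specified; mean
   absolute deviation is the declared convention here. Cluster-level
   comparisons use pairwise rank-sum tests, BH-adjusted, excluding
   clusters with < 3 cells.

An optional denoise step (zeroing track values within k pooled reference
SDs, default off) mirrors the reference tool's stabilisation; at the
simulator's default depth it does not change integer calls.

Known attenuation: because log1p compresses, the observed log ratio of a
true 1.5× dosage is ≈ 0.48 log2 rather than 0.585, and the compression
grows as normalized per-gene magnitudes shrink (i.e. with more genes per
scale factor). Per-(cell, bin) integer calls are therefore reliable at
the package's desk scale (~1,000–2,000 genes) but would be conservative
on a full 20,000-gene transcriptome, where the published practice is to
interpret cluster-averaged tracks rather than per-cell integers.

## Subtype stratification

The tumor-epithelial signature keeps genes with |log2fc| > 1.5 and
(adjusted) p < 0.05 from the tumor-vs-NAT epithelial comparison. Both
directions are retained — the signature describes the tumor–normal
contrast, not only up-regulation. Two documented ambiguities are exposed
as flags: "log FC > 1.5" is read as log2FC > 1.5 (≈ 2.8-fold), and
"P < 0.05" as adjusted p (`use_adj_p=False` switches to raw p).

Bulk samples restricted to the signature are z-scored per gene
(zero-variance genes dropped; ≥ 20 signature genes required), then
clustered by **consensus k-means**: 50 k-means restarts, co-assignment
matrix averaged, final k = 4 groups from an average-linkage hierarchical
cut of the consensus distances — deterministic given the seed. The
clustering algorithm behind the original stratification is unnamed;
consensus k-means is this package's choice.

Labels are assigned one-to-one by maximizing the total mean-z score of
each subtype's ten-gene marker panel over all 4! permutations, ties
broken lexicographically with a warning. The default panels are kept
verbatim from the published lists, including the printed symbols
"FLOD2" and "CKD1" (likely typos for FLOT2/CDK1) — the synthetic bulk
generator uses the same symbols, so no external gene universe is
implied; the immunoactive panel lists one gene twice and is
de-duplicated to nine genes at load. Set-level enrichment is reported as
one-sided hypergeometric overlap tests with BH correction — a labeling
device, not a GSEA reproduction.

## Survival

Kaplan–Meier estimation is the textbook product-limit estimator over
distinct event times; all-censored groups yield a flat curve at 1 with a
warning. The k-group log-rank test accumulates observed and expected
events and the hypergeometric covariance at each distinct event time and
forms the quadratic `x′V⁻¹x` on k−1 groups (pseudo-inverse for safety),
χ² with k−1 df. Single-gene contrasts split the cohort at the median
(configurable quantile); ties go to the low group, so an odd cohort puts
the extra sample low. No Cox modeling — the emulated analyses report
only KM/log-rank contrasts.

## Synthetic data

**Single cell.** Counts are negative-binomial (gamma–Poisson), mean
`base(g) · marker(g,type) · CN(g,subclone)/2 · libsize(c)`, with a
single global dispersion of 0.15 (mid-range of droplet UMI estimates)
and log-normal library size (σ = 0.35). Per-gene base means are
Gamma(2, 1.5), giving ≈ 6,000 UMIs per good cell at the 2,000-gene
default — a mid-depth droplet run. Marker genes (4-fold by default) are
drawn from genes expressed above the median base level — a fold change
on a near-silent gene is not a usable marker — and are scattered across
the genome so cell-type expression differences smooth away in the CNA
track instead of mimicking focal events, as in real genomes. CNA events
act multiplicatively on the mean (dosage model) — exactly the assumption
under which expression-based inference is valid. Low-quality cells (5%)
are created by down-scaling totals below the UMI threshold or inflating
the mitochondrial fraction, so the standard QC thresholds are the exact
discriminator. Genes are laid out contiguously on 10 chromosomes by
default so each chromosome holds the 100-gene smoothing window at desk
scale; mitochondrial genes live on an extra contig outside the analysis
karyotype.

**Bulk.** Log2-scale expression with per-gene Normal baselines; each
sample's latent subtype (balanced, shuffled) elevates its ten-gene
label panel plus private signature genes by `effect_log2fc` (default 2)
over Normal(0, 0.5) noise. Survival is exponential with hazard
`baseline (0.02/month) × HR(subtype)`, HRs (3, 1.5, 1, 0.5) in the order
S-H, S-P, S-D, S-I — hypoxia worst, immunoactive best; censoring occurs
with probability `censoring_rate` (0.2) uniformly on (0, t_event).

**What the simulators do not model:** doublets, ambient RNA, batch
effects, per-gene dispersion variation, gene–gene correlation beyond
cell type/subclone structure, subclonal mosaicism within a cell type,
non-proportional hazards. Passing tests therefore demonstrate the
correctness and calibration of the implementation under the stated
generative assumptions, not robustness to every artifact of real data.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to exercise
every code path with comfortable statistical margins: single-cell
studies of 1,500–1,600 cells × 1,200–2,000 genes; the CNA study uses
500 tumor and ≈ 480 diploid reference cells with one whole-chromosome
(120-gene) CN = 3 event; bulk cohorts of 400–800 samples; survival
ordering is evaluated over 100 simulation replicates.
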