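# cervstrat

Single-cell-informed molecular stratification of cervical cancer.

Cervical carcinomas are cellularly heterogeneous: bulk expression mixes
malignant epithelium with stroma and immune infiltrate, so bulk-derived
subtypes often track microenvironment composition rather than tumor-cell
biology. `cervstrat` implements the analysis chain that addresses this by
anchoring the stratification in single-cell data:

1. **QC & normalization** — droplet UMI counts are filtered (total UMI
   < 200, detected genes < 200, or mitochondrial fraction > 10% removes a
   cell; boundary values are kept), normalized per cell to a 10,000-count
   scale factor and ln(1+x)-transformed; the top 2,000 highly variable
   genes are ranked by binned dispersion.
2. **Differential markers** — two-group Wilcoxon rank-sum tests with a
   fraction-expressed filter (tested only if expressed in ≥ 20% of one
   group), fold changes on de-logged means, and Benjamini–Hochberg
   adjustment; the default marker filters are |log₂FC| > 0.585 (= log₂ 1.5)
   at adjusted p < 0.01.
3. **Copy-number inference** — per-cell expression relative to a diploid
   reference population, clipped at ±3 SD, smoothed along the genome with
   a 100-gene window within each chromosome, median-centered, averaged in
   non-overlapping 30-gene bins and rounded to integer copy number
   (CN = round(2·2^m), neutral = 2); per-cell burden = mean |CN − 2|.
4. **Subtype stratification** — tumor-vs-normal epithelial markers
   (|log₂FC| > 1.5, p < 0.05) define a signature; a bulk cohort restricted
   to the signature is z-scored, consensus-k-means clustered into k = 4
   groups, and the groups are labeled **S-H** (hypoxia), **S-P**
   (proliferation), **S-D** (differentiation) and **S-I** (immunoactive)
   by mean-z enrichment of each subtype's ten-gene marker panel.
5. **Survival** — Kaplan–Meier product-limit curves
   Ŝ(t) = Π_{tᵢ≤t}(1 − dᵢ/nᵢ) and the k-group log-rank test
   (χ² = x′V⁻¹x on k−1 groups, df = k−1), plus single-gene median-split
   contrasts.

Because the original cohorts are not redistributable, the package ships a
fully parameterized synthetic-data module (`cervstrat.synthetic_data`)
that emulates both data layers with complete ground truth: multi-type
negative-binomial single-cell counts with planted markers, low-quality
cells and chromosome-scale dosage events, and bulk cohorts with latent
subtypes and subtype-dependent exponential survival.

## Worked example

```python
import pandas as pd
from cervstrat.synthetic_data import (
    ScSimConfig, CNAEvent, BulkSimConfig, simulate_scrna, simulate_bulk,
)
from cervstrat import qc_norm, cna_infer, io_formats, subtype_strat, survival_stats

# -- single-cell layer: a tumor subclone with a chromosome-scale gain -------
cfg = ScSimConfig(
    n_genes=1200, n_chromosomes=10,
    n_cells_per_type={"epithelial_tumor": 500, "epithelial_normal": 100,
                      "fibroblast": 400, "smc": 300, "tcell": 300},
    cna_events=(CNAEvent("chr3", 0, 120, 3, "epithelial_tumor"),),
    seed=1,
)
counts, truth = simulate_scrna(cfg)
filtered, report = qc_norm.filter_cells(counts)
norm = qc_norm.lognormalize(filtered)

positions = io_formats.gene_positions_from_var(norm)
reference = ((norm.obs["condition"] == "nat")
             & (~norm.obs["cell_type"].str.startswith("epithelial"))).values
track, profile = cna_infer.infer_cna(norm, positions, reference)

# -- bulk layer: four subtypes with decreasing hazards ----------------------
cohort, bulk_truth = simulate_bulk(BulkSimConfig(seed=2))
genes = sorted({g for gs in bulk_truth.elevated_genes.values() for g in gs})
signature = subtype_strat.SignatureSet(
    table=pd.DataFrame({"gene": genes, "log2fc": 2.0, "adj_p": 1e-4}),
    logfc_min=1.5, p_max=0.05)
assignment, _ = subtype_strat.stratify_cohort(cohort, signature, seed=2)
labels = assignment.labels.values
kms = survival_stats.km_estimate(
    cohort.survival_time.values, cohort.event.values, labels)
lr = survival_stats.logrank_test(
    cohort.survival_time.values, cohort.event.values, labels)
```

Printed results (seeds as above):

```
QC: retained 1514/1600 cells (low UMI 44, low genes 44, high mito 48)
mean CNA burden, tumor epithelium: 0.099
mean CNA burden, diploid reference: 0.007
chr3 gain bins called CN=3 in tumor cells: 92.8%
subtype sizes: {'S-P': 100, 'S-D': 100, 'S-I': 100, 'S-H': 100}
median survival (months): {'S-H': 14.4, 'S-P': 28.4, 'S-D': 33.9, 'S-I': 88.5}
4-group log-rank: chi2=135.4, df=3, p=3.69e-29
```

Reading: QC removes exactly the planted low-quality cells; the simulated
single-copy chr3 gain (true dosage 1.5×) is recovered in 92.8% of
(cell, bin) calls in the tumor subclone while the diploid reference stays
at burden ≈ 0; the bulk cohort splits into the four subtypes perfectly,
and their survival separates with the expected ordering — hypoxia-like
S-H worst, immunoactive S-I best.

A command-line interface mirrors the library
(`cervstrat simulate-sc / simulate-bulk / qc / markers / cna / subtype /
survival`); see `cervstrat --help`.

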