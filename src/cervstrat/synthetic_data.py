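"""Synthetic single-cell and bulk cohorts with full ground truth.

Two simulators mirror the data structure the pipeline assumes:

* :func:`simulate_scrna` draws negative-binomial UMI counts for a mixture
  of cell types (tumor/normal epithelium plus stroma and immune cells)
  with per-type marker genes, a controllable fraction of low-quality
  cells, and chromosome-segment copy-number events on named subclones
  acting multiplicatively on the mean (dosage model) — the assumption
  under which expression-based CNA inference is valid.
* :func:`simulate_bulk` draws a bulk expression cohort with K latent
  subtypes, subtype-specific signature elevation, and exponential
  survival with subtype-dependent hazard ratios and uniform censoring.

Both are deterministic under a fixed seed and return truth objects
recording every latent assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from cervstrat.subtype_strat import DEFAULT_LABEL_SETS, SUBTYPE_LABELS


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class CNAEvent:
    """A copy-number event on a contiguous run of genes of one chromosome.

    ``start_gene_index`` is 0-based within the chromosome's gene block;
    ``subclone`` names the cell type carrying the event.
    """

    chromosome: str
    start_gene_index: int
    n_genes: int
    copy_number: int
    subclone: str

    def __post_init__(self) -> None:
        if self.copy_number not in (0, 1, 3, 4):
            raise ConfigError(f"copy_number must be in {{0,1,3,4}}, got {self.copy_number}")
        if self.n_genes <= 0 or self.start_gene_index < 0:
            raise ConfigError("event gene range must be non-empty and non-negative")


@dataclass
class ScSimConfig:
    """Configuration of the single-cell count simulator.

    Defaults emulate a mid-depth droplet run: ~6,000 UMIs per good cell
    over 2,000 nuclear genes, negative-binomial dispersion 0.15 (the
    middle of typical per-gene UMI estimates), 5% low-quality cells, and
    a 4-fold marker shift per type.
    """

    n_genes: int = 2000
    cell_types: tuple[str, ...] = (
        "epithelial_tumor",
        "epithelial_normal",
        "fibroblast",
        "smc",
        "tcell",
    )
    n_cells_per_type: Mapping[str, int] | None = None  # default 300 per type
    marker_genes_per_type: int = 25
    marker_log2fc: float = 2.0
    base_mean_shape: float = 2.0
    base_mean_scale: float = 1.5
    dispersion: float = 0.15
    libsize_sigma: float = 0.35
    n_chromosomes: int = 10  # ~200 genes per chromosome: room for the 100-gene window
    n_mito_genes: int = 10
    mito_fraction_range: tuple[float, float] = (0.02, 0.08)
    low_quality_mito_range: tuple[float, float] = (0.15, 0.40)
    low_quality_umi_range: tuple[float, float] = (40.0, 150.0)
    frac_low_quality: float = 0.05
    cna_events: tuple[CNAEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_type is None:
            self.n_cells_per_type = {t: 300 for t in self.cell_types}
        if not 0.0 <= self.frac_low_quality <= 1.0:
            raise ConfigError("frac_low_quality must be in [0,1]")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        for t in self.n_cells_per_type:
            if t not in self.cell_types:
                raise ConfigError(f"n_cells_per_type names unknown type {t!r}")


@dataclass
class ScTruth:
    """Ground truth of a single-cell simulation."""

    obs: pd.DataFrame
    true_copy_number: dict[str, np.ndarray]  # cell type -> per-nuclear-gene CN
    marker_genes: dict[str, list[str]]

    def cn_for_cells(self, genes: Sequence[str] | None = None) -> pd.DataFrame:
        """Per-cell x per-gene true copy number (nuclear genes)."""
        types = self.obs["cell_type"].values
        mat = np.stack([self.true_copy_number[t] for t in types])
        df = pd.DataFrame(mat, index=self.obs.index, columns=self.gene_names)
        return df if genes is None else df[list(genes)]

    gene_names: list[str] = field(default_factory=list)


def _chromosome_blocks(n_genes: int, n_chromosomes: int) -> list[tuple[str, int, int]]:
    """Contiguous gene index blocks per chromosome: (name, start, stop)."""
    sizes = np.full(n_chromosomes, n_genes // n_chromosomes)
    sizes[: n_genes % n_chromosomes] += 1
    blocks, pos = [], 0
    for i, s in enumerate(sizes):
        blocks.append((f"chr{i + 1}", pos, pos + int(s)))
        pos += int(s)
    return blocks


def simulate_scrna(config: ScSimConfig) -> tuple[ad.AnnData, ScTruth]:
    """Draw a synthetic droplet scRNA-seq count matrix with ground truth.

    Cells of a subclone carrying a CNA event have the affected genes'
    negative-binomial means multiplied by ``copy_number / 2`` before the
    draw.  Low-quality cells are generated by down-scaling totals below
    the UMI threshold or by inflating the mitochondrial fraction, so the
    standard QC thresholds are the exact discriminator.
    """
    rng = np.random.default_rng(config.seed)
    blocks = _chromosome_blocks(config.n_genes, config.n_chromosomes)
    chrom_of = np.empty(config.n_genes, dtype=object)
    within = np.empty(config.n_genes, dtype=np.int64)
    for name, lo, hi in blocks:
        chrom_of[lo:hi] = name
        within[lo:hi] = np.arange(hi - lo)

    nuclear = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    mito = [f"MT-{i + 1}" for i in range(config.n_mito_genes)]
    gene_names = nuclear + mito

    base_mean = rng.gamma(config.base_mean_shape, config.base_mean_scale, size=config.n_genes)
    base_mean = np.maximum(base_mean, 1e-3)

    # per-type mean multipliers: markers then CNA dosage.  Marker genes are
    # scattered across the genome (as real cell-type markers are), so they
    # smooth away in the CNA track instead of mimicking focal events, and
    # drawn from genes expressed above the median base level — a fold
    # change on a near-silent gene is not a usable marker.
    types = list(config.cell_types)
    mult = {t: np.ones(config.n_genes) for t in types}
    marker_genes: dict[str, list[str]] = {}
    m = config.marker_genes_per_type
    eligible = np.where(base_mean >= np.median(base_mean))[0]
    marker_pool = rng.permutation(eligible)[: m * len(types)]
    for i, t in enumerate(types):
        idx = np.sort(marker_pool[i * m : (i + 1) * m])
        mult[t][idx] *= 2.0 ** config.marker_log2fc
        marker_genes[t] = [nuclear[j] for j in idx]

    true_cn = {t: np.full(config.n_genes, 2, dtype=np.int64) for t in types}
    chrom_lookup = {name: (lo, hi) for name, lo, hi in blocks}
    for ev in config.cna_events:
        if ev.subclone not in types:
            raise ConfigError(f"event subclone {ev.subclone!r} is not a configured cell type")
        if ev.chromosome not in chrom_lookup:
            raise ConfigError(f"event chromosome {ev.chromosome!r} not simulated")
        lo, hi = chrom_lookup[ev.chromosome]
        g0 = lo + ev.start_gene_index
        g1 = g0 + ev.n_genes
        if g1 > hi:
            raise ConfigError(
                f"event on {ev.chromosome} spans genes beyond the chromosome block "
                f"({ev.start_gene_index}+{ev.n_genes} > {hi - lo})"
            )
        mult[ev.subclone][g0:g1] *= ev.copy_number / 2.0
        true_cn[ev.subclone][g0:g1] = ev.copy_number

    # assemble cells
    cell_type_col, cond_col, sample_col = [], [], []
    for t in types:
        n = int(config.n_cells_per_type[t])
        cell_type_col += [t] * n
        if "tumor" in t:
            conds = ["tumor"] * n
        elif "normal" in t:
            conds = ["nat"] * n
        else:  # stroma/immune present in both compartments
            conds = ["tumor" if i % 2 == 0 else "nat" for i in range(n)]
        cond_col += conds
        sample_col += ["T1" if c == "tumor" else "N1" for c in conds]
    n_cells = len(cell_type_col)
    cell_type_arr = np.array(cell_type_col)

    libsize = np.exp(rng.normal(0.0, config.libsize_sigma, size=n_cells))
    mito_target = rng.uniform(*config.mito_fraction_range, size=n_cells)

    n_lq = int(np.floor(config.frac_low_quality * n_cells))
    lq_idx = rng.choice(n_cells, size=n_lq, replace=False)
    lq_mode = np.array([""] * n_cells, dtype=object)
    is_lq = np.zeros(n_cells, dtype=bool)
    is_lq[lq_idx] = True
    nuclear_total = {t: float(np.sum(base_mean * mult[t])) for t in types}
    for i in lq_idx:
        if rng.random() < 0.5:
            # shrink the expected total below the UMI threshold
            target = rng.uniform(*config.low_quality_umi_range)
            libsize[i] = target / nuclear_total[cell_type_arr[i]]
            lq_mode[i] = "low_umi"
        else:
            mito_target[i] = rng.uniform(*config.low_quality_mito_range)
            lq_mode[i] = "high_mito"

    # mean matrix: nuclear genes scaled by type multiplier and library size;
    # mito genes sized to hit the per-cell target mitochondrial fraction
    mean = np.empty((n_cells, config.n_genes + config.n_mito_genes))
    mito_profile = rng.gamma(2.0, 1.0, size=config.n_mito_genes)
    mito_profile /= mito_profile.sum()
    for t in types:
        rows = np.where(cell_type_arr == t)[0]
        nuc = base_mean * mult[t]
        mean[np.ix_(rows, np.arange(config.n_genes))] = nuc[None, :] * libsize[rows, None]
    nuc_tot = mean[:, : config.n_genes].sum(axis=1)
    mito_tot = mito_target / (1.0 - mito_target) * nuc_tot
    mean[:, config.n_genes :] = mito_tot[:, None] * mito_profile[None, :]

    # gamma-Poisson draw: NB with mean m, var m + dispersion * m^2
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mean / shape)
    counts = rng.poisson(lam)

    var = pd.DataFrame(index=pd.Index(gene_names, name="gene_symbol"))
    var["chromosome"] = list(chrom_of) + ["chrM"] * config.n_mito_genes
    var["start"] = np.concatenate([within * 10_000, np.arange(config.n_mito_genes) * 1_000])
    var["end"] = var["start"] + 500
    var["mito"] = var.index.str.startswith("MT-")

    obs = pd.DataFrame(
        {
            "cell_type": cell_type_arr,
            "condition": cond_col,
            "sample": sample_col,
            "is_low_quality": is_lq,
            "low_quality_mode": lq_mode,
        },
        index=pd.Index([f"cell{i + 1:05d}" for i in range(n_cells)], name="barcode"),
    )

    adata = ad.AnnData(X=sp.csr_matrix(counts.astype(np.int64)), obs=obs, var=var)
    truth = ScTruth(obs=obs.copy(), true_copy_number=true_cn, marker_genes=marker_genes, gene_names=nuclear)
    return adata, truth


@dataclass
class BulkSimConfig:
    """Configuration of the bulk cohort simulator.

    With the default four subtypes, each subtype elevates its own
    prognostic label gene set (hypoxia, proliferation, differentiation,
    immunoactive) plus ``signature_genes_per_subtype`` extra private
    signature genes by ``effect_log2fc`` on the log2 scale.  Survival is
    exponential with hazard ``baseline_hazard x HR(subtype)`` (per month);
    the default hazard-ratio order makes S-H worst and S-I best.
    """

    n_samples: int = 400
    k_subtypes: int = 4
    signature_genes_per_subtype: int = 10
    effect_log2fc: float = 2.0
    noise_sd: float = 0.5
    baseline_hazard: float = 0.02
    subtype_hazard_ratios: tuple[float, ...] = (3.0, 1.5, 1.0, 0.5)
    censoring_rate: float = 0.2
    n_background_genes: int = 160
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_subtypes < 1:
            raise ConfigError("k_subtypes must be >= 1")
        if self.k_subtypes > self.n_samples:
            raise ConfigError("k_subtypes cannot exceed n_samples")
        if len(self.subtype_hazard_ratios) != self.k_subtypes:
            raise ConfigError("subtype_hazard_ratios must have length k_subtypes")
        if any(h <= 0 for h in self.subtype_hazard_ratios):
            raise ConfigError("hazard ratios must be positive")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ConfigError("censoring_rate must be in [0,1]")


@dataclass
class BulkTruth:
    """Ground truth of a bulk simulation."""

    subtype_index: pd.Series
    subtype_label: pd.Series | None
    elevated_genes: dict[int, list[str]]


def simulate_bulk(config: BulkSimConfig):
    """Draw a synthetic bulk cohort with latent subtypes and survival.

    Returns
    -------
    (BulkCohort, BulkTruth)
    """
    from cervstrat.io_formats import BulkCohort  # local import: io depends on nothing here

    rng = np.random.default_rng(config.seed)
    k = config.k_subtypes

    use_labels = k == len(SUBTYPE_LABELS)
    labels = list(SUBTYPE_LABELS) if use_labels else [f"subtype{i}" for i in range(k)]

    genes: list[str] = []
    elevated: dict[int, list[str]] = {i: [] for i in range(k)}
    if use_labels:
        for i, lab in enumerate(labels):
            for g in DEFAULT_LABEL_SETS[lab]:
                genes.append(g)
                elevated[i].append(g)
    for i in range(k):
        extra = [f"SIG{i + 1}_{j + 1:03d}" for j in range(config.signature_genes_per_subtype)]
        genes += extra
        elevated[i] += extra
    genes += [f"B{j + 1:04d}" for j in range(config.n_background_genes)]

    # balanced subtype assignment, shuffled
    assign = np.tile(np.arange(k), config.n_samples // k + 1)[: config.n_samples]
    rng.shuffle(assign)

    baseline = rng.normal(5.0, 1.0, size=len(genes))
    gene_index = {g: j for j, g in enumerate(genes)}
    expr = baseline[None, :] + rng.normal(0.0, config.noise_sd, size=(config.n_samples, len(genes)))
    for i in range(k):
        rows = np.where(assign == i)[0]
        cols = [gene_index[g] for g in elevated[i]]
        expr[np.ix_(rows, cols)] += config.effect_log2fc

    hr = np.asarray(config.subtype_hazard_ratios)[assign]
    hazard = config.baseline_hazard * hr
    t_event = rng.exponential(1.0 / hazard)
    censor = rng.random(config.n_samples) < config.censoring_rate
    time = np.where(censor, rng.uniform(0.0, t_event), t_event)
    time = np.maximum(time, 1e-6)  # survival times must be strictly positive
    event = (~censor).astype(np.int64)

    sample_ids = pd.Index([f"S{i + 1:04d}" for i in range(config.n_samples)], name="sample_id")
    cohort = BulkCohort(
        expression=pd.DataFrame(expr, index=sample_ids, columns=genes),
        survival_time=pd.Series(time, index=sample_ids, name="time"),
        event=pd.Series(event, index=sample_ids, name="event"),
    )
    truth = BulkTruth(
        subtype_index=pd.Series(assign, index=sample_ids, name="subtype_index"),
        subtype_label=pd.Series([labels[i] for i in assign], index=sample_ids, name="subtype_label")
        if use_labels
        else None,
        elevated_genes=elevated,
    )
    return cohort, truth
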