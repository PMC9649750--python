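"""Expression-based copy-number inference and per-cell burden scoring.

The malignancy discriminator of the pipeline: per-cell expression is
expressed relative to a diploid reference population, clipped, smoothed
along the genome with a 100-gene sliding window within each chromosome,
median-centered per cell, averaged into nonoverlapping 30-gene bins, and
rounded to integer copy numbers (neutral = 2) in copy-number space via
CN = round(2 * 2^m), with half-integer ties rounded away from neutral.
The per-cell burden is the mean absolute deviation |CN - 2| over bins.

The reference population should be cells believed diploid — by default
the non-epithelial cells of normal adjacent tissue.  Sex chromosomes are
excluded from the analysis karyotype by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Autosomes only — the default analysis karyotype.
AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))


def order_genes(
    norm: ad.AnnData,
    positions: pd.DataFrame,
    *,
    karyotype: tuple[str, ...] = AUTOSOMES,
    window: int = 100,
) -> pd.DataFrame:
    """Genomic ordering of the genes shared by matrix and position table.

    Genes without positions, or on chromosomes outside ``karyotype``, are
    dropped (counts logged).  Ordering is stable by (karyotype chromosome
    rank, start).  Raises if no chromosome retains at least ``window``
    genes — too little contiguity to smooth.
    """
    pos = positions.set_index("gene_symbol")
    present = norm.var_names.intersection(pos.index)
    n_dropped = norm.n_vars - len(present)
    if n_dropped:
        logger.info("order_genes: %d genes without positions dropped", n_dropped)
    sub = pos.loc[present, ["chromosome", "start"]].copy()
    rank = {c: i for i, c in enumerate(karyotype)}
    known = sub["chromosome"].isin(rank)
    if (~known).any():
        logger.info(
            "order_genes: %d genes on chromosomes outside the karyotype dropped",
            int((~known).sum()),
        )
        sub = sub[known]
    sub["_rank"] = sub["chromosome"].map(rank)
    sub = sub.sort_values(["_rank", "start"], kind="stable").drop(columns="_rank")
    if sub.empty or sub.groupby("chromosome", sort=False).size().max() < window:
        raise ValueError(f"no chromosome has >= {window} positioned genes; cannot smooth")
    return sub.reset_index().rename(columns={"index": "gene_symbol"})


@dataclass
class SmoothedTrack:
    """Per-cell smoothed relative log-expression over genomically ordered genes."""

    values: np.ndarray  # cells x ordered genes
    cell_ids: pd.Index
    genes: pd.DataFrame  # ordering table (gene_symbol, chromosome, start)
    window: int

    @property
    def chromosomes(self) -> np.ndarray:
        return self.genes["chromosome"].values


def _chromosome_slices(chroms: np.ndarray) -> list[tuple[str, int, int]]:
    out, start = [], 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            out.append((chroms[start], start, i))
            start = i
    return out


def _centered_moving_average(block: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1, truncated at the edges.

    The window at position i covers [i - h, i + h] with h = window // 2,
    intersected with the chromosome; near an edge it is truncated (not
    symmetrically shrunk), so every average pools at least h + 1 genes —
    a symmetric shrink degenerates to single-gene windows at chromosome
    ends and inflates the variance of edge bins far beyond the
    neutral-call margin.
    """
    L = block.shape[1]
    h = window // 2
    cs = np.concatenate([np.zeros((block.shape[0], 1)), np.cumsum(block, axis=1)], axis=1)
    pos = np.arange(L)
    lo = np.maximum(pos - h, 0)
    hi = np.minimum(pos + h + 1, L)
    return (cs[:, hi] - cs[:, lo]) / (hi - lo)


def smooth_expression(
    norm: ad.AnnData,
    ordering: pd.DataFrame,
    reference_cells,
    window: int = 100,
    clip_sd: float = 3.0,
    denoise_sd: float = 0.0,
) -> SmoothedTrack:
    """Smoothed relative expression per cell along the ordered genome.

    Steps: subtract the reference-cell mean per gene; clip to
    ``+-clip_sd`` pooled standard deviations of the reference residuals;
    centered ``window``-gene moving average within each chromosome
    (chromosomes shorter than the window are averaged whole, with a
    warning); median-center each cell's full track.  Optionally denoise:
    with ``denoise_sd > 0``, values within that many pooled standard
    deviations of the reference cells' centered tracks are shrunk to
    zero (the reference tool's documented stabilisation; off by default).

    ``reference_cells`` may be a boolean mask over cells or a list of
    cell ids; it may overlap the cells of interest.
    """
    ref_mask = np.asarray(reference_cells)
    if ref_mask.dtype != bool:
        ref_mask = norm.obs_names.isin(reference_cells)
    if not ref_mask.any():
        raise ValueError("reference cell set is empty")

    M = np.asarray(norm[:, ordering["gene_symbol"].values].X.todense())
    ref_mean = M[ref_mask].mean(axis=0)
    R = M - ref_mean
    sd = float(R[ref_mask].std())
    if sd > 0:
        R = np.clip(R, -clip_sd * sd, clip_sd * sd)

    smoothed = np.empty_like(R)
    for chrom, lo, hi in _chromosome_slices(ordering["chromosome"].values):
        block = R[:, lo:hi]
        if hi - lo < window:
            warnings.warn(
                f"{chrom}: {hi - lo} genes < window {window}; using whole-chromosome mean",
                stacklevel=2,
            )
            smoothed[:, lo:hi] = block.mean(axis=1, keepdims=True)
        else:
            smoothed[:, lo:hi] = _centered_moving_average(block, window)
    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    if denoise_sd > 0:
        ref_sd = float(smoothed[ref_mask].std())
        smoothed = np.where(np.abs(smoothed) < denoise_sd * ref_sd, 0.0, smoothed)
    return SmoothedTrack(values=smoothed, cell_ids=norm.obs_names, genes=ordering, window=window)


@dataclass
class CNAProfile:
    """Integer copy-number calls per cell over nonoverlapping genomic bins."""

    copy_number: np.ndarray  # cells x bins, int
    bins: pd.DataFrame  # chromosome, gene_start, gene_stop, n_genes, span_start, span_end
    cell_ids: pd.Index

    def burden(self) -> pd.Series:
        """Mean |CN - 2| per cell."""
        return pd.Series(np.abs(self.copy_number - 2).mean(axis=1), index=self.cell_ids, name="burden")


def _round_away_from_neutral(values: np.ndarray) -> np.ndarray:
    """Round to nearest integer; exact halves round away from CN 2."""
    return np.where(values >= 2.0, np.floor(values + 0.5), np.ceil(values - 0.5))


def call_bins(
    track: SmoothedTrack, bin_size: int = 30, min_trailing: int = 10, log_base: float = np.e
) -> CNAProfile:
    """Average the smoothed track in nonoverlapping ``bin_size``-gene bins
    and convert to integer copy number.

    Bins never cross chromosome boundaries.  A trailing remainder of at
    least ``min_trailing`` genes forms its own bin; a smaller remainder is
    merged into the previous bin (or kept alone if the chromosome has no
    other bin).  The bin mean m is a relative log expression in base
    ``log_base`` (natural log for ln(1+x)-normalized input); it is
    converted to a log2 dosage ratio and mapped to copy number as
    CN = round(2 * 2^m2), clamped to [0, 6], with half-integer ties
    rounded away from neutral.
    """
    edges: list[tuple[str, int, int]] = []
    for chrom, lo, hi in _chromosome_slices(track.chromosomes):
        L = hi - lo
        n_full = L // bin_size
        rem = L - n_full * bin_size
        bounds = [lo + i * bin_size for i in range(n_full)] + [lo + n_full * bin_size]
        if rem:
            if rem >= min_trailing or n_full == 0:
                bounds.append(hi)
            else:
                bounds[-1] = hi  # merge remainder into the previous bin
                logger.info("call_bins: %s trailing %d genes merged into last bin", chrom, rem)
        for a, b in zip(bounds[:-1], bounds[1:]):
            edges.append((chrom, a, b))

    to_log2 = np.log2(np.e) if log_base == np.e else np.log2(log_base)
    starts = track.genes["start"].values
    bin_rows, cn_cols = [], []
    for chrom, a, b in edges:
        m = track.values[:, a:b].mean(axis=1) * to_log2
        cn = np.clip(_round_away_from_neutral(2.0 * np.exp2(m)), 0, 6)
        cn_cols.append(cn)
        bin_rows.append(
            {
                "chromosome": chrom,
                "gene_start": a,
                "gene_stop": b,
                "n_genes": b - a,
                "span_start": int(starts[a]),
                "span_end": int(starts[b - 1]),
            }
        )
    copy_number = np.column_stack(cn_cols).astype(np.int64)
    return CNAProfile(copy_number=copy_number, bins=pd.DataFrame(bin_rows), cell_ids=track.cell_ids)


def cna_burden(profile: CNAProfile) -> pd.Series:
    """Per-cell CNA burden: mean absolute deviation from diploid over bins."""
    return profile.burden()


def compare_cluster_cna(profile: CNAProfile, clusters) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster burden summary and pairwise rank-sum tests (BH-adjusted).

    Clusters with fewer than 3 cells are excluded from testing (logged).
    With a single eligible cluster the pairwise table is empty.
    """
    burden = profile.burden()
    clusters = pd.Series(np.asarray(clusters), index=profile.cell_ids, name="cluster")
    summary = (
        pd.DataFrame({"cluster": clusters, "burden": burden})
        .groupby("cluster")["burden"]
        .agg(n_cells="size", mean_burden="mean", median_burden="median")
        .reset_index()
    )
    eligible = summary.loc[summary["n_cells"] >= 3, "cluster"].tolist()
    skipped = set(summary["cluster"]) - set(eligible)
    if skipped:
        logger.info("compare_cluster_cna: clusters excluded from testing (<3 cells): %s", sorted(skipped))
    rows = []
    for i, a in enumerate(eligible):
        for b in eligible[i + 1 :]:
            x, y = burden[clusters == a], burden[clusters == b]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                p = stats.mannwhitneyu(
                    x, y, alternative="two-sided", method="asymptotic"
                ).pvalue
            p = 1.0 if np.isnan(p) else float(p)  # all-tied burdens: no evidence
            rows.append({"cluster_a": a, "cluster_b": b, "p_value": p})
    pairwise = pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "p_value"])
    if len(pairwise):
        pairwise["adj_p"] = multipletests(pairwise["p_value"], method="fdr_bh")[1]
    else:
        pairwise["adj_p"] = pd.Series(dtype=float)
    return summary, pairwise


def infer_cna(
    norm: ad.AnnData,
    positions: pd.DataFrame,
    reference_cells,
    *,
    window: int = 100,
    bin_size: int = 30,
    karyotype: tuple[str, ...] = AUTOSOMES,
) -> tuple[SmoothedTrack, CNAProfile]:
    """Convenience pipeline: order genes, smooth, call integer bins."""
    ordering = order_genes(norm, positions, karyotype=karyotype, window=window)
    track = smooth_expression(norm, ordering, reference_cells, window=window)
    profile = call_bins(track, bin_size=bin_size)
    return track, profile
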