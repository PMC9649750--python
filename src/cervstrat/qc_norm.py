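"""Cell-level quality control, log-normalization and HVG selection.

QC removes cells with total UMI < 200, detected genes < 200 or
mitochondrial UMI fraction > 10% (strict inequalities: cells exactly at a
threshold are kept).  Normalization divides each cell by its total count,
multiplies by a scale factor (10,000 by default) and applies the natural
log1p; zeros map to zeros and sparsity is preserved.  Highly variable
genes are ranked by binned dispersion: the variance-to-mean ratio is
z-scored within 20 mean bins, with ties broken by gene order.

Downstream grouping of cells, where needed, uses k-means on the top
principal components of the HVG-scaled data with a fixed seed
(:func:`cluster_cells`) — cluster identity is only an input to marker and
CNA comparisons here, not a deliverable of its own.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


class EmptyResultError(RuntimeError):
    """A filtering step removed every observation."""


@dataclass(frozen=True)
class QCThresholds:
    """Cell-quality thresholds. A cell is removed when total UMI < min_umi,
    detected genes < min_genes, or mito fraction > max_mito_frac."""

    min_umi: int = 200
    min_genes: int = 200
    max_mito_frac: float = 0.10
    scale_factor: float = 10_000.0
    n_hvg: int = 2000

    def __post_init__(self) -> None:
        if min(self.min_umi, self.min_genes, self.scale_factor, self.n_hvg) <= 0:
            raise ValueError("all thresholds must be positive")
        if not 0.0 < self.max_mito_frac <= 1.0:
            raise ValueError("max_mito_frac must be in (0, 1]")


@dataclass(frozen=True)
class QCReport:
    """Per-criterion removal tallies (non-exclusive: a cell failing several
    criteria is counted in each tally but removed once)."""

    n_input_cells: int
    n_removed_low_umi: int
    n_removed_low_genes: int
    n_removed_high_mito: int
    n_retained: int


def cell_qc_metrics(counts: ad.AnnData) -> pd.DataFrame:
    """Per-cell total UMI, detected genes and mitochondrial fraction."""
    if "mito" not in counts.var:
        raise ValueError("var lacks the 'mito' flag; load counts through io_formats")
    X = sp.csr_matrix(counts.X)
    total = np.asarray(X.sum(axis=1)).ravel()
    n_genes = X.getnnz(axis=1)
    mito_mask = counts.var["mito"].values.astype(bool)
    mito_total = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 1.0)
    return pd.DataFrame(
        {"total_umi": total, "n_genes": n_genes, "mito_frac": mito_frac},
        index=counts.obs_names,
    )


def filter_cells(
    counts: ad.AnnData, thresholds: QCThresholds = QCThresholds()
) -> tuple[ad.AnnData, QCReport]:
    """Remove low-quality cells; returns the filtered matrix and a report."""
    metrics = cell_qc_metrics(counts)
    low_umi = metrics["total_umi"].values < thresholds.min_umi
    low_genes = metrics["n_genes"].values < thresholds.min_genes
    high_mito = metrics["mito_frac"].values > thresholds.max_mito_frac
    remove = low_umi | low_genes | high_mito
    report = QCReport(
        n_input_cells=counts.n_obs,
        n_removed_low_umi=int(low_umi.sum()),
        n_removed_low_genes=int(low_genes.sum()),
        n_removed_high_mito=int(high_mito.sum()),
        n_retained=int((~remove).sum()),
    )
    if report.n_retained == 0:
        raise EmptyResultError("no cells pass the quality thresholds")
    return counts[~remove].copy(), report


def lognormalize(counts: ad.AnnData, scale_factor: float = 10_000.0) -> ad.AnnData:
    """Per-cell total-count normalization to ``scale_factor`` and ln(1+x).

    value(g, c) = ln(1 + count(g, c) * scale_factor / total(c)).
    """
    X = sp.csr_matrix(counts.X, dtype=np.float64)
    total = np.asarray(X.sum(axis=1)).ravel()
    if (total <= 0).any():
        raise ValueError("cells with zero total counts present; run filter_cells first")
    norm = X.multiply(scale_factor / total[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out = counts.copy()
    out.X = norm
    out.uns["scale_factor"] = float(scale_factor)
    out.uns["lognormalized"] = True
    return out


def select_hvgs(norm: ad.AnnData, n_hvg: int = 2000, n_bins: int = 20) -> list[str]:
    """Top ``n_hvg`` genes by mean-binned standardized dispersion.

    Dispersion = variance / mean of the normalized values; z-scored within
    ``n_bins`` equal-frequency mean bins.  Genes with zero variance are
    never selected.  If fewer informative genes exist than requested, all
    are returned with a warning.
    """
    X = sp.csr_matrix(norm.X)
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0)
    informative = (var > 1e-12) & (mean > 0)
    if informative.sum() < n_hvg:
        warnings.warn(
            f"only {int(informative.sum())} informative genes available for n_hvg={n_hvg}",
            stacklevel=2,
        )
    idx = np.where(informative)[0]
    disp = var[idx] / mean[idx]
    bins = pd.qcut(mean[idx], q=min(n_bins, len(idx)), labels=False, duplicates="drop")
    z = np.zeros(len(idx))
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = disp[sel].mean(), disp[sel].std()
        z[sel] = (disp[sel] - mu) / sd if sd > 0 else 0.0
    # rank by z descending; ties broken by original gene order
    order = np.lexsort((idx, -z))
    chosen = idx[order][:n_hvg]
    return [norm.var_names[j] for j in chosen]


def cluster_cells(
    norm: ad.AnnData,
    hvgs: list[str] | None = None,
    n_clusters: int = 7,
    n_pcs: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Group cells by k-means on the top PCs of z-scaled HVG expression."""
    if hvgs is None:
        hvgs = select_hvgs(norm)
    X = np.asarray(norm[:, hvgs].X.todense())
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Z = np.clip((X - mu) / np.where(sd > 0, sd, 1.0), -10, 10)
    n_pcs = min(n_pcs, Z.shape[1], Z.shape[0] - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(Z)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(pcs)
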