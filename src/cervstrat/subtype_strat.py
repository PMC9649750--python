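"""Signature-based stratification of a bulk cohort into four subtypes.

A tumor-vs-normal epithelial marker table from single-cell analysis is
thresholded into a signature gene set; the bulk cohort is restricted to
those genes and z-scored per gene; samples are grouped by consensus
k-means (many restarts, hierarchical cut of the co-assignment matrix);
and the k clusters are labeled with the four prognostic subtype names —
S-H (hypoxia), S-P (proliferation), S-D (differentiation) and S-I
(immunoactive) — by maximizing total mean-z enrichment of each subtype's
marker gene list under a one-to-one assignment.

The default label gene lists follow the published ten-gene subtype
marker panels verbatim (including their printed symbol spellings; the
immunoactive list contains nine unique genes after deduplication).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from cervstrat.io_formats import BulkCohort

logger = logging.getLogger(__name__)

#: Canonical subtype order: hypoxia, proliferation, differentiation, immunoactive.
SUBTYPE_LABELS: tuple[str, ...] = ("S-H", "S-P", "S-D", "S-I")

DEFAULT_LABEL_SETS: dict[str, tuple[str, ...]] = {
    "S-H": ("MMP1", "IGFBP3", "ITGA5", "CDH3", "ICAM1", "FLOD2", "TGFB1", "PLAU", "FSCN1", "ITGB4"),
    "S-P": ("TUBB", "UBE2C", "NUSAP1", "CKD1", "PSMC4", "PCNA", "DLG1", "ATP2C1", "MKI67", "TOP2A"),
    "S-D": ("KRT6A", "SPRR1B", "KRT16", "AQP3", "PERP", "CSTA", "DSG3", "SPRR2D", "CAPN1", "CDKN2A"),
    "S-I": ("HLA-DMA", "CD74", "HLA-C", "CXCL10", "PSMB3", "IFI6", "CXCL17", "CST6", "HLA-DQA1"),
}


def load_label_sets(sets: dict[str, list[str] | tuple[str, ...]]) -> dict[str, tuple[str, ...]]:
    """Validate label gene sets: within-set duplicates dropped with a warning,
    duplicates *across* sets rejected with an error listing them."""
    clean: dict[str, tuple[str, ...]] = {}
    for name, genes in sets.items():
        uniq = list(dict.fromkeys(genes))
        if len(uniq) != len(genes):
            warnings.warn(f"label set {name!r}: duplicate genes dropped", stacklevel=2)
        clean[name] = tuple(uniq)
    seen: dict[str, str] = {}
    shared = []
    for name, genes in clean.items():
        for g in genes:
            if g in seen:
                shared.append(f"{g} ({seen[g]}/{name})")
            seen[g] = name
    if shared:
        raise ValueError(f"genes shared across label sets: {', '.join(shared)}")
    return clean


@dataclass
class SignatureSet:
    """Tumor-epithelial signature genes with their DE evidence."""

    table: pd.DataFrame  # gene, log2fc, adj_p
    logfc_min: float
    p_max: float

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def derive_signature(
    markers: pd.DataFrame, logfc_min: float = 1.5, p_max: float = 0.05, use_adj_p: bool = True
) -> SignatureSet:
    """Threshold a tumor-vs-normal marker table into a signature set.

    Keeps genes with |log2fc| > ``logfc_min`` (both up- and down-regulated
    in tumor) and (adjusted) p < ``p_max``.
    """
    pcol = "adj_p" if use_adj_p else "p_value"
    keep = (markers["log2fc"].abs() > logfc_min) & (markers[pcol] < p_max)
    table = markers.loc[keep, ["gene", "log2fc", pcol]].rename(columns={pcol: "adj_p"})
    if table.empty:
        raise ValueError(
            f"no genes pass |log2fc| > {logfc_min} and {pcol} < {p_max}; relax the thresholds"
        )
    return SignatureSet(table=table.reset_index(drop=True), logfc_min=logfc_min, p_max=p_max)


def score_samples(bulk: BulkCohort, signature: SignatureSet, min_genes: int = 20) -> pd.DataFrame:
    """Restrict the cohort to signature genes and z-score each gene.

    Genes missing from the cohort are tolerated with a warning as long as
    at least ``min_genes`` remain; zero-variance genes are dropped (logged).
    """
    present = [g for g in signature.genes if g in bulk.expression.columns]
    missing = sorted(set(signature.genes) - set(present))
    if len(present) < min_genes:
        raise ValueError(
            f"only {len(present)} signature genes present (need >= {min_genes}); "
            f"missing: {', '.join(missing[:20])}"
        )
    if missing:
        warnings.warn(f"{len(missing)} signature genes absent from cohort", stacklevel=2)
    sub = bulk.expression[present]
    sd = sub.std(ddof=0)
    degenerate = sd.index[sd == 0].tolist()
    if degenerate:
        logger.info("score_samples: dropping %d zero-variance genes", len(degenerate))
        sub = sub.drop(columns=degenerate)
        sd = sd.drop(index=degenerate)
    return (sub - sub.mean()) / sd


def consensus_matrix(z: pd.DataFrame, k: int, n_restarts: int, seed: int) -> np.ndarray:
    """Average co-assignment over ``n_restarts`` k-means runs."""
    n = z.shape[0]
    co = np.zeros((n, n))
    X = z.values
    for r in range(n_restarts):
        labels = KMeans(n_clusters=k, n_init=1, init="random", random_state=seed + r).fit_predict(X)
        co += labels[:, None] == labels[None, :]
    return co / n_restarts


def cluster_subtypes(
    z: pd.DataFrame, k: int = 4, n_restarts: int = 50, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Consensus k-means clustering of the sample z-matrix.

    Returns (cluster indices 0..k-1, consensus co-assignment matrix).
    Final clusters come from an average-linkage hierarchical cut of the
    consensus distances at k; deterministic given the seed.
    """
    if k > z.shape[0]:
        raise ValueError(f"k={k} exceeds n_samples={z.shape[0]}")
    if k == 1:
        return np.zeros(z.shape[0], dtype=int), np.ones((z.shape[0], z.shape[0]))
    co = consensus_matrix(z, k, n_restarts, seed)
    dist = 1.0 - co
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    return labels, co


@dataclass
class SubtypeAssignment:
    """Per-sample cluster index and semantic subtype label."""

    assignment: pd.DataFrame  # sample_id index; cluster, label
    cluster_scores: pd.DataFrame = field(repr=False)  # clusters x labels mean-z

    @property
    def labels(self) -> pd.Series:
        return self.assignment["label"]


def label_subtypes(
    z: pd.DataFrame,
    clusters,
    label_sets: dict[str, tuple[str, ...]] | None = None,
) -> SubtypeAssignment:
    """Assign one semantic label per cluster by maximizing total mean-z.

    score(cluster, label) = mean z over the cluster's samples and the
    label's genes present in ``z``.  The one-to-one assignment maximizing
    the total score is found exhaustively over permutations; ties break
    deterministically by lexicographic permutation order (warned).
    """
    sets = load_label_sets(label_sets or DEFAULT_LABEL_SETS)
    clusters = np.asarray(clusters)
    uniq = np.unique(clusters)
    names = list(sets)
    if len(uniq) != len(names):
        raise ValueError(f"{len(uniq)} clusters cannot be labeled with {len(names)} labels one-to-one")
    for name, genes in sets.items():
        if not any(g in z.columns for g in genes):
            raise ValueError(f"no genes of label set {name!r} present; label unassignable")

    scores = pd.DataFrame(index=uniq, columns=names, dtype=float)
    for c in uniq:
        rows = z.loc[clusters == c]
        for name, genes in sets.items():
            cols = [g for g in genes if g in z.columns]
            scores.loc[c, name] = float(rows[cols].values.mean())

    best_perm, best_total, tied = None, -np.inf, False
    for perm in itertools.permutations(names):
        total = sum(scores.loc[c, lab] for c, lab in zip(uniq, perm))
        if total > best_total + 1e-12:
            best_perm, best_total, tied = perm, total, False
        elif abs(total - best_total) <= 1e-12 and perm != best_perm:
            tied = True
    if tied:
        warnings.warn("tie between label permutations; broken lexicographically", stacklevel=2)

    label_of = dict(zip(uniq, best_perm))
    assignment = pd.DataFrame(
        {"cluster": clusters, "label": [label_of[c] for c in clusters]}, index=z.index
    )
    return SubtypeAssignment(assignment=assignment, cluster_scores=scores)


def enrichment_report(
    cluster_genes: dict, label_sets: dict[str, tuple[str, ...]], universe: list[str]
) -> pd.DataFrame:
    """Hypergeometric overlap of per-cluster gene lists with each label set.

    One-sided upper-tail p-values, BH-adjusted across all (cluster, set)
    pairs.  ``universe`` is the gene background both lists are drawn from.
    """
    sets = load_label_sets(label_sets)
    uni = set(universe)
    M = len(uni)
    rows = []
    for cluster, genes in cluster_genes.items():
        glist = set(genes) & uni
        for name, sgenes in sets.items():
            s = set(sgenes) & uni
            overlap = len(glist & s)
            # P(X >= overlap) drawing |glist| from universe with |s| successes
            p = float(stats.hypergeom.sf(overlap - 1, M, len(s), len(glist))) if s and glist else 1.0
            rows.append(
                {"cluster": cluster, "label_set": name, "overlap": overlap,
                 "set_size": len(s), "query_size": len(glist), "p_value": min(p, 1.0)}
            )
    df = pd.DataFrame(rows)
    df["adj_p"] = multipletests(df["p_value"], method="fdr_bh")[1] if len(df) else []
    return df


def stratify_cohort(
    bulk: BulkCohort,
    signature: SignatureSet,
    *,
    k: int = 4,
    n_restarts: int = 50,
    seed: int = 0,
    label_sets: dict[str, tuple[str, ...]] | None = None,
) -> tuple[SubtypeAssignment, pd.DataFrame]:
    """End-to-end stratification: score, cluster, label.

    Returns the labeled assignment and the z-matrix used.
    """
    z = score_samples(bulk, signature)
    clusters, _ = cluster_subtypes(z, k=k, n_restarts=n_restarts, seed=seed)
    return label_subtypes(z, clusters, label_sets), z
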