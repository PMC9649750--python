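"""Two-group differential expression with fraction-expressed filters.

The test is the two-sided Wilcoxon rank-sum (Mann–Whitney U) with the
tie-corrected normal approximation; genes are tested only if expressed
(nonzero) in at least ``min_pct`` of cells in one of the two groups, and
Benjamini–Hochberg adjustment runs over tested genes only (filtering
precedes testing).  The fold change is computed on de-logged normalized
means with a +1 pseudocount in numerator and denominator:
log2fc = log2((mean(expm1 x)_1 + 1) / (mean(expm1 x)_2 + 1)).

The default significance filters encode a 1.5-fold change
(|log2fc| > 0.585 = log2 1.5) at adjusted p < 0.01.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIN_PCT = 0.20
MIN_ABS_LOG2FC = 0.585  # log2(1.5)
MAX_ADJ_P = 0.01


def find_markers(
    norm: ad.AnnData,
    groups,
    *,
    group1=None,
    min_pct: float = MIN_PCT,
    min_abs_log2fc: float = MIN_ABS_LOG2FC,
    max_adj_p: float = MAX_ADJ_P,
) -> pd.DataFrame:
    """Differential expression between the two groups of a cell partition.

    Parameters
    ----------
    norm
        Log-normalized expression (cells x genes).
    groups
        Per-cell labels with exactly two distinct values, or a boolean
        mask (True = group 1).
    group1
        Which label is treated as group 1 (fold changes are group1 over
        group2).  Default: the first distinct label in sorted order.

    Returns
    -------
    DataFrame with one row per *tested* gene: ``gene, log2fc, pct_group1,
    pct_group2, p_value, adj_p, direction, significant`` sorted by
    p-value.  Rows failing the fold-change or adjusted-p filters are kept
    with ``significant=False``.
    """
    groups = np.asarray(groups)
    if groups.dtype == bool:
        mask1 = groups
    else:
        uniq = sorted(pd.unique(groups).tolist())
        if len(uniq) != 2:
            raise ValueError(f"groups must have exactly 2 distinct values, got {len(uniq)}")
        if group1 is None:
            group1 = uniq[0]
        mask1 = groups == group1
    mask2 = ~mask1
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    if min(n1, n2) < 3:
        warnings.warn(f"a group has fewer than 3 cells (n1={n1}, n2={n2}); p-values unreliable",
                      stacklevel=2)

    X = np.asarray(norm.X.todense()) if hasattr(norm.X, "todense") else np.asarray(norm.X)
    X1, X2 = X[mask1], X[mask2]
    pct1 = (X1 > 0).mean(axis=0)
    pct2 = (X2 > 0).mean(axis=0)
    tested = (pct1 >= min_pct) | (pct2 >= min_pct)
    if not tested.any():
        return pd.DataFrame(
            columns=["gene", "log2fc", "pct_group1", "pct_group2", "p_value", "adj_p",
                     "direction", "significant"]
        )

    t1, t2 = X1[:, tested], X2[:, tested]
    m1 = np.expm1(t1).mean(axis=0)
    m2 = np.expm1(t2).mean(axis=0)
    log2fc = np.log2((m1 + 1.0) / (m2 + 1.0))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(
            t1, t2, axis=0, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        pvals = np.asarray(res.pvalue, dtype=float)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # all-tied gene -> no evidence

    adj = multipletests(pvals, method="fdr_bh")[1]
    df = pd.DataFrame(
        {
            "gene": np.asarray(norm.var_names)[tested],
            "log2fc": log2fc,
            "pct_group1": pct1[tested],
            "pct_group2": pct2[tested],
            "p_value": pvals,
            "adj_p": adj,
        }
    )
    df["direction"] = np.where(df["log2fc"] >= 0, "up", "down")
    df["significant"] = (df["log2fc"].abs() > min_abs_log2fc) & (df["adj_p"] < max_adj_p)
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def one_vs_rest_markers(norm: ad.AnnData, clusters, **kwargs) -> dict:
    """Apply :func:`find_markers` for each cluster against all other cells."""
    clusters = np.asarray(clusters)
    uniq = pd.unique(clusters)
    if len(uniq) < 2:
        raise ValueError("one-vs-rest requires at least 2 clusters")
    out = {}
    for c in uniq:
        out[c] = find_markers(norm, clusters == c, **kwargs)
    return out
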