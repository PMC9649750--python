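"""Independent brute-force oracles used to cross-check the implementation.

Written from the textbook definitions, deliberately sharing no code with
the package paths they verify.
"""

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats


def norm_adata(X):
    """Wrap a dense matrix as an AnnData of 'normalized' values."""
    X = np.asarray(X, dtype=float)
    return ad.AnnData(
        X=sp.csr_matrix(X),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=[f"G{j}" for j in range(X.shape[1])]),
    )


def oracle_ranksum_p(x, y):
    """Two-sided tie-corrected normal-approximation rank-sum p-value."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12 * (n + 1 - tie_term)
    if var == 0:
        return 1.0
    z = (u1 - mu) / np.sqrt(var)
    return 2 * stats.norm.sf(abs(z))


def naive_product_limit(times, events):
    """Textbook Kaplan-Meier values at each distinct event time."""
    out = {}
    s = 1.0
    for et in sorted(set(times[events == 1])):
        n_i = (times >= et).sum()
        d_i = ((times == et) & (events == 1)).sum()
        s *= 1.0 - d_i / n_i
        out[et] = s
    return out
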