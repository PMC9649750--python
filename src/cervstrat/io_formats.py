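"""Readers and writers for the external formats the pipeline touches.

Single-cell counts travel as the standard 10x triple (``matrix.mtx`` +
``barcodes.tsv`` + ``features.tsv``, optionally gzipped), gene genomic
positions as BED-like 4+-column TSV, and bulk cohorts as plain TSV with
survival columns.  In memory, single-cell data lives in an
:class:`anndata.AnnData` with cells as observations and genes as variables
(the scanpy convention; the on-disk MTX is genes x cells and is transposed
on load), and a bulk cohort in the :class:`BulkCohort` dataclass.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Human autosome + sex chromosome vocabulary, in karyotype order.
HUMAN_KARYOTYPE: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")

#: Default symbol prefix marking mitochondrion-encoded genes.
MITO_PREFIX = "MT-"


class SchemaError(ValueError):
    """An input file violates the declared schema."""


def _find_file(directory: Path, stem: str) -> Path:
    """Locate ``stem`` or ``stem + '.gz'`` in ``directory``."""
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"missing required file {stem}[.gz] in {directory}")


def _read_tsv_lines(path: Path) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return pd.read_csv(fh, sep="\t", header=None, dtype=str)


def read_10x_mtx(
    directory: str | Path,
    *,
    mito_prefix: str = MITO_PREFIX,
    symbol_column: int | None = None,
) -> ad.AnnData:
    """Read a 10x-style MTX triple into an AnnData of integer counts.

    Parameters
    ----------
    directory
        Directory containing ``matrix.mtx``, ``barcodes.tsv`` and
        ``features.tsv`` (or ``genes.tsv``), each optionally gzipped.
    mito_prefix
        Gene symbols starting with this prefix are flagged mitochondrial
        in ``var["mito"]``.
    symbol_column
        Column of the features file holding gene symbols.  Default: the
        only column for 1-column files, otherwise the second column
        (id + symbol [+ feature type]).

    Returns
    -------
    AnnData with sparse integer ``X`` (cells x genes), barcodes as
    ``obs_names`` and symbols as ``var_names``.
    """
    directory = Path(directory)
    mtx_path = _find_file(directory, "matrix.mtx")
    barcodes_path = _find_file(directory, "barcodes.tsv")
    try:
        features_path = _find_file(directory, "features.tsv")
    except FileNotFoundError:
        features_path = _find_file(directory, "genes.tsv")

    mat = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    barcodes = _read_tsv_lines(barcodes_path)[0].tolist()
    features = _read_tsv_lines(features_path)

    n_feat, n_bar = len(features), len(barcodes)
    if mat.shape == (n_feat, n_bar):
        mat = mat.T.tocsr()  # on-disk convention is genes x cells
    elif mat.shape == (n_bar, n_feat):
        pass
    else:
        raise SchemaError(
            f"matrix shape {mat.shape} matches neither (features={n_feat}, "
            f"barcodes={n_bar}) nor its transpose"
        )

    if symbol_column is None:
        symbol_column = 0 if features.shape[1] == 1 else 1
    symbols = features[symbol_column].tolist()

    var = pd.DataFrame(index=pd.Index(symbols, name="gene_symbol"))
    if features.shape[1] >= 2:
        var["gene_id"] = features[0].values
    if features.shape[1] >= 3:
        var["feature_type"] = features[2].values
    var["mito"] = var.index.str.startswith(mito_prefix)

    adata = ad.AnnData(
        X=mat.astype(np.int64),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=var,
    )
    return adata


def write_10x_mtx(adata: ad.AnnData, directory: str | Path) -> None:
    """Write an AnnData of counts as a plain-text 10x triple (genes x cells)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(adata.X).T.astype(np.int64)  # back to genes x cells
    scipy.io.mmwrite(str(directory / "matrix.mtx"), mat, field="integer")
    (directory / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    gene_ids = (
        adata.var["gene_id"] if "gene_id" in adata.var else pd.Series(adata.var_names, index=adata.var_names)
    )
    ftype = (
        adata.var["feature_type"]
        if "feature_type" in adata.var
        else pd.Series("Gene Expression", index=adata.var_names)
    )
    feat = pd.DataFrame({0: gene_ids.values, 1: adata.var_names, 2: ftype.values})
    feat.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)


def read_gene_positions(
    path: str | Path,
    *,
    karyotype: Sequence[str] = HUMAN_KARYOTYPE,
    on_unknown: str = "error",
) -> pd.DataFrame:
    """Read a BED-like TSV of gene positions (chrom, start, end, symbol).

    Coordinates are 0-based half-open (BED convention).  Rows on
    chromosomes outside ``karyotype`` raise (``on_unknown="error"``) or are
    dropped with a log message (``on_unknown="drop"``).

    Returns a DataFrame with columns ``gene_symbol, chromosome, start, end``
    in file order.
    """
    path = Path(path)
    if on_unknown not in ("error", "drop"):
        raise ValueError("on_unknown must be 'error' or 'drop'")
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 4:
        raise SchemaError(f"{path}: expected >=4 tab-separated columns, got {df.shape[1]}")
    out = pd.DataFrame(
        {
            "gene_symbol": df[3].astype(str),
            "chromosome": df[0].astype(str),
            "start": pd.to_numeric(df[1], errors="raise").astype(np.int64),
            "end": pd.to_numeric(df[2], errors="raise").astype(np.int64),
        }
    )
    bad = out.index[(out["end"] <= out["start"]) | (out["start"] < 0)]
    if len(bad):
        raise SchemaError(f"{path}: line {bad[0] + 1}: end must exceed start and start must be >= 0")
    dup = out["gene_symbol"][out["gene_symbol"].duplicated()].unique()
    if len(dup):
        raise SchemaError(f"{path}: duplicate gene symbols: {', '.join(dup[:10])}")
    unknown = ~out["chromosome"].isin(set(karyotype))
    if unknown.any():
        if on_unknown == "error":
            raise SchemaError(
                f"{path}: line {unknown.idxmax() + 1}: chromosome "
                f"{out.loc[unknown.idxmax(), 'chromosome']!r} not in karyotype"
            )
        logger.info("dropping %d rows on chromosomes outside karyotype", int(unknown.sum()))
        out = out[~unknown].reset_index(drop=True)
    return out


def write_gene_positions(positions: pd.DataFrame, path: str | Path) -> None:
    """Write a gene position table back to BED-like TSV."""
    positions[["chromosome", "start", "end", "gene_symbol"]].to_csv(
        path, sep="\t", header=False, index=False
    )


@dataclass
class BulkCohort:
    """A bulk expression cohort with overall-survival follow-up.

    Attributes
    ----------
    expression
        samples x genes matrix of (log-scale) expression, no missing values.
    survival_time
        Positive follow-up time per sample (months).
    event
        1 if death observed, 0 if censored.
    """

    expression: pd.DataFrame
    survival_time: pd.Series = field(repr=False)
    event: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.expression.index.duplicated().any():
            raise SchemaError("duplicate sample ids")
        if self.expression.isna().any().any():
            raise SchemaError("expression contains missing values")
        if not self.survival_time.index.equals(self.expression.index) or not self.event.index.equals(
            self.expression.index
        ):
            raise SchemaError("survival columns not aligned with expression samples")
        if (self.survival_time <= 0).any():
            raise SchemaError("survival_time must be positive")
        if not self.event.isin([0, 1]).all():
            raise SchemaError("event must be binary 0/1")
        self.event = self.event.astype(np.int64)

    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.index

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]


def read_bulk_cohort(
    path: str | Path,
    *,
    time_col: str = "time",
    event_col: str = "event",
    orientation: str = "samples_by_genes",
) -> BulkCohort:
    """Read a bulk cohort TSV with expression plus survival columns.

    ``orientation="genes_by_samples"`` reads the transposed layout (rows =
    genes plus ``time``/``event`` rows, columns = samples) and yields the
    same cohort as the direct layout.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "genes_by_samples":
        df = df.T
    elif orientation != "samples_by_genes":
        raise ValueError("orientation must be 'samples_by_genes' or 'genes_by_samples'")
    df.index.name = "sample_id"
    df.columns.name = None
    for col in (time_col, event_col):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    time = df[time_col].astype(float)
    event = pd.to_numeric(df[event_col], errors="raise")
    if not event.isin([0, 1]).all():
        raise SchemaError(f"{path}: event column contains values outside {{0,1}}")
    expr = df.drop(columns=[time_col, event_col]).astype(float)
    return BulkCohort(expression=expr, survival_time=time, event=event.astype(np.int64))


def write_bulk_cohort(
    cohort: BulkCohort,
    path: str | Path,
    *,
    time_col: str = "time",
    event_col: str = "event",
) -> None:
    """Write a bulk cohort to TSV (samples as rows)."""
    df = cohort.expression.copy()
    df[time_col] = cohort.survival_time
    df[event_col] = cohort.event
    df.to_csv(path, sep="\t", index_label="sample_id")


def gene_positions_from_var(adata: ad.AnnData) -> pd.DataFrame:
    """Extract a gene position table from AnnData ``var`` annotation."""
    missing = [c for c in ("chromosome", "start", "end") if c not in adata.var]
    if missing:
        raise SchemaError(f"var lacks position columns: {missing}")
    return pd.DataFrame(
        {
            "gene_symbol": adata.var_names,
            "chromosome": adata.var["chromosome"].values,
            "start": adata.var["start"].values.astype(np.int64),
            "end": adata.var["end"].values.astype(np.int64),
        }
    ).reset_index(drop=True)
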