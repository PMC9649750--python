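"""Shared fixtures: simulated studies reused across test modules.

Everything is generated at test time from the package's own simulators
with fixed seeds; nothing is read from disk.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from cervstrat import cna_infer, io_formats, qc_norm
from cervstrat.synthetic_data import (
    BulkSimConfig,
    CNAEvent,
    ScSimConfig,
    simulate_bulk,
    simulate_scrna,
)

CANONICAL_SEED = 1


@pytest.fixture(scope="session")
def sc_default():
    """Default five-type single-cell simulation (no CNA events)."""
    adata, truth = simulate_scrna(ScSimConfig(seed=CANONICAL_SEED))
    return SimpleNamespace(adata=adata, truth=truth)


@pytest.fixture(scope="session")
def sc_norm(sc_default):
    """QC-filtered, log-normalized version of the default simulation."""
    filtered, report = qc_norm.filter_cells(sc_default.adata)
    norm = qc_norm.lognormalize(filtered)
    return SimpleNamespace(norm=norm, report=report, truth=sc_default.truth)


@pytest.fixture(scope="session")
def cna_study():
    """Chromosome-scale CN=3 gain study: 500 tumor cells, ~500 diploid
    reference cells, 1,200 genes on 10 chromosomes, event = whole chr3."""
    cfg = ScSimConfig(
        n_genes=1200,
        n_chromosomes=10,
        n_cells_per_type={
            "epithelial_tumor": 500,
            "epithelial_normal": 100,
            "fibroblast": 400,
            "smc": 300,
            "tcell": 300,
        },
        cna_events=(CNAEvent("chr3", 0, 120, 3, "epithelial_tumor"),),
        seed=CANONICAL_SEED,
    )
    adata, truth = simulate_scrna(cfg)
    filtered, _ = qc_norm.filter_cells(adata)
    norm = qc_norm.lognormalize(filtered)
    positions = io_formats.gene_positions_from_var(norm)
    ref = (
        (norm.obs["condition"] == "nat") & (~norm.obs["cell_type"].str.startswith("epithelial"))
    ).values
    ordering = cna_infer.order_genes(norm, positions)
    track = cna_infer.smooth_expression(norm, ordering, ref)
    profile = cna_infer.call_bins(track)
    tumor = (norm.obs["cell_type"] == "epithelial_tumor").values
    in_event = (profile.bins["chromosome"] == "chr3").values
    return SimpleNamespace(
        config=cfg,
        norm=norm,
        truth=truth,
        positions=positions,
        reference=ref,
        tumor=tumor,
        ordering=ordering,
        track=track,
        profile=profile,
        in_event_bins=in_event,
    )


@pytest.fixture(scope="session")
def bulk_default():
    """Default four-subtype bulk cohort (strong effect, HRs 3/1.5/1/0.5)."""
    cohort, truth = simulate_bulk(BulkSimConfig(seed=CANONICAL_SEED))
    return SimpleNamespace(cohort=cohort, truth=truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(CANONICAL_SEED)
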