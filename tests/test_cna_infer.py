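"""Genomic ordering, smoothing oracle, integer calls and burden."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cervstrat import cna_infer
from cervstrat.cna_infer import (
    CNAProfile,
    SmoothedTrack,
    _centered_moving_average,
    _round_away_from_neutral,
)


def _norm_adata(X, gene_names=None):
    X = np.asarray(X, dtype=float)
    names = gene_names or [f"G{j}" for j in range(X.shape[1])]
    return ad.AnnData(
        X=sp.csr_matrix(X),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])]),
        var=pd.DataFrame(index=names),
    )


class TestOrderGenes:
    def _positions(self):
        return pd.DataFrame(
            {
                "gene_symbol": ["a", "b", "c", "d"],
                "chromosome": ["chr10", "chr2", "chr2", "chrBAD"],
                "start": [5, 100, 7, 1],
                "end": [6, 101, 8, 2],
            }
        )

    def test_karyotype_not_lexicographic(self):
        norm = _norm_adata(np.ones((2, 4)), gene_names=["a", "b", "c", "d"])
        ordering = cna_infer.order_genes(norm, self._positions(), window=2)
        # chr2 precedes chr10; within chr2, start order c(7) then b(100)
        assert ordering["gene_symbol"].tolist() == ["c", "b", "a"]

    def test_unknown_chromosome_dropped(self):
        norm = _norm_adata(np.ones((2, 4)), gene_names=["a", "b", "c", "d"])
        ordering = cna_infer.order_genes(norm, self._positions(), window=2)
        assert "d" not in ordering["gene_symbol"].tolist()

    def test_shuffled_input_same_ordering(self, cna_study):
        shuffled = cna_study.positions.sample(frac=1.0, random_state=0).reset_index(drop=True)
        again = cna_infer.order_genes(cna_study.norm, shuffled)
        assert again["gene_symbol"].tolist() == cna_study.ordering["gene_symbol"].tolist()

    def test_no_smoothable_chromosome_rejected(self):
        norm = _norm_adata(np.ones((2, 4)), gene_names=["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="cannot smooth"):
            cna_infer.order_genes(norm, self._positions(), window=50)


class TestSmoothing:
    def test_moving_average_matches_naive_oracle(self, rng):
        """Cumulative-sum implementation equals an explicit O(n*w) loop."""
        block = rng.normal(size=(5, 1000))
        for window in (1, 10, 100, 101):
            fast = _centered_moving_average(block, window)
            h = window // 2
            naive = np.empty_like(block)
            for i in range(block.shape[1]):
                lo, hi = max(i - h, 0), min(i + h + 1, block.shape[1])
                naive[:, i] = block[:, lo:hi].mean(axis=1)
            assert np.abs(fast - naive).max() < 1e-10

    def test_window_one_is_identity_up_to_centering(self, rng):
        """window=1 smoothing leaves the clipped relative values unchanged
        (tracks are reported after per-cell median-centering)."""
        X = rng.poisson(8, size=(40, 60)).astype(float)
        norm = _norm_adata(np.log1p(X))
        positions = pd.DataFrame(
            {"gene_symbol": [f"G{j}" for j in range(60)], "chromosome": "chr1",
             "start": np.arange(60) * 10, "end": np.arange(60) * 10 + 5}
        )
        ordering = cna_infer.order_genes(norm, positions, window=1)
        ref = np.ones(40, dtype=bool)
        track = cna_infer.smooth_expression(norm, ordering, ref, window=1)
        M = np.log1p(X)[:, [int(g[1:]) for g in ordering["gene_symbol"]]]
        R = M - M.mean(axis=0)
        sd = R.std()
        R = np.clip(R, -3 * sd, 3 * sd)
        expected = R - np.median(R, axis=1, keepdims=True)
        assert np.allclose(track.values, expected, atol=1e-12)

    def test_reference_cells_have_null_tracks(self, cna_study):
        ref_vals = cna_study.track.values[cna_study.reference]
        assert abs(ref_vals.mean()) < 0.05

    def test_translation_equivariance_after_centering(self, cna_study):
        """Adding a constant to one cell's expression leaves its centered
        track unchanged (the shift is absorbed by the median)."""
        norm = cna_study.norm.copy()
        X = np.asarray(norm.X.todense())
        X[0] += 0.5
        norm.X = sp.csr_matrix(X)
        track2 = cna_infer.smooth_expression(norm, cna_study.ordering, cna_study.reference)
        # clipping bounds change slightly if cell 0 is a reference cell; it is not
        assert not cna_study.reference[0]
        assert np.allclose(track2.values[0], cna_study.track.values[0], atol=0.02)

    def test_short_chromosome_warns(self, rng):
        X = np.log1p(rng.poisson(8, size=(20, 130)).astype(float))
        norm = _norm_adata(X)
        positions = pd.DataFrame(
            {"gene_symbol": [f"G{j}" for j in range(130)],
             "chromosome": ["chr1"] * 110 + ["chr2"] * 20,
             "start": list(np.arange(110) * 10) + list(np.arange(20) * 10),
             "end": list(np.arange(110) * 10 + 5) + list(np.arange(20) * 10 + 5)}
        )
        ordering = cna_infer.order_genes(norm, positions)
        with pytest.warns(UserWarning, match="chr2"):
            cna_infer.smooth_expression(norm, ordering, np.ones(20, dtype=bool))


class TestCallBins:
    @staticmethod
    def _track(values, chroms, window=100):
        n = values.shape[1]
        genes = pd.DataFrame(
            {"gene_symbol": [f"G{j}" for j in range(n)], "chromosome": chroms,
             "start": np.arange(n) * 10}
        )
        return SmoothedTrack(values=values, cell_ids=pd.Index(["c0"]), genes=genes, window=window)

    def test_ninety_genes_three_bins(self):
        track = self._track(np.zeros((1, 90)), ["chr1"] * 90)
        profile = cna_infer.call_bins(track)
        assert len(profile.bins) == 3
        assert (profile.bins["n_genes"] == 30).all()

    def test_neutral_track_all_diploid(self):
        track = self._track(np.zeros((1, 120)), ["chr1"] * 120)
        profile = cna_infer.call_bins(track)
        assert (profile.copy_number == 2).all()

    def test_small_trailing_remainder_merged(self):
        track = self._track(np.zeros((1, 65)), ["chr1"] * 65)
        profile = cna_infer.call_bins(track)  # 30 + 35 (trailing 5 merged)
        assert profile.bins["n_genes"].tolist() == [30, 35]

    def test_rounding_half_away_from_neutral(self):
        vals = np.array([2.5, 1.5, 2.0, 3.5, 0.5, 2.49, 1.51])
        out = _round_away_from_neutral(vals)
        assert out.tolist() == [3.0, 1.0, 2.0, 4.0, 0.0, 2.0, 2.0]

    def test_log2_dosage_mapping(self):
        """A natural-log track at ln(1.5) maps to CN 3; at ln(0.5) to CN 1."""
        vals = np.full((1, 60), np.log(1.5))
        vals[0, 30:] = np.log(0.5)
        profile = cna_infer.call_bins(self._track(vals, ["chr1"] * 30 + ["chr2"] * 30))
        assert profile.copy_number[0].tolist() == [3, 1]

    def test_gene_permutation_within_bin_invariant(self, rng):
        vals = rng.normal(0, 0.2, size=(3, 60))
        track = self._track(vals.copy(), ["chr1"] * 60)
        p1 = cna_infer.call_bins(track)
        perm = np.concatenate([rng.permutation(30), 30 + rng.permutation(30)])
        track2 = self._track(vals[:, perm], ["chr1"] * 60)
        p2 = cna_infer.call_bins(track2)
        assert np.array_equal(p1.copy_number, p2.copy_number)

    def test_event_recovery_on_simulated_gain(self, cna_study):
        cn = cna_study.profile.copy_number
        tum, in_ev = cna_study.tumor, cna_study.in_event_bins
        assert (cn[np.ix_(tum, in_ev)] == 3).mean() >= 0.9
        assert (cn[np.ix_(tum, ~in_ev)] == 2).mean() >= 0.95

    def test_monotone_dosage_response(self):
        """Mean inferred CN is nondecreasing in true CN over {1, 2, 3, 4}."""
        from cervstrat import io_formats, qc_norm
        from cervstrat.synthetic_data import CNAEvent, ScSimConfig, simulate_scrna

        cfg = ScSimConfig(
            n_genes=1200, n_chromosomes=10,
            n_cells_per_type={"epithelial_tumor": 200, "epithelial_normal": 50,
                              "fibroblast": 150, "smc": 100, "tcell": 100},
            cna_events=(
                CNAEvent("chr2", 0, 120, 1, "epithelial_tumor"),
                CNAEvent("chr3", 0, 120, 3, "epithelial_tumor"),
                CNAEvent("chr4", 0, 120, 4, "epithelial_tumor"),
            ),
            seed=2,
        )
        adata, truth = simulate_scrna(cfg)
        filtered, _ = qc_norm.filter_cells(adata)
        norm = qc_norm.lognormalize(filtered)
        ref = ((norm.obs["condition"] == "nat")
               & (~norm.obs["cell_type"].str.startswith("epithelial"))).values
        _, profile = cna_infer.infer_cna(
            norm, io_formats.gene_positions_from_var(norm), ref
        )
        tum = (norm.obs["cell_type"] == "epithelial_tumor").values
        means = []
        for chrom in ("chr2", "chr1", "chr3", "chr4"):  # true CN 1, 2, 3, 4
            mask = (profile.bins["chromosome"] == chrom).values
            means.append(profile.copy_number[np.ix_(tum, mask)].mean())
        assert all(a < b for a, b in zip(means, means[1:]))


class TestBurden:
    def test_neutral_profile_zero_burden(self):
        profile = CNAProfile(
            copy_number=np.full((3, 8), 2), bins=pd.DataFrame({"chromosome": ["chr1"] * 8}),
            cell_ids=pd.Index(["a", "b", "c"]),
        )
        assert (cna_infer.cna_burden(profile) == 0).all()

    def test_quarter_gain_burden(self):
        cn = np.full((1, 8), 2)
        cn[0, :2] = 3  # CN 3 over exactly 25% of bins
        profile = CNAProfile(copy_number=cn, bins=pd.DataFrame({"chromosome": ["chr1"] * 8}),
                             cell_ids=pd.Index(["a"]))
        assert cna_infer.cna_burden(profile).iloc[0] == pytest.approx(0.25)

    def test_subclone_burden_exceeds_reference(self, cna_study):
        from scipy.stats import mannwhitneyu

        burden = cna_study.profile.burden()
        p = mannwhitneyu(
            burden[cna_study.tumor], burden[cna_study.reference], alternative="greater"
        ).pvalue
        assert p < 0.01


class TestCompareClusters:
    def test_planted_high_burden_cluster_ranks_first(self, cna_study):
        clusters = cna_study.norm.obs["cell_type"].values
        summary, pairwise = cna_infer.compare_cluster_cna(cna_study.profile, clusters)
        top = summary.sort_values("mean_burden", ascending=False).iloc[0]
        assert top["cluster"] == "epithelial_tumor"
        sig = pairwise[
            (pairwise["cluster_a"] == "epithelial_tumor") | (pairwise["cluster_b"] == "epithelial_tumor")
        ]
        assert (sig["adj_p"] < 0.01).all()

    def test_all_neutral_clusters_tie(self):
        profile = CNAProfile(
            copy_number=np.full((6, 5), 2), bins=pd.DataFrame({"chromosome": ["chr1"] * 5}),
            cell_ids=pd.Index([f"c{i}" for i in range(6)]),
        )
        summary, pairwise = cna_infer.compare_cluster_cna(profile, ["a"] * 3 + ["b"] * 3)
        assert summary["mean_burden"].nunique() == 1
        assert (pairwise["p_value"] == 1.0).all() or pairwise["p_value"].isna().all()

    def test_single_cluster_no_tests(self):
        profile = CNAProfile(
            copy_number=np.full((4, 5), 2), bins=pd.DataFrame({"chromosome": ["chr1"] * 5}),
            cell_ids=pd.Index([f"c{i}" for i in range(4)]),
        )
        summary, pairwise = cna_infer.compare_cluster_cna(profile, ["a"] * 4)
        assert len(summary) == 1
        assert pairwise.empty
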