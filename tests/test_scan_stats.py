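"""Differentiation-scan statistics: FST, CMH, BH, tracks, peaks, annotation."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from domescan import study_design
from domescan.scan_stats import (
    RollingTrack,
    bh_adjust,
    cmh_scan,
    compute_scan,
    find_peaks,
    genes_near,
    pairwise_fst,
    pool_pi,
    read_gff3_genes,
    rolling_average,
)


class TestPoolPi:
    def test_formula_value(self):
        assert pool_pi(50, 50) == pytest.approx(0.5 * 100 / 99)

    def test_monomorphic_is_zero(self):
        assert pool_pi(100, 0) == 0.0

    def test_maximal_at_half(self):
        depth = 100
        values = [pool_pi(k, depth - k) for k in range(0, depth + 1, 5)]
        assert max(values) == pool_pi(50, 50)

    def test_undefined_below_depth_two(self):
        assert np.isnan(pool_pi(1, 0))


class TestPairwiseFst:
    def test_identical_pools_near_zero(self):
        """Identical count vectors give FST ~ 0: exactly zero up to the
        finite-depth C/(C-1) correction, whose residual is O(1/C) and
        negative (each pool's corrected pi slightly exceeds the total's)."""
        val = pairwise_fst(40, 10, 40, 10)
        assert -0.02 < val <= 0.0
        # residual vanishes as depth grows
        assert abs(pairwise_fst(4000, 1000, 4000, 1000)) < 2e-4

    def test_fixed_difference_is_one(self):
        assert pairwise_fst(100, 0, 0, 100) == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        # pi_T = 0.50505, mean within-pi = 0.32653 -> 0.3535
        assert pairwise_fst(40, 10, 10, 40) == pytest.approx(0.3535, abs=2e-4)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 80, size=4)
            if (a + b) < 2 or (c + d) < 2:
                continue
            assert pairwise_fst(a, b, c, d) == pytest.approx(pairwise_fst(c, d, a, b), nan_ok=True)

    def test_monomorphic_combined_masked(self):
        assert np.isnan(pairwise_fst(50, 0, 30, 0))


class TestCmh:
    def test_null_tables_give_zero(self):
        a = b = c = d = np.full(3, 10.0)
        stat, p = cmh_scan(a, b, c, d, continuity=False)
        assert stat == 0.0 and p == 1.0

    def test_single_stratum_relates_to_yates_chisq(self):
        """At K=1 the CMH statistic equals (N-1)/N times the continuity-
        corrected Pearson chi-square."""
        table = np.array([[20, 5], [10, 15]])
        stat, _ = cmh_scan([20], [5], [10], [15], continuity=True)
        chi2_yates = st.chi2_contingency(table, correction=True)[0]
        n = table.sum()
        assert stat == pytest.approx((n - 1) / n * chi2_yates, rel=1e-10)

    def test_matches_statsmodels_stratified_table(self):
        from statsmodels.stats.contingency_tables import StratifiedTable

        rng = np.random.default_rng(2)
        for _ in range(25):
            k = rng.integers(1, 5)
            tables = rng.integers(1, 20, size=(2, 2, k))
            ours, _ = cmh_scan(tables[0, 0], tables[0, 1], tables[1, 0], tables[1, 1])
            ref = StratifiedTable(tables.astype(float)).test_null_odds(correction=True).statistic
            assert ours == pytest.approx(ref, abs=1e-8)

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning, match="zero variance"):
            _, p = cmh_scan([0], [0], [5], [5])
        assert p == 1.0


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]).tolist() == [0.37]

    def test_step_up_hand_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestRollingAverage:
    def test_constant_series(self):
        t = rolling_average(np.arange(10), np.full(10, 2.5), window=4)
        assert np.allclose(t.values, 2.5)

    def test_window_one_is_identity(self):
        vals = np.array([1.0, 3.0, 2.0])
        t = rolling_average(np.arange(3), vals, window=1)
        assert np.array_equal(t.values, vals)

    def test_centred_hand_example(self):
        t = rolling_average(np.arange(5), np.array([0, 0, 9, 0, 0.0]), window=3)
        assert t.values[2] == pytest.approx(3.0)

    def test_masked_values_skipped(self):
        t = rolling_average(np.arange(3), np.array([1.0, np.nan, 3.0]), window=3)
        assert t.values[1] == pytest.approx(2.0)

    def test_window_longer_than_series_collapses_with_warning(self):
        with pytest.warns(UserWarning, match="global mean"):
            t = rolling_average(np.arange(4), np.array([1, 2, 3, 4.0]), window=10)
        assert t.values.tolist() == [2.5]

    def test_window_mean_bounded_by_member_range(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=200)
        t = rolling_average(np.arange(200), vals, window=21)
        assert t.values.min() >= vals.min() - 1e-12
        assert t.values.max() <= vals.max() + 1e-12


class TestFindPeaks:
    def test_single_snp_is_the_peak(self):
        track = rolling_average(np.array([42]), np.array([0.3]), window=1)
        rep = find_peaks(track, np.array([42]), np.array([0.3]), snp_adj_p=np.array([0.004]))
        assert rep.peak_pos == 42
        assert rep.best_snp_pos == 42
        assert rep.stars == "**"

    def test_all_masked_track_empty_report(self):
        track = RollingTrack(positions=np.array([1, 2]), values=np.array([np.nan, np.nan]), window=1)
        rep = find_peaks(track, np.array([1, 2]), np.array([np.nan, np.nan]))
        assert rep.empty


class TestGenesNear:
    def test_six6_chromosome_peak_recovers_published_genes(self):
        """The reported peak on the seabass six6 chromosome lies within
        50 kbp of mboat2, kidin220 and id2."""
        genes = read_gff3_genes(study_design.peak_gene_gff3("seabass", "HG916829.1"))
        hit = genes_near(12_321_585, genes, flank=50_000)
        assert sorted(hit["name"]) == ["id2", "kidin220", "mboat2"]

    def test_vgll3_chromosome_peak_recovers_all_ten_genes(self):
        genes = read_gff3_genes(study_design.peak_gene_gff3("seabass", "HG916832.1"))
        hit = genes_near(16_286_816, genes, flank=50_000)
        assert len(hit) == 10
        assert "rpgr" in set(hit["name"])  # ends 42,287 bp from the peak

    def test_empty_annotation(self):
        assert genes_near(100, pd.DataFrame()).empty

    def test_flank_boundary_inclusive(self):
        genes = pd.DataFrame(
            [{"chrom": "c", "start": 150, "end": 200, "strand": "+", "gene_id": "g", "name": "g"}]
        )
        assert len(genes_near(100, genes, flank=50)) == 1
        assert genes_near(100, genes, flank=49).empty


class TestComputeScan:
    def test_null_scan_statistics_behave(self, small_poolseq_sim):
        from domescan.poolseq_core import call_biallelic, merge_replicates

        sim = small_poolseq_sim
        pools = {
            pid: merge_replicates([df for (p, _), df in sim.pileups.items() if p == pid])
            for pid in {p for p, _ in sim.pileups}
        }
        snps = call_biallelic(pools)
        stats = compute_scan(snps, sim.manifest)
        assert len(stats) == len(snps)
        for col in ("fisher_p", "cmh_p", "fisher_q", "cmh_q"):
            v = stats[col].to_numpy()
            assert ((v >= 0) & (v <= 1)).all()
        assert (stats["fisher_q"] >= stats["fisher_p"] - 1e-12).all()
        fst = stats["combined_fst"].dropna()
        assert (fst <= 1.0 + 1e-9).all()
        # signal region injected at 0.9-1.1 Mb must stand out
        in_reg = (stats["pos"] >= 900_000) & (stats["pos"] <= 1_100_000)
        assert stats.loc[in_reg, "combined_fst"].mean() > stats.loc[~in_reg, "combined_fst"].mean()

    def test_manifest_pairing_matches_index_pairing_when_aligned(self, small_poolseq_sim):
        from domescan.poolseq_core import call_biallelic, merge_replicates

        sim = small_poolseq_sim
        pools = {
            pid: merge_replicates([df for (p, _), df in sim.pileups.items() if p == pid])
            for pid in {p for p, _ in sim.pileups}
        }
        snps = call_biallelic(pools)
        man = sim.manifest.copy()
        farmed = sorted(man.loc[man["origin"] == "farmed", "pool_id"])
        wild = sorted(man.loc[man["origin"] == "wild", "pool_id"])
        stratum = {p: i for i, p in enumerate(farmed)} | {p: i for i, p in enumerate(wild)}
        man["stratum"] = man["pool_id"].map(stratum)
        a = compute_scan(snps, sim.manifest, pairing="index")
        b = compute_scan(snps, man, pairing="manifest")
        pd.testing.assert_series_equal(a["cmh_stat"], b["cmh_stat"])

    def test_missing_pool_in_manifest_rejected(self, small_poolseq_sim):
        from domescan.poolseq_core import call_biallelic, merge_replicates

        sim = small_poolseq_sim
        pools = {
            pid: merge_replicates([df for (p, _), df in sim.pileups.items() if p == pid])
            for pid in {p for p, _ in sim.pileups}
        }
        snps = call_biallelic(pools)
        with pytest.raises(ValueError, match="missing from manifest"):
            compute_scan(snps, sim.manifest.iloc[:2])
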