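"""Rank transform, windowed P-value combination, BH FDR, clustering, QTL calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressgate.datatypes import GeneticMap, GenotypeTable, InvalidArgumentError
from stressgate.simulate import make_map, simulate_phenotypes, simulate_ril_genotypes
from stressgate.datatypes import QTLSpec, TrueArchitecture
from stressgate.scan import scan_interaction
from stressgate.smooth import (
    SmoothingConfig,
    add_smoothing,
    bh_fdr,
    call_qtl,
    cluster_markers,
    fractional_ranks,
    smooth_pvalues,
)


class TestFractionalRanks:
    def test_definition_n3(self):
        assert list(fractional_ranks([0.2, 0.01, 0.99])) == [2 / 4, 1 / 4, 3 / 4]

    def test_all_ties_map_to_half(self):
        assert np.allclose(fractional_ranks([0.3] * 5), 0.5)

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fractional_ranks([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=30, unique=True))
    def test_order_preserving(self, pvals):
        ranks = fractional_ranks(pvals)
        order_in = np.argsort(pvals)
        order_out = np.argsort(ranks)
        assert list(order_in) == list(order_out)


class TestSmoothing:
    def test_simes_hand_example(self):
        # window (0.01, 0.04, 0.90): min(3*0.01/1, 3*0.04/2, 3*0.90/3) = 0.03
        out = smooth_pvalues([0.01, 0.04, 0.90], [1, 1, 1], SmoothingConfig(window=3))
        assert out[1] == pytest.approx(0.03)

    def test_window_one_is_identity(self):
        p = [0.3, 0.01, 0.8, 0.5]
        out = smooth_pvalues(p, [1, 1, 2, 2], SmoothingConfig(window=1))
        assert np.allclose(out, p)

    @pytest.mark.parametrize("method", ["simes", "fisher"])
    def test_all_ones_combine_to_one(self, method):
        out = smooth_pvalues([1.0] * 5, [1] * 5, SmoothingConfig(window=3, method=method))
        assert np.allclose(out, 1.0)

    @pytest.mark.parametrize("method", ["simes", "fisher"])
    def test_values_stay_in_unit_interval(self, method):
        rng = np.random.default_rng(85)
        p = rng.uniform(0, 1, 40)
        out = smooth_pvalues(p, [1] * 20 + [2] * 20, SmoothingConfig(window=3, method=method))
        assert ((out >= 0) & (out <= 1)).all()

    def test_simes_at_least_window_minimum(self):
        rng = np.random.default_rng(87)
        p = rng.uniform(0, 1, 30)
        out = smooth_pvalues(p, [1] * 30, SmoothingConfig(window=5))
        for i in range(30):
            lo, hi = max(0, i - 2), min(30, i + 3)
            assert out[i] >= p[lo:hi].min() - 1e-12

    def test_windows_respect_chromosome_boundaries(self):
        p = [0.9, 0.9, 1e-6, 0.9, 0.9]
        chrom = [1, 1, 1, 2, 2]
        out = smooth_pvalues(p, chrom, SmoothingConfig(window=3))
        # chromosome-2 markers never see the chromosome-1 signal
        assert out[3] > 0.1 and out[4] > 0.1

    def test_unsorted_chromosomes_rejected(self):
        with pytest.raises(InvalidArgumentError):
            smooth_pvalues([0.5, 0.5, 0.5], [1, 2, 1], SmoothingConfig())

    def test_even_window_rejected(self):
        with pytest.raises(InvalidArgumentError):
            SmoothingConfig(window=4)


class TestBhFdr:
    def test_stepup_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_value_passthrough(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(89)
        p = rng.uniform(0, 1, 100)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_global_null_rarely_significant(self):
        rng = np.random.default_rng(91)
        hits = 0
        for _ in range(50):
            q = bh_fdr(rng.uniform(0, 1, 2000))
            hits += (q < 0.05).sum()
        assert hits / (50 * 2000) < 0.005


class TestClustering:
    def test_identical_adjacent_markers_merge(self, small_map, ril_population):
        calls = ril_population.calls.copy()
        m = small_map.table.iloc[0]["marker"]
        m2 = small_map.table.iloc[1]["marker"]
        calls[m2] = calls[m]
        geno = GenotypeTable(calls=calls, family=ril_population.family)
        clusters = cluster_markers(geno, small_map, cluster_r2=0.9)
        first = clusters[0]
        assert set([m, m2]) <= set(first["members"])

    def test_threshold_one_with_distinct_columns_no_merging(self, small_map, ril_population):
        clusters = cluster_markers(ril_population, small_map, cluster_r2=1.0)
        assert all(len(c["members"]) == 1 for c in clusters)

    def test_zero_distance_markers_cluster(self):
        gmap = GeneticMap(pd.DataFrame({
            "marker": ["a", "b", "c"],
            "chrom": [1, 1, 1],
            "pos_cM": [0.0, 0.0, 80.0],
            "bin": ["1.00", "1.00", "1.05"],
        }))
        geno = simulate_ril_genotypes(gmap, 2000, 0, seed=93)
        clusters = cluster_markers(geno, gmap, cluster_r2=0.99)
        assert clusters[0]["members"] == ["a", "b"]


class TestCallQtl:
    def test_no_marker_below_threshold(self, small_map):
        q = np.full(small_map.n_markers, 0.8)
        assert len(call_qtl(q, small_map, 0.05)) == 0

    def test_single_marker_zero_width_interval(self, small_map):
        q = np.full(small_map.n_markers, 0.8)
        q[5] = 0.001
        intervals = call_qtl(q, small_map, 0.05)
        assert len(intervals) == 1
        row = intervals.iloc[0]
        assert row["start_cM"] == row["end_cM"]
        assert row["peak_marker"] == small_map.table.iloc[5]["marker"]

    def test_run_merged_within_chromosome(self, small_map):
        q = np.full(small_map.n_markers, 0.8)
        q[2:5] = [0.01, 0.001, 0.02]
        intervals = call_qtl(q, small_map, 0.05)
        assert len(intervals) == 1
        assert intervals.iloc[0]["peak_marker"] == small_map.table.iloc[3]["marker"]

    def test_chromosome_order_permutation_invariance(self, small_map, ril_population, one_qtl_arch):
        pheno = simulate_phenotypes(ril_population, one_qtl_arch, n_blocks=2, seed=95)
        scan = scan_interaction(ril_population, pheno, "trait", gmap=small_map)
        cfg = SmoothingConfig(window=3)
        res = add_smoothing(scan, small_map, cfg)
        # permute chromosome identities (relabel 1<->4, 2<->3) and re-run
        remap = {1: 4, 2: 3, 3: 2, 4: 1}
        tab = small_map.table.copy()
        tab["chrom"] = tab["chrom"].map(remap)
        gmap2 = GeneticMap(tab)
        scan2 = scan_interaction(ril_population, pheno, "trait", gmap=gmap2)
        res2 = add_smoothing(scan2, gmap2, cfg)
        merged = res.table[["marker", "smoothed_p"]].merge(
            res2.table[["marker", "smoothed_p"]], on="marker", suffixes=("_a", "_b")
        )
        assert np.allclose(merged["smoothed_p_a"], merged["smoothed_p_b"], equal_nan=True)


@pytest.fixture(scope="module")
def dense_scan_inputs():
    gmap = make_map(2, 25, 120.0, seed=97)
    geno = simulate_ril_genotypes(gmap, 200, 4, seed=99)
    marker = gmap.table.iloc[12]["marker"]
    arch = TrueArchitecture(
        qtl=(QTLSpec(marker=marker, gate="attenuator_UV", effect_uv=0.35),),
        block_sd=0.3, residual_sd=1.0,
    )
    return gmap, geno, arch, marker


class TestSmoothingTradeoff:
    """Windowed combination raises power at flanked QTL but widens intervals."""

    def test_wider_windows_widen_intervals_and_keep_power(self, dense_scan_inputs):
        gmap, geno, arch, marker = dense_scan_inputs
        pos = gmap.positions_of([marker]).iloc[0]
        widths = {1: [], 5: []}
        detections = {1: 0, 5: 0}
        n_sims = 12
        for i in range(n_sims):
            pheno = simulate_phenotypes(geno, arch, n_blocks=2, seed=7000 + i)
            scan = scan_interaction(geno, pheno, "trait", gmap=gmap)
            for w in (1, 5):
                res = add_smoothing(scan, gmap, SmoothingConfig(window=w))
                intervals = call_qtl(
                    pd.Series(res.table["q_value"].to_numpy(), index=res.table["marker"]),
                    gmap, 0.05,
                )
                near = intervals[
                    (intervals["chromosome"] == pos["chrom"])
                    & (intervals["start_cM"] - 10 <= pos["pos_cM"])
                    & (intervals["end_cM"] + 10 >= pos["pos_cM"])
                ]
                if len(near):
                    detections[w] += 1
                    widths[w].append(float((near["end_cM"] - near["start_cM"]).max()))
        assert detections[5] >= detections[1]
        if widths[1] and widths[5]:
            assert np.mean(widths[5]) >= np.mean(widths[1])

    def test_five_qtl_recovery_through_pipeline(self):
        gmap = make_map(5, 30, 145.0, seed=101)
        geno = simulate_ril_genotypes(gmap, 250, 0, seed=103)
        markers = [gmap.table[gmap.table["chrom"] == c].iloc[14]["marker"] for c in range(1, 6)]
        qtl = tuple(
            QTLSpec(marker=m, gate="independent", effect_uv=a, effect_drought=a)
            for m, a in zip(markers, (0.8, 0.6, 0.5, 0.4, 0.35))
        )
        arch = TrueArchitecture(qtl=qtl, block_sd=0.3, residual_sd=1.0)
        recovered = 0
        n_sims = 5
        for i in range(n_sims):
            pheno = simulate_phenotypes(geno, arch, n_blocks=2, seed=8000 + i)
            scan = scan_interaction(geno, pheno, "trait", gmap=gmap)
            res = add_smoothing(scan, gmap, SmoothingConfig(window=3))
            intervals = call_qtl(
                pd.Series(res.table["q_value"].to_numpy(), index=res.table["marker"]),
                gmap, 0.05,
            )
            hits = 0
            for m in markers:
                p = gmap.positions_of([m]).iloc[0]
                near = intervals[
                    (intervals["chromosome"] == p["chrom"])
                    & (intervals["start_cM"] - 10 <= p["pos_cM"])
                    & (intervals["end_cM"] + 10 >= p["pos_cM"])
                ]
                hits += bool(len(near))
            recovered += hits >= 4
        assert recovered >= 4  # >= 4/5 QTL found in >= 4/5 simulations
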