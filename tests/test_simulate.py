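"""Synthetic-data generator: maps, RIL/NAM genotypes, gate phenotypes, effects."""

import numpy as np
import pandas as pd
import pytest

from stressgate.datatypes import (
    ENVIRONMENTS,
    GeneticMap,
    InvalidArgumentError,
    QTLSpec,
    TrueArchitecture,
    haldane_r,
)
from stressgate.simulate import (
    effects_for_variance_target,
    make_map,
    simulate_nam_genotypes,
    simulate_phenotypes,
    simulate_ril_genotypes,
)


class TestMakeMap:
    def test_even_spacing_endpoints(self):
        gmap = make_map(1, 2, 100.0)
        assert list(gmap.table["pos_cM"]) == [0.0, 100.0]

    def test_deterministic_given_seed(self):
        a = make_map(10, 50, 150.0, seed=1, spacing="random")
        b = make_map(10, 50, 150.0, seed=1, spacing="random")
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_random_positions_sorted_within_chromosome(self):
        gmap = make_map(10, 50, 150.0, seed=3, spacing="random")
        for _, sub in gmap.table.groupby("chrom"):
            assert sub["pos_cM"].is_monotonic_increasing

    def test_bin_labels_are_chromosome_deciles(self):
        gmap = make_map(2, 11, 100.0)
        row = gmap.table[gmap.table["pos_cM"] == 50.0].iloc[0]
        assert row["bin"] == f"{row['chrom']}.05"

    @pytest.mark.parametrize("args", [(0, 5, 100.0), (5, 0, 100.0), (5, 5, -1.0)])
    def test_invalid_arguments(self, args):
        with pytest.raises(InvalidArgumentError):
            make_map(*args)


class TestRilGenotypes:
    def test_lines_fully_homozygous_codes(self, small_map):
        geno = simulate_ril_genotypes(small_map, 40, 0, seed=5)
        assert set(np.unique(geno.calls.to_numpy())) <= {"A", "B"}

    def test_allele_frequency_near_half(self, small_map):
        geno = simulate_ril_genotypes(small_map, 600, 0, seed=7)
        freq = geno.allele_frequency("B")
        se = np.sqrt(0.25 / 600)
        assert (np.abs(freq - 0.5) < 3 * se + 1e-12).mean() > 0.95
        assert np.abs(freq.mean() - 0.5) < 3 * se

    def test_zero_distance_markers_identical(self):
        gmap = GeneticMap(
            pd.DataFrame(
                {
                    "marker": ["a", "b"],
                    "chrom": [1, 1],
                    "pos_cM": [10.0, 10.0],
                    "bin": ["1.00", "1.00"],
                }
            )
        )
        geno = simulate_ril_genotypes(gmap, 300, 0, seed=9)
        assert (geno.calls["a"] == geno.calls["b"]).all()

    def test_deterministic_given_seed(self, small_map):
        a = simulate_ril_genotypes(small_map, 30, 2, seed=13)
        b = simulate_ril_genotypes(small_map, 30, 2, seed=13)
        pd.testing.assert_frame_equal(a.calls, b.calls)

    def test_recombinant_fraction_matches_selfing_limit(self, two_marker_map):
        # Haldane r over 50 cM; selfed-RIL fixation gives R = 2r/(1+2r).
        geno = simulate_ril_genotypes(two_marker_map, 2000, 0, seed=17)
        s = geno.signs().to_numpy()
        observed = float((s[:, 0] != s[:, 1]).mean())
        r = haldane_r(50.0)
        expected = 2 * r / (1 + 2 * r)
        se = np.sqrt(expected * (1 - expected) / 2000)
        assert abs(observed - expected) < 3 * se

    def test_recombination_monotone_in_distance(self):
        fractions = []
        for d in (5.0, 20.0, 50.0, 90.0):
            gmap = GeneticMap(
                pd.DataFrame(
                    {
                        "marker": ["a", "b"],
                        "chrom": [1, 1],
                        "pos_cM": [0.0, d],
                        "bin": ["1.00", "1.01"],
                    }
                )
            )
            geno = simulate_ril_genotypes(gmap, 2000, 0, seed=19)
            s = geno.signs().to_numpy()
            fractions.append(float((s[:, 0] != s[:, 1]).mean()))
        assert all(a < b for a, b in zip(fractions, fractions[1:]))

    def test_intermating_increases_recombinant_fraction(self, two_marker_map):
        def frac(n_im, seed):
            g = simulate_ril_genotypes(two_marker_map, 2000, n_im, seed=seed)
            s = g.signs().to_numpy()
            return float((s[:, 0] != s[:, 1]).mean())

        assert frac(4, 21) > frac(0, 21)

    def test_empty_map_rejected(self):
        empty = GeneticMap(pd.DataFrame(columns=["marker", "chrom", "pos_cM", "bin"]))
        with pytest.raises(InvalidArgumentError):
            simulate_ril_genotypes(empty, 10, 0, seed=1)


class TestNamGenotypes:
    def test_five_families_of_fifty(self, small_map):
        geno = simulate_nam_genotypes(small_map, 5, 50, seed=31)
        assert geno.n_lines == 250
        assert len(geno.families) == 5

    def test_single_family_reduces_to_biparental(self, small_map):
        geno = simulate_nam_genotypes(small_map, 1, 30, seed=33)
        assert len(geno.families) == 1
        assert set(np.unique(geno.calls.to_numpy())) <= {"A", "B"}

    def test_per_family_allele_frequency_half(self, small_map):
        geno = simulate_nam_genotypes(small_map, 3, 400, seed=35)
        se = np.sqrt(0.25 / 400)
        for fam in geno.families:
            sub = geno.calls[geno.family == fam]
            freq = (sub == "B").mean()
            assert np.abs(freq.mean() - 0.5) < 3 * se


class TestGatePhenotypes:
    def _noiseless(self, geno, qtl, n_blocks=2):
        arch = TrueArchitecture(qtl=qtl, trait_mean=5.0, block_sd=0.0, residual_sd=0.0)
        return simulate_phenotypes(geno, arch, n_blocks=n_blocks, seed=41)

    def _class_diff(self, geno, pheno, marker, env):
        d = pheno.data[pheno.data["environment"] == env].copy()
        alleles = d["line_id"].map(geno.calls[marker])
        return d.loc[alleles == "A", "value"].mean() - d.loc[alleles == "B", "value"].mean()

    @pytest.mark.parametrize(
        "gate,kw,env_expect",
        [
            ("attenuator_UV", dict(effect_uv=0.7), {"UV": 1.4, "combined": 0.0, "drought": 0.0}),
            ("attenuator_drought", dict(effect_drought=0.7), {"drought": 1.4, "combined": 0.0}),
            ("XOR", dict(effect_uv=0.7, effect_drought=-0.7), {"UV": 1.4, "drought": -1.4, "combined": 0.0}),
            ("AND_gate", dict(effect_combined=0.7), {"UV": 0.0, "drought": 0.0, "combined": 1.4}),
            ("OR_gate", dict(effect_uv=0.5, effect_drought=0.3), {"UV": 1.0, "drought": 0.6, "combined": 1.6}),
            ("independent", dict(effect_uv=0.5, effect_drought=0.3), {"combined": 1.6}),
        ],
    )
    def test_gate_class_differences_noiseless(self, ril_population, gate, kw, env_expect):
        marker = ril_population.marker_names[2]
        pheno = self._noiseless(ril_population, (QTLSpec(marker=marker, gate=gate, **kw),))
        for env, expect in env_expect.items():
            diff = self._class_diff(ril_population, pheno, marker, env)
            assert diff == pytest.approx(expect, abs=1e-10)

    def test_all_gates_silent_in_control(self, ril_population):
        marker = ril_population.marker_names[0]
        for gate, kw in [
            ("independent", dict(effect_uv=1.0)),
            ("AND_gate", dict(effect_combined=1.0)),
            ("OR_gate", dict(effect_uv=1.0, effect_drought=1.0)),
            ("XOR", dict(effect_uv=1.0, effect_drought=-1.0)),
            ("attenuator_UV", dict(effect_uv=1.0)),
            ("attenuator_drought", dict(effect_drought=1.0)),
        ]:
            pheno = self._noiseless(ril_population, (QTLSpec(marker=marker, gate=gate, **kw),))
            assert self._class_diff(ril_population, pheno, marker, "control") == pytest.approx(0.0, abs=1e-10)

    def test_unknown_gate_rejected(self):
        with pytest.raises(InvalidArgumentError):
            QTLSpec(marker="m", gate="NAND")

    def test_reproducible_bit_exact(self, ril_population, one_qtl_arch):
        a = simulate_phenotypes(ril_population, one_qtl_arch, n_blocks=3, seed=43)
        b = simulate_phenotypes(ril_population, one_qtl_arch, n_blocks=3, seed=43)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_variance_fraction_hits_target(self, small_map):
        # one independent QTL aimed at 50% of UV-environment variance
        geno = simulate_ril_genotypes(small_map, 250, 0, seed=47)
        a = effects_for_variance_target([0.5], 1.0)[0]
        marker = small_map.table.iloc[10]["marker"]
        arch = TrueArchitecture(
            qtl=(QTLSpec(marker=marker, gate="independent", effect_uv=float(a)),),
            block_sd=0.0,
            residual_sd=1.0,
        )
        pheno = simulate_phenotypes(geno, arch, n_blocks=4, seed=49)
        d = pheno.data[pheno.data["environment"] == "UV"]
        genetic = geno.signs()[marker] * a
        # genetic share of single-observation phenotypic variance
        obs_share = genetic.var() / d["value"].var()
        assert abs(obs_share - 0.5) < 0.05


class TestEffectSizes:
    def test_single_target_closed_form(self):
        assert effects_for_variance_target([0.5], 1.0)[0] == pytest.approx(1.0)

    def test_zero_target_zero_effect(self):
        assert effects_for_variance_target([0.0], 2.0)[0] == 0.0

    def test_infeasible_joint_targets_rejected(self):
        with pytest.raises(InvalidArgumentError):
            effects_for_variance_target([0.6, 0.5], 1.0)

    def test_marginal_mode_allows_large_totals(self):
        a = effects_for_variance_target([0.5, 0.5], 1.0, mode="marginal")
        assert np.allclose(a, [1.0, 1.0])

    def test_joint_targets_realized_in_large_population(self):
        targets = np.linspace(0.5, 0.08, 5) * 0.5  # jointly feasible (sum 0.725)
        a = effects_for_variance_target(targets, 1.0)
        rng = np.random.default_rng(51)
        signs = rng.choice([-1.0, 1.0], size=(10000, 5))
        g = signs @ a
        noise = rng.normal(0, 1.0, 10000)
        y = g + noise
        for j, t in enumerate(targets):
            realized = a[j] ** 2 * signs[:, j].var() / y.var()
            assert abs(realized - t) < 0.01
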