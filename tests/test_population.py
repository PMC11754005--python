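"""Covariance structures, two-generation simulation, independent records."""

import numpy as np
import pandas as pd
import pytest

from ratiotrait import (
    GeneticParams,
    IndependentRatioSpec,
    PopulationDesign,
    build_cov_structure,
    read_trait_table,
    simulate_base_generation,
    simulate_independent_records,
    simulate_offspring,
    simulate_population,
    write_trait_table,
)
from ratiotrait.population import _chol2


def _params(h1=0.3, h2=0.3, rg=0.0, re=0.0):
    return GeneticParams(mu1=10.0, mu2=10.0, h2_1=h1, h2_2=h2, r_g=rg, r_e=re)


class TestCovStructure:
    def test_direct_construction(self):
        cov = build_cov_structure(_params(0.1, 0.1, -0.5, -0.5))
        np.testing.assert_allclose(cov.G, [[0.1, -0.05], [-0.05, 0.1]], atol=1e-14)
        np.testing.assert_allclose(cov.E, [[0.9, -0.45], [-0.45, 0.9]], atol=1e-14)
        np.testing.assert_allclose(cov.P, cov.G + cov.E, atol=1e-14)

    def test_diagonal_cholesky_when_uncorrelated(self):
        cov = build_cov_structure(_params(0.3, 0.5, 0.0, 0.0))
        assert cov.Lg[1, 0] == 0.0
        np.testing.assert_allclose(np.diag(cov.Lg), np.sqrt([0.3, 0.5]), rtol=1e-14)

    @pytest.mark.parametrize("seed", range(5))
    def test_cholesky_round_trip(self, seed):
        r = np.random.default_rng(seed)
        p = GeneticParams(
            mu1=float(r.uniform(1, 20)),
            mu2=float(r.uniform(1, 20)),
            varp1=float(r.uniform(0.1, 5)),
            varp2=float(r.uniform(0.1, 5)),
            h2_1=float(r.uniform(0, 1)),
            h2_2=float(r.uniform(0, 1)),
            r_g=float(r.uniform(-1, 1)),
            r_e=float(r.uniform(-1, 1)),
        )
        cov = build_cov_structure(p)
        np.testing.assert_allclose(cov.Lg @ cov.Lg.T, cov.G, atol=1e-10)
        np.testing.assert_allclose(cov.Le @ cov.Le.T, cov.E, atol=1e-10)

    def test_zero_heritability_gives_singular_but_valid_factor(self):
        cov = build_cov_structure(_params(0.0, 0.3, 0.5, 0.0))
        np.testing.assert_allclose(cov.Lg @ cov.Lg.T, cov.G, atol=1e-12)
        assert cov.G[0, 1] == 0.0  # covariance scaled away by zero variance

    def test_non_psd_matrix_rejected_by_name(self):
        with pytest.raises(ValueError, match="genetic"):
            _chol2(np.array([[0.0, 0.1], [0.1, 1.0]]), "genetic")
        with pytest.raises(ValueError, match="environmental"):
            _chol2(np.array([[1.0, 2.0], [2.0, 1.0]]), "environmental")


class TestBaseGeneration:
    def test_counts_and_location(self, small_design):
        g0 = simulate_base_generation(_params(), small_design)
        assert len(g0) == small_design.n_sires + small_design.n_dams
        assert (g0["sire_id"] == 0).all() and (g0["dam_id"] == 0).all()
        n = len(g0)
        assert g0["p1"].mean() == pytest.approx(10.0, abs=4 / np.sqrt(n))

    def test_genetic_variance_recovered(self):
        design = PopulationDesign(n_sires=100_000, dams_per_sire=1, seed=3)
        g0 = simulate_base_generation(_params(0.3, 0.3), design)
        n = len(g0)
        se = 0.3 * np.sqrt(2.0 / n)
        assert g0["g1"].var() == pytest.approx(0.3, abs=3 * se)

    def test_zero_heritability_zero_breeding_values(self, small_design):
        g0 = simulate_base_generation(_params(0.0, 0.0, 0.0, 0.5), small_design)
        assert (g0["g1"] == 0).all() and (g0["g2"] == 0).all()


@pytest.fixture(scope="module")
def population():
    params = _params(0.3, 0.5, -0.5, 0.5)
    design = PopulationDesign(n_sires=2_000, dams_per_sire=10, offspring_per_dam=2, seed=11)
    g0, g1 = simulate_population(params, design)
    return params, design, g0, g1


class TestOffspring:
    def test_pedigree_structure(self, population):
        _, design, g0, g1 = population
        assert len(g1) == design.n_offspring
        assert g1["sire_id"].isin(g0["id"]).all()
        assert g1["dam_id"].isin(g0["id"]).all()
        assert (g1.groupby("dam_id").size() == design.offspring_per_dam).all()
        per_sire = design.dams_per_sire * design.offspring_per_dam
        assert (g1.groupby("sire_id").size() == per_sire).all()

    def test_ratio_identity(self, population):
        _, _, _, g1 = population
        np.testing.assert_allclose(g1["p0"] * g1["p2"], g1["p1"], atol=1e-10)

    def test_genetic_variance_stationary(self, population):
        params, design, _, g1 = population
        n = len(g1)
        for col, h2 in (("g1", params.h2_1), ("g2", params.h2_2)):
            se = h2 * np.sqrt(2.0 / n) * 2  # sibs correlated: inflate SE
            assert g1[col].var() == pytest.approx(h2, abs=4 * se)

    def test_midparent_offspring_covariance_is_half_g(self, population):
        params, _, g0, g1 = population
        cov = build_cov_structure(params)
        parents = g0.set_index("id")
        for col, j in (("g1", 0), ("g2", 1)):
            mid = 0.5 * (
                parents.loc[g1["sire_id"], col].to_numpy()
                + parents.loc[g1["dam_id"], col].to_numpy()
            )
            c = np.cov(mid, g1[col].to_numpy())[0, 1]
            assert c == pytest.approx(0.5 * cov.G[j, j], abs=0.01)

    def test_full_sib_covariance_is_half_g(self, population):
        params, _, _, g1 = population
        cov = build_cov_structure(params)
        sib = g1.sort_values(["dam_id", "id"])
        first = sib.groupby("dam_id").nth(0)
        second = sib.groupby("dam_id").nth(1)
        c = np.cov(first["g1"].to_numpy(), second["g1"].to_numpy())[0, 1]
        assert c == pytest.approx(0.5 * cov.G[0, 0], abs=0.01)

    def test_ratio_mean_in_delta_band(self, population):
        # grid settings put the G1 ratio mean between 1.005 and 1.015
        _, _, _, g1 = population
        assert 1.004 < g1["p0"].mean() < 1.016

    def test_zero_heritability_offspring_have_zero_breeding_values(self, small_design):
        params = _params(0.0, 0.0)
        g0, g1 = simulate_population(params, small_design)
        assert (g1["g1"] == 0).all() and (g1["g2"] == 0).all()

    def test_design_mismatch_rejected(self, small_design):
        params = _params()
        g0 = simulate_base_generation(params, small_design)
        bigger = PopulationDesign(n_sires=300, dams_per_sire=10, seed=7)
        with pytest.raises(ValueError, match="rows"):
            simulate_offspring(g0, params, bigger)


class TestReproducibilityAndIO:
    def test_same_seed_bit_identical(self, default_params, small_design):
        a0, a1 = simulate_population(default_params, small_design)
        b0, b1 = simulate_population(default_params, small_design)
        pd.testing.assert_frame_equal(a0, b0, check_exact=True)
        pd.testing.assert_frame_equal(a1, b1, check_exact=True)

    def test_different_seed_differs(self, default_params, small_design):
        from dataclasses import replace

        a0, _ = simulate_population(default_params, small_design)
        b0, _ = simulate_population(default_params, replace(small_design, seed=8))
        assert not np.allclose(a0["p1"], b0["p1"])

    def test_tsv_round_trip(self, default_params, small_design, tmp_path):
        g0, g1 = simulate_population(default_params, small_design)
        table = pd.concat([g0, g1], ignore_index=True)
        path = tmp_path / "pop.tsv"
        write_trait_table(table, path)
        back = read_trait_table(path)
        pd.testing.assert_frame_equal(back, table, check_exact=False, rtol=1e-12)


class TestIndependentRecords:
    def test_degenerate_cvs_give_ratio_of_means(self, rng):
        spec = IndependentRatioSpec(mu1=10, mu2=10, cv1=1e-6, cv2=1e-6, n_records=1000)
        records = simulate_independent_records(spec, rng)
        np.testing.assert_allclose(records, 1.0, atol=1e-4)

    @pytest.mark.parametrize("mu1,mu2", [(10, 25), (10, 10), (25, 10)])
    def test_mean_tracks_ratio_of_means(self, mu1, mu2, rng):
        # second-order expansion: E(p0) ≈ (mu1/mu2)(1 + cv2²)
        spec = IndependentRatioSpec(mu1=mu1, mu2=mu2, cv1=0.10, cv2=0.05, n_records=200_000)
        records = simulate_independent_records(spec, rng)
        expected = mu1 / mu2 * (1 + 0.05**2)
        assert np.mean(records) == pytest.approx(expected, rel=2e-3)

    def test_right_skewed_heavy_tailed(self, rng):
        from ratiotrait import moment_summary

        spec = IndependentRatioSpec(cv1=0.05, cv2=0.15, n_records=100_000)
        ms = moment_summary(simulate_independent_records(spec, rng))
        assert ms.skewness > 0 and ms.kurtosis > 0

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            IndependentRatioSpec(cv1=0.0)
        with pytest.raises(ValueError):
            IndependentRatioSpec(mu2=-1.0)
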