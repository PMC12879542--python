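"""Geometric grid, population bookkeeping, and discrete growth/nucleation terms."""

import logging

import numpy as np
import pytest

from batchcryst import (
    CrystalPopulation,
    build_grid,
    growth_rates,
    nucleation_rates,
    sauter_mean_diameter,
    volumetric_growth_rate,
)


class TestGrid:
    def test_smallest_bin_volume(self):
        grid = build_grid(1e-6, 1000e-6, 40)
        assert grid.V0 == pytest.approx(5.23599e-19, rel=1e-5)

    def test_ratio_factor_reference_grid(self):
        grid = build_grid(1e-6, 1000e-6, 40)
        assert grid.q == pytest.approx(9.0 * np.log2(10.0) / 39.0, rel=1e-12)
        assert grid.q == pytest.approx(0.7666, abs=1e-4)
        np.testing.assert_allclose(grid.V[1:] / grid.V[:-1], 2.0**grid.q, rtol=1e-12)

    def test_integer_q_doubles_diameters(self):
        # d_max = d_min * 2**(n-1) makes q exactly 3: diameters double per bin
        grid = build_grid(1e-6, 8e-6, 4)
        assert grid.q == pytest.approx(3.0, rel=1e-12)
        np.testing.assert_allclose(grid.d[1:] / grid.d[:-1], 2.0, rtol=1e-12)

    def test_diameters_match_volumes_and_increase(self):
        grid = build_grid(2e-6, 500e-6, 25)
        np.testing.assert_allclose(grid.d, (6 * grid.V / np.pi) ** (1 / 3), rtol=1e-12)
        assert np.all(np.diff(grid.d) > 0)
        assert grid.d[0] == pytest.approx(2e-6) and grid.d[-1] == pytest.approx(500e-6)

    @pytest.mark.parametrize("dmin,dmax,n", [(0.0, 1e-4, 10), (1e-4, 1e-5, 10), (1e-6, 1e-4, 1)])
    def test_invalid_bounds(self, dmin, dmax, n):
        with pytest.raises(ValueError):
            build_grid(dmin, dmax, n)


class TestVolumetricGrowthRate:
    def test_zero_growth(self, grid40):
        assert np.all(volumetric_growth_rate(0.0, grid40) == 0.0)

    def test_sphere_surface_formula(self):
        # bin at exactly 100 um: Gv = (pi/2) d^2 G
        grid = build_grid(100e-6, 800e-6, 4)
        gv = volumetric_growth_rate(1e-8, grid)
        assert gv[0] == pytest.approx(np.pi / 2 * (1e-4) ** 2 * 1e-8, rel=1e-12)
        assert gv[0] == pytest.approx(1.5708e-16, rel=1e-4)

    def test_linearity(self, grid40):
        np.testing.assert_allclose(
            volumetric_growth_rate(2e-8, grid40),
            2.0 * volumetric_growth_rate(1e-8, grid40),
            rtol=1e-14,
        )


class TestGrowthRates:
    def test_empty_population(self, grid40):
        pop = CrystalPopulation.empty(grid40)
        assert np.all(growth_rates(pop, grid40, 1e-8) == 0.0)

    def test_monodisperse_transfer_direction(self, grid40):
        alpha = np.zeros(40)
        alpha[10] = 1e-4
        pop = CrystalPopulation(alpha=alpha)
        dalpha = growth_rates(pop, grid40, 1e-8)
        assert dalpha[10] < 0.0 < dalpha[11]
        assert np.all(dalpha[:10] == 0.0) and np.all(dalpha[12:] == 0.0)

    def test_particle_number_conserved(self, grid40):
        rng = np.random.default_rng(7)
        pop = CrystalPopulation(alpha=rng.uniform(0, 1e-4, 40))
        dalpha = growth_rates(pop, grid40, 1e-8)
        dN = dalpha / grid40.V
        # telescoping oracle: the transfer terms cancel pairwise
        assert abs(dN.sum()) <= 1e-12 * np.abs(dN).sum()

    def test_against_bruteforce_summation(self, grid40):
        """Re-derive the upwind transfer bin by bin with explicit loops."""
        rng = np.random.default_rng(11)
        alpha = rng.uniform(0, 1e-4, 40)
        pop = CrystalPopulation(alpha=alpha)
        G = 3e-8
        N = alpha / grid40.V
        Gv = 3.0 * grid40.V / grid40.d * G
        expected = np.zeros(40)
        for i in range(40):
            inflow = Gv[i - 1] * N[i - 1] / (grid40.V[i] - grid40.V[i - 1]) if i > 0 else 0.0
            outflow = Gv[i] * N[i] / (grid40.V[i + 1] - grid40.V[i]) if i < 39 else 0.0
            expected[i] = grid40.V[i] * (inflow - outflow)
        np.testing.assert_allclose(growth_rates(pop, grid40, G), expected, rtol=1e-12)

    def test_top_bin_truncation_warning(self, grid40, caplog):
        alpha = np.zeros(40)
        alpha[-1] = 1e-4
        pop = CrystalPopulation(alpha=alpha)
        with caplog.at_level(logging.WARNING, logger="batchcryst.pbe"):
            growth_rates(pop, grid40, 1e-8)
        assert any("truncation" in rec.message for rec in caplog.records)


class TestNucleationRates:
    def test_zero_rate(self, grid40):
        assert np.all(nucleation_rates(0.0, grid40) == 0.0)

    def test_source_into_smallest_bin(self, grid40):
        dalpha = nucleation_rates(1.1e6, grid40)
        assert dalpha[0] == pytest.approx(5.76e-13, rel=1e-3)
        assert np.all(dalpha[1:] == 0.0)

    def test_number_rate_consistency(self, grid40):
        ndot0 = 2.5e5
        dalpha = nucleation_rates(ndot0, grid40)
        assert dalpha[0] / grid40.V0 == pytest.approx(ndot0, rel=1e-14)


class TestSauterMeanDiameter:
    def test_monodisperse(self, grid40):
        alpha = np.zeros(40)
        alpha[20] = 1e-3
        assert sauter_mean_diameter(CrystalPopulation(alpha), grid40) == pytest.approx(
            grid40.d[20]
        )

    def test_two_size_example(self):
        # equal numbers at 100 and 200 um: d32 = (1e6+8e6)/(1e4+4e4) = 180 um
        grid = build_grid(100e-6, 200e-6, 2)
        alpha = grid.V * 1.0  # one particle per unit volume in each bin
        d32 = sauter_mean_diameter(CrystalPopulation(alpha), grid)
        assert d32 == pytest.approx(180e-6, rel=1e-9)

    def test_bounded_by_occupied_bins(self, grid40):
        rng = np.random.default_rng(3)
        alpha = np.zeros(40)
        alpha[5:15] = rng.uniform(0, 1e-4, 10)
        d32 = sauter_mean_diameter(CrystalPopulation(alpha), grid40)
        assert grid40.d[5] <= d32 <= grid40.d[14]

    def test_empty_population_error(self, grid40):
        with pytest.raises(ValueError, match="empty"):
            sauter_mean_diameter(CrystalPopulation.empty(grid40), grid40)


class TestPopulation:
    def test_invariants(self, grid40):
        alpha = np.linspace(0, 1e-4, 40)
        pop = CrystalPopulation(alpha=alpha)
        np.testing.assert_allclose(pop.number_density(grid40) * grid40.V, alpha, rtol=1e-14)
        assert pop.volume_fractions().sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            CrystalPopulation(alpha=np.array([1e-4, -1e-6]))

    def test_csv_round_trip(self, grid40, tmp_path):
        alpha = np.linspace(1e-6, 1e-4, 40)
        pop = CrystalPopulation(alpha=alpha)
        path = tmp_path / "pop.csv"
        pop.to_csv(path, grid40)
        back, back_grid = CrystalPopulation.from_csv(path)
        np.testing.assert_allclose(back.alpha, alpha, rtol=1e-12)
        np.testing.assert_allclose(back_grid.V, grid40.V, rtol=1e-12)
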