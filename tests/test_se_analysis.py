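"""Global sedimentation-equilibrium fitting: model, recovery, invariances."""

import numpy as np
import pytest

from sedstoich import (
    BufferState,
    FitFailureError,
    InvalidInputError,
    NumericalFailureError,
    SEProfile,
    analytic_sector_integral,
    fit_one_species_global,
    fit_two_species_global,
    se_model,
    sigma_coefficient,
)
from sedstoich.lamm import CellGeometry
from sedstoich.se_analysis import DegenerateModelWarning
from sedstoich.synthetic_data import gen_se_dataset


@pytest.fixture
def flat_geometry_profile():
    geom = CellGeometry(6.8, 7.2)
    grid = np.arange(6.8, 7.2, 0.003)
    return SEProfile(rpm=23_000, radius_grid=grid,
                     signal=np.zeros_like(grid), r0=7.0, geometry=geom)


class TestSeModel:
    def test_zero_mass_gives_flat_profile(self, flat_geometry_profile, buffer):
        prof = flat_geometry_profile
        out = se_model(prof, [1e-9], [0.7], [0.4], 0.05, buffer)
        assert np.allclose(out, 0.45, atol=1e-6)

    def test_reference_point_identity(self, buffer):
        geom = CellGeometry(6.8, 7.2)
        grid = np.array([6.85, 7.0, 7.15])
        prof = SEProfile(23_000, grid, np.zeros(3), r0=7.0, geometry=geom)
        out = se_model(prof, [50_000.0, 20_000.0], [0.7, 0.6],
                       [0.3, 0.2], 0.04, buffer)
        assert out[1] == pytest.approx(0.3 + 0.2 + 0.04, abs=1e-12)

    def test_exponent_coefficient_value(self):
        # M (1 - vbar rho) w^2 / (2RT) with M = 33800 g/mol, vbar = 0.706,
        # rho = 1.05 g/ml at 23000 rpm, 298.15 K:
        # 8744.06 * (2*pi*23000/60)^2 / (2 * 8.31446e7 * 298.15) = 1.0231 cm^-2
        buf = BufferState(density=1.05, temperature=298.15)
        sigma = sigma_coefficient(33_800.0, 0.706, buf, 23_000.0)
        assert sigma == pytest.approx(1.0231, rel=1e-3)

    def test_monotonic_in_r_for_positive_buoyant_mass(self, buffer):
        geom = CellGeometry(6.8, 7.2)
        grid = np.arange(6.8, 7.2, 0.003)
        prof = SEProfile(23_000, grid, np.zeros_like(grid), r0=7.0,
                         geometry=geom)
        out = se_model(prof, [60_000.0], [0.7], [0.2], 0.0, buffer)
        assert np.all(np.diff(out) > 0)

    def test_overflow_exponent_raises(self, buffer):
        geom = CellGeometry(6.8, 7.2)
        grid = np.arange(6.8, 7.2, 0.01)
        prof = SEProfile(42_000, grid, np.zeros_like(grid), r0=6.8,
                         geometry=geom)
        with pytest.raises(NumericalFailureError):
            se_model(prof, [5e8], [0.7], [0.1], 0.0, buffer)


class TestOneSpeciesGlobal:
    def test_noiseless_round_trip_recovers_mass(self, buffer):
        profiles = gen_se_dataset(69_500.0, 0.7044, buffer,
                                  noise_sigma=0.0, seed=1)
        result = fit_one_species_global(profiles, 0.7044, buffer)
        assert result.molar_mass == pytest.approx(69_500.0, rel=1e-3)

    def test_noisy_recovery_within_two_standard_errors(self, buffer):
        profiles = gen_se_dataset(121_500.0, 0.7098, buffer,
                                  noise_sigma=0.005, seed=12)
        result = fit_one_species_global(profiles, 0.7098, buffer)
        assert result.molar_mass_se is not None and result.molar_mass_se > 0
        assert abs(result.molar_mass - 121_500.0) <= 2 * result.molar_mass_se

    def test_pure_baseline_is_unidentifiable(self, buffer):
        profiles = gen_se_dataset(69_500.0, 0.7044, buffer,
                                  noise_sigma=0.0, seed=1, loading=0.0)
        with pytest.raises(FitFailureError):
            fit_one_species_global(profiles, 0.7044, buffer)

    def test_mass_conservation_requires_two_speeds(self, buffer):
        profiles = gen_se_dataset(69_500.0, 0.7044, buffer,
                                  speeds=[23_000.0], noise_sigma=0.0, seed=1)
        with pytest.raises(InvalidInputError):
            fit_one_species_global(profiles, 0.7044, buffer,
                                   mass_conservation=True)
        # without the constraint a single speed is allowed
        result = fit_one_species_global(profiles, 0.7044, buffer,
                                        mass_conservation=False)
        assert result.molar_mass == pytest.approx(69_500.0, rel=1e-3)

    def test_fitted_loading_is_speed_invariant(self, buffer):
        profiles = gen_se_dataset(33_800.0, 0.7067, buffer,
                                  noise_sigma=0.005, seed=3)
        result = fit_one_species_global(profiles, 0.7067, buffer,
                                        mass_conservation=True)
        loads = [
            result.amplitudes[j, 0]
            * analytic_sector_integral(
                result.molar_mass, 0.7067, buffer, p.rpm, p.r0,
                p.geometry.meniscus, p.geometry.bottom,
            )
            for j, p in enumerate(profiles)
        ]
        assert max(loads) - min(loads) <= 1e-6 * abs(loads[0])

    def test_fit_invariant_to_reference_radius(self, buffer):
        profiles = gen_se_dataset(69_500.0, 0.7044, buffer,
                                  noise_sigma=0.005, seed=2)
        shifted = [
            SEProfile(p.rpm, p.radius_grid, p.signal,
                      r0=p.radius_grid[5], geometry=p.geometry)
            for p in profiles
        ]
        m1 = fit_one_species_global(profiles, 0.7044, buffer).molar_mass
        m2 = fit_one_species_global(shifted, 0.7044, buffer).molar_mass
        assert m1 == pytest.approx(m2, rel=1e-6)


def mix_two_species(m1, m2, vb1, vb2, buffer, seed, noise=0.005,
                    load1=0.3, load2=0.3):
    p1 = gen_se_dataset(m1, vb1, buffer, noise_sigma=0.0, seed=seed,
                        loading=load1, baseline_range=(0.0, 0.0))
    p2 = gen_se_dataset(m2, vb2, buffer, noise_sigma=0.0, seed=seed,
                        loading=load2, baseline_range=(0.0, 0.0))
    rng = np.random.default_rng(seed)
    return [
        SEProfile(
            a.rpm, a.radius_grid,
            a.signal + b.signal + rng.normal(0, noise, a.signal.size),
            a.r0, a.geometry,
        )
        for a, b in zip(p1, p2)
    ]


class TestTwoSpeciesGlobal:
    def test_single_species_data_yields_tiny_second_fraction(self, buffer):
        profiles = gen_se_dataset(33_800.0, 0.7067, buffer,
                                  noise_sigma=0.005, seed=8)
        result = fit_two_species_global(
            profiles, 0.7067, 0.56, buffer, fixed_m2=5008.7
        )
        assert result.masses[1][1] is None  # fixed mass carries no error
        assert result.fractions[1] < 0.01

    def test_even_mixture_recovery(self, buffer):
        profiles = mix_two_species(30_000.0, 120_000.0, 0.71, 0.71,
                                   buffer, seed=9)
        result = fit_two_species_global(profiles, 0.71, 0.71, buffer)
        masses = sorted(m for m, _ in result.masses)
        assert masses[0] == pytest.approx(30_000.0, rel=0.05)
        assert masses[1] == pytest.approx(120_000.0, rel=0.05)
        assert result.fractions[0] == pytest.approx(0.5, abs=0.05)
        assert result.fractions[1] == pytest.approx(0.5, abs=0.05)

    def test_equal_masses_flagged_as_degenerate(self, buffer):
        profiles = gen_se_dataset(60_000.0, 0.71, buffer,
                                  noise_sigma=0.002, seed=4)
        # fixing species 2 at the true (shared) mass forces the degeneracy
        with pytest.warns(DegenerateModelWarning):
            fit_two_species_global(profiles, 0.71, 0.71, buffer,
                                   fixed_m2=60_000.0)
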