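"""Lamm-equation forward solver: conservation, linearity, transport rate."""

import numpy as np
import pytest

from sedstoich import (
    CellGeometry,
    InvalidInputError,
    LammSpecies,
    NumericalFailureError,
    sector_mass,
    simulate_sv,
    species_from_s,
)
from sedstoich.physchem import SVEDBERG, omega_from_rpm


@pytest.fixture(scope="module")
def geometry():
    return CellGeometry(meniscus=6.0, bottom=7.2)


@pytest.fixture(scope="module")
def times():
    return np.linspace(2000.0, 20000.0, 5)


def test_no_transport_keeps_uniform_profile(geometry, times, buffer):
    species = LammSpecies(s=0.0, D=1e-12, loading_signal=0.4)
    scans = simulate_sv([species], geometry, 42_000, buffer, times,
                        noise_sigma=0.0)
    assert np.allclose(scans.signals, 0.4, atol=1e-10)


def test_sector_mass_conserved(geometry, times, buffer):
    species = species_from_s(3.0, 0.71, buffer, loading_signal=0.5)
    scans = simulate_sv([species], geometry, 42_000, buffer, times,
                        noise_sigma=0.0)
    masses = [sector_mass(scans.radius_grid, s) for s in scans.signals]
    spread = (max(masses) - min(masses)) / masses[0]
    assert spread < 1e-3


def test_superposition_linearity(geometry, times, buffer):
    sp1 = species_from_s(3.0, 0.71, buffer, loading_signal=0.5)
    sp2 = species_from_s(1.5, 0.71, buffer, loading_signal=0.3)
    both = simulate_sv([sp1, sp2], geometry, 42_000, buffer, times,
                       noise_sigma=0.0)
    one = simulate_sv([sp1], geometry, 42_000, buffer, times, noise_sigma=0.0)
    two = simulate_sv([sp2], geometry, 42_000, buffer, times, noise_sigma=0.0)
    assert np.array_equal(both.signals, one.signals + two.signals)


def test_noiseless_solution_nonnegative(geometry, times, buffer):
    species = species_from_s(5.0, 0.71, buffer, loading_signal=1.0)
    scans = simulate_sv([species], geometry, 42_000, buffer, times,
                        noise_sigma=0.0)
    assert scans.signals.min() >= 0.0


def test_boundary_velocity_matches_analytic_rate(geometry, buffer):
    """The half-height boundary radius obeys ln(r/r_men) = s w^2 t.

    Checked once the boundary has developed clear of the meniscus but is
    still in the first half of the column; the plateau reference is the
    analytic radial-dilution value exp(-2 s w^2 t).
    """
    s_true = 3.0
    species = species_from_s(s_true, 0.71, buffer, loading_signal=1.0)
    check_times = np.array([6000.0, 9000.0, 12000.0])
    scans = simulate_sv([species], geometry, 42_000, buffer, check_times,
                        noise_sigma=0.0)
    w2 = omega_from_rpm(42_000) ** 2
    for k, t in enumerate(check_times):
        sig = scans.signals[k]
        r = scans.radius_grid
        half = 0.5 * np.exp(-2.0 * s_true * SVEDBERG * w2 * t)
        i = int(np.argmax(sig > half))
        r_mid = np.interp(half, [sig[i - 1], sig[i]], [r[i - 1], r[i]])
        expected = s_true * SVEDBERG * w2 * t
        assert np.log(r_mid / geometry.meniscus) == pytest.approx(
            expected, rel=0.02
        )


def test_self_convergence_under_refinement(geometry, times, buffer):
    species = species_from_s(3.0, 0.71, buffer, loading_signal=0.5)
    coarse = simulate_sv([species], geometry, 42_000, buffer, times,
                         noise_sigma=0.0, n_cells=400)
    fine = simulate_sv([species], geometry, 42_000, buffer, times,
                       noise_sigma=0.0, n_cells=800)
    rel_rms = np.linalg.norm(coarse.signals - fine.signals) / np.linalg.norm(
        coarse.signals
    )
    assert rel_rms < 2e-3


def test_noise_is_seeded_and_reproducible(geometry, times, buffer):
    species = species_from_s(2.0, 0.71, buffer, loading_signal=0.3)
    a = simulate_sv([species], geometry, 42_000, buffer, times,
                    noise_sigma=0.005, seed=11)
    b = simulate_sv([species], geometry, 42_000, buffer, times,
                    noise_sigma=0.005, seed=11)
    assert np.array_equal(a.signals, b.signals)


def test_radius_grid_outside_cell_rejected(geometry, buffer):
    species = species_from_s(2.0, 0.71, buffer)
    with pytest.raises(InvalidInputError):
        simulate_sv([species], geometry, 42_000, buffer, [1000.0],
                    radius_grid=np.linspace(5.5, 7.0, 50))


def test_bad_time_step_raises_numerical_failure(geometry, buffer):
    species = species_from_s(2.0, 0.71, buffer)
    with pytest.raises(NumericalFailureError):
        simulate_sv([species], geometry, 42_000, buffer, [1000.0], dt=-5.0)


def test_species_validation():
    with pytest.raises(InvalidInputError):
        LammSpecies(s=-1.0, D=1e-7)
    with pytest.raises(InvalidInputError):
        LammSpecies(s=1.0, D=0.0)
    with pytest.raises(InvalidInputError):
        CellGeometry(meniscus=7.0, bottom=6.5)


def test_mass_from_s_round_trip(buffer):
    """s -> (M, D) is consistent with the Svedberg relation s = MD(1-vr)/RT."""
    from sedstoich import mass_and_diffusion_from_s
    from sedstoich.physchem import R_GAS

    s = 2.9
    vbar = 0.71
    mass, diffusion = mass_and_diffusion_from_s(s, vbar, buffer, 1.2)
    s_back = (
        mass * diffusion * (1.0 - vbar * buffer.density)
        / (R_GAS * buffer.temperature)
    ) / SVEDBERG
    # R is carried to 6 significant figures, so agreement is ~1e-6
    assert s_back == pytest.approx(s, rel=1e-5)
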