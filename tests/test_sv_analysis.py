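"""c(s) inversion round trips against the forward Lamm oracle."""

import numpy as np
import pytest

from sedstoich import (
    CsDistribution,
    InvalidInputError,
    SVScanSet,
    UndefinedResultError,
    fit_cs,
    peak_fraction,
    weight_average_s,
)
from sedstoich.lamm import CellGeometry
from sedstoich.synthetic_data import gen_sv_dataset, sv_scan_times

S_GRID = np.geomspace(0.5, 8.0, 30)
VBAR = 0.71


def quick_scans(s_values, loadings, buffer, noise=0.0, seed=None):
    times = sv_scan_times(float(np.max(s_values)), n_scans=8,
                          last_fraction=0.6)
    return gen_sv_dataset(
        s_values, loadings, VBAR, buffer, times=times,
        noise_sigma=noise, seed=seed, n_cells=250,
    )


def quick_fit(scans, buffer, **kw):
    kw.setdefault("s_grid", S_GRID)
    kw.setdefault("solver_cells", 120)
    return fit_cs(scans, buffer, VBAR, **kw)


@pytest.fixture(scope="module")
def single_species_fit(buffer):
    scans = quick_scans([3.0], [0.3], buffer)
    return fit_cs(scans, buffer, VBAR, s_grid=S_GRID, solver_cells=120)


class TestFitCs:
    def test_noiseless_single_species_peak_position(self, single_species_fit):
        dist = single_species_fit
        peak_s = dist.s_grid[np.argmax(dist.amplitudes)]
        grid_step = np.max(np.diff(dist.s_grid[(dist.s_grid > 2)
                                               & (dist.s_grid < 4)]))
        assert abs(peak_s - 3.0) <= grid_step

    def test_noiseless_total_signal_matches_loading(self, single_species_fit):
        assert single_species_fit.total_signal() == pytest.approx(0.3, rel=0.02)

    def test_noiseless_weight_average_recovery(self, single_species_fit):
        assert weight_average_s(single_species_fit) == pytest.approx(
            3.0, rel=0.05
        )

    def test_amplitudes_nonnegative(self, single_species_fit):
        assert np.all(single_species_fit.amplitudes >= 0.0)

    def test_zero_signal_gives_zero_distribution(self, buffer):
        times = np.linspace(500.0, 8000.0, 6)
        grid = np.arange(6.0, 7.2, 0.003)
        scans = SVScanSet(
            geometry=CellGeometry(6.0, 7.2),
            rpm=42_000,
            times=times,
            radius_grid=grid,
            signals=np.zeros((6, grid.size)),
        )
        dist = fit_cs(scans, buffer, VBAR, s_grid=S_GRID, solver_cells=120)
        assert np.all(dist.amplitudes == 0.0)
        assert dist.fit_rmsd == 0.0

    def test_two_species_area_ratio(self, buffer):
        scans = quick_scans([2.0, 6.0], [0.1, 0.1], buffer,
                            noise=0.002, seed=5)
        dist = quick_fit(scans, buffer)
        below, above = peak_fraction(dist, 3.5)
        assert below == pytest.approx(0.5, rel=0.10)
        assert above == pytest.approx(0.5, rel=0.10)

    def test_minority_species_fraction_recovery(self, buffer):
        # a 20% minority needs a little more resolution than the other
        # round trips: 12 scans and a 40-point grid
        times = sv_scan_times(6.0, n_scans=12, last_fraction=0.7)
        scans = gen_sv_dataset([2.0, 6.0], [0.02, 0.08], VBAR, buffer,
                               times=times, noise_sigma=0.002, seed=6,
                               n_cells=300)
        dist = fit_cs(scans, buffer, VBAR,
                      s_grid=np.geomspace(0.5, 8.0, 40), solver_cells=200)
        below, above = peak_fraction(dist, 3.5)
        assert below == pytest.approx(0.20, rel=0.10)
        assert above == pytest.approx(0.80, rel=0.10)

    def test_regularization_cannot_reduce_misfit(self, buffer):
        scans = quick_scans([3.0], [0.3], buffer, noise=0.005, seed=2)
        free = quick_fit(scans, buffer, alpha_policy="none")
        smoothed = quick_fit(scans, buffer, alpha_policy=50.0)
        assert smoothed.fit_rmsd >= free.fit_rmsd

    def test_input_validation(self, buffer):
        scans = quick_scans([3.0], [0.3], buffer)
        with pytest.raises(InvalidInputError):
            fit_cs(scans, buffer, VBAR, s_grid=np.linspace(1, 5, 10))
        few = SVScanSet(
            geometry=scans.geometry, rpm=scans.rpm,
            times=scans.times[:3], radius_grid=scans.radius_grid,
            signals=scans.signals[:3],
        )
        with pytest.raises(InvalidInputError):
            fit_cs(few, buffer, VBAR, s_grid=S_GRID)


def triangle_distribution(center, width=0.05, grid=None):
    if grid is None:
        grid = np.linspace(center - 10 * width, center + 10 * width, 201)
        grid = grid[grid > 0]
    amps = np.maximum(0.0, 1.0 - np.abs(grid - center) / width)
    return CsDistribution(grid, amps, 1.2, 0.0, 0.0)


class TestWeightAverage:
    def test_delta_like_distribution(self):
        dist = triangle_distribution(2.9)
        assert weight_average_s(dist) == pytest.approx(2.9, abs=1e-6)

    def test_two_equal_peaks_average_midway(self):
        grid = np.linspace(1.0, 5.0, 401)
        amps = np.exp(-0.5 * ((grid - 2.0) / 0.05) ** 2) + np.exp(
            -0.5 * ((grid - 4.0) / 0.05) ** 2
        )
        dist = CsDistribution(grid, amps, 1.2, 0.0, 0.0)
        assert weight_average_s(dist) == pytest.approx(3.0, abs=1e-3)

    def test_zero_distribution_is_undefined(self):
        dist = CsDistribution(np.linspace(1, 5, 30), np.zeros(30), 1.2, 0, 0)
        with pytest.raises(UndefinedResultError):
            weight_average_s(dist)


class TestPeakFraction:
    def test_boundary_below_everything(self):
        dist = triangle_distribution(3.0, grid=np.linspace(1.0, 5.0, 200))
        below, above = peak_fraction(dist, 1.5)
        assert below == pytest.approx(0.0, abs=1e-9)
        assert above == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_peak_splits_evenly(self):
        dist = triangle_distribution(3.0, grid=np.linspace(1.0, 5.0, 401))
        below, above = peak_fraction(dist, 3.0)
        assert below == pytest.approx(0.5, abs=0.01)

    def test_pair_sums_to_one_exactly(self):
        dist = triangle_distribution(2.2, grid=np.linspace(0.5, 6.0, 157))
        below, above = peak_fraction(dist, 2.9)
        assert below + above == 1.0

    def test_boundary_outside_grid_rejected(self):
        dist = triangle_distribution(3.0, grid=np.linspace(1.0, 5.0, 100))
        with pytest.raises(InvalidInputError):
            peak_fraction(dist, 9.0)
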