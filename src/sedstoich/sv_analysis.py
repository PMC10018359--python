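"""Sedimentation-coefficient distribution c(s) analysis.

Inverts a set of sedimentation-velocity scans into a regularised,
non-negative distribution of sedimentation coefficients.  The model is a
superposition of single-species Lamm-equation solutions on a grid of s
values, with the diffusion coefficient of each grid species tied to s
through a common frictional ratio f/f0 (the standard c(s)
parameterisation).  Systematic offsets of absorbance optics — a
time-invariant radial baseline plus a per-scan constant — are removed by
orthogonal projection (double centering), which is equivalent to co-fitting
them as unpenalised linear parameters.

The amplitudes solve a non-negative least-squares problem with a
second-difference smoothness penalty; the regularisation strength is picked
as the largest penalty whose chi-square remains statistically
indistinguishable (one-sided F test at a chosen confidence, default 0.68)
from the unregularised fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import nnls

from .exceptions import InvalidInputError, UndefinedResultError
from .lamm import (
    SVScanSet,
    _interp_exponential,
    _solve_single_species,
    species_from_s,
)
from .physchem import BufferState

logger = logging.getLogger(__name__)

DEFAULT_S_MIN = 0.2
DEFAULT_S_MAX = 12.0
DEFAULT_S_POINTS = 100


def default_s_grid(
    s_min: float = DEFAULT_S_MIN,
    s_max: float = DEFAULT_S_MAX,
    n_points: int = DEFAULT_S_POINTS,
) -> np.ndarray:
    """Log-spaced s grid covering the species range of interest."""
    return np.geomspace(s_min, s_max, n_points)


@dataclass
class CsDistribution:
    """A differential sedimentation-coefficient distribution.

    ``amplitudes`` are signal densities (AU per Svedberg) on ``s_grid``;
    the integral of c(s) ds over the grid equals the total fitted loading
    signal.
    """

    s_grid: np.ndarray
    amplitudes: np.ndarray
    frictional_ratio: float
    regularization_alpha: float
    fit_rmsd: float

    def __post_init__(self):
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(np.diff(self.s_grid) <= 0):
            raise InvalidInputError("s_grid must be strictly increasing")
        if np.any(self.amplitudes < 0):
            raise InvalidInputError("c(s) amplitudes must be non-negative")
        if self.fit_rmsd < 0:
            raise InvalidInputError("fit_rmsd must be >= 0")

    def total_signal(self) -> float:
        """Integrated c(s) ds — the total loading signal, AU."""
        return float(np.trapezoid(self.amplitudes, self.s_grid))


# ---------------------------------------------------------------------------
# Baseline projection: remove span{per-radius offsets} + span{per-scan offsets}
# ---------------------------------------------------------------------------


def _double_center(matrix: np.ndarray) -> np.ndarray:
    """Project out row effects (per scan) and column effects (per radius)."""
    row_mean = matrix.mean(axis=1, keepdims=True)
    col_mean = matrix.mean(axis=0, keepdims=True)
    return matrix - row_mean - col_mean + matrix.mean()


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.zeros_like(grid)
    d = np.diff(grid)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    return w


# ---------------------------------------------------------------------------
# c(s) fit
# ---------------------------------------------------------------------------


def fit_cs(
    scans: SVScanSet,
    buffer: BufferState,
    vbar: float,
    s_grid: np.ndarray | None = None,
    frictional_ratio: float = 1.2,
    alpha_policy: str | float = "fstat",
    confidence: float = 0.68,
    solver_cells: int = 200,
    fit_range: tuple[float, float] | None = None,
) -> CsDistribution:
    """Fit a c(s) distribution to a sedimentation-velocity scan set.

    Parameters
    ----------
    scans : SVScanSet
        At least 5 scans spanning visible boundary movement.
    buffer, vbar : solution conditions used for the s -> D mapping.
    s_grid : array, optional
        Grid of candidate sedimentation coefficients (>= 20 points);
        defaults to 100 log-spaced points on 0.2-12 S.
    frictional_ratio : float
        Common f/f0 tying D to s for every grid species.
    alpha_policy : "fstat" | "none" | float
        Regularisation selection: F-statistic criterion (default), no
        regularisation, or a fixed penalty weight.
    confidence : float
        Confidence level of the F criterion.
    solver_cells : int
        Radial cells of the finite-volume solver building the basis.
    fit_range : (float, float), optional
        Radial window (cm) actually fitted.  Defaults to excluding the
        optical artifact zone just off the meniscus (0.05 cm) and the
        steep back-diffusion pile-up at the cell bottom (0.10 cm), as is
        standard in boundary analysis.
    """
    if s_grid is None:
        s_grid = default_s_grid()
    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.size < 20:
        raise InvalidInputError(
            f"s_grid too coarse: need >= 20 points, got {s_grid.size}"
        )
    if scans.times.size < 5:
        raise InvalidInputError(
            f"need >= 5 scans for a c(s) fit, got {scans.times.size}"
        )

    if fit_range is None:
        fit_range = (
            scans.geometry.meniscus + 0.05,
            scans.geometry.bottom - 0.10,
        )
    radial_mask = (scans.radius_grid >= fit_range[0]) & (
        scans.radius_grid <= fit_range[1]
    )
    if radial_mask.sum() < 10:
        raise InvalidInputError(
            f"fit_range {fit_range} leaves fewer than 10 radius points"
        )
    radii = scans.radius_grid[radial_mask]
    data = np.asarray(scans.signals, dtype=float)[:, radial_mask]
    nt, nr = data.shape
    if not np.any(np.abs(data) > 0):
        logger.warning("all-zero scan set: returning an all-zero c(s)")
        return CsDistribution(
            s_grid=s_grid,
            amplitudes=np.zeros_like(s_grid),
            frictional_ratio=frictional_ratio,
            regularization_alpha=0.0,
            fit_rmsd=0.0,
        )

    # Basis: unit-loading Lamm solutions for each grid s, sampled like data.
    n_s = s_grid.size
    basis = np.empty((n_s, nt, nr))
    for k, s_val in enumerate(s_grid):
        sp = species_from_s(
            s_val, vbar, buffer, loading_signal=1.0,
            frictional_ratio=frictional_ratio,
        )
        conc, centers = _solve_single_species(
            sp, scans.geometry, scans.rpm, scans.times, solver_cells, None
        )
        for t in range(nt):
            basis[k, t] = _interp_exponential(radii, centers, conc[t])

    y = _double_center(data).ravel()
    design = np.stack(
        [_double_center(basis[k]).ravel() for k in range(n_s)], axis=1
    )

    # Normal-equation compression: chi2(x) = x'Gx - 2 b'x + yty.
    gram = design.T @ design
    b = design.T @ y
    yty = float(y @ y)
    # Second-difference penalty operator on the s grid.
    smooth = np.zeros((n_s - 2, n_s))
    idx = np.arange(n_s - 2)
    smooth[idx, idx] = 1.0
    smooth[idx, idx + 1] = -2.0
    smooth[idx, idx + 2] = 1.0
    ltl = smooth.T @ smooth

    def solve_alpha(alpha: float) -> tuple[np.ndarray, float]:
        m = gram + alpha**2 * ltl
        m = m + 1e-12 * np.trace(m) / n_s * np.eye(n_s)
        upper = cholesky(m, lower=False)
        rhs = cho_solve((upper, False), b)
        x, _ = nnls(upper, upper @ rhs)
        chi2 = float(x @ gram @ x - 2.0 * b @ x + yty)
        return x, max(chi2, 0.0)

    x0, chi2_0 = solve_alpha(0.0)
    if alpha_policy == "none":
        alpha, x, chi2 = 0.0, x0, chi2_0
    elif isinstance(alpha_policy, (int, float)):
        alpha = float(alpha_policy)
        x, chi2 = solve_alpha(alpha)
    elif alpha_policy == "fstat":
        n_obs = y.size
        dof = max(n_obs - n_s - nt - nr, 1)
        threshold = chi2_0 * stats.f.ppf(confidence, dof, dof)
        # largest alpha with chi2(alpha) <= threshold, by log bisection
        scale = np.sqrt(np.trace(gram) / max(np.trace(ltl), 1e-300))
        lo, hi = 1e-6 * scale, 1e6 * scale
        x_hi, chi2_hi = solve_alpha(hi)
        if chi2_hi <= threshold:
            alpha, x, chi2 = hi, x_hi, chi2_hi
        else:
            x, chi2 = x0, chi2_0
            alpha = 0.0
            for _ in range(40):
                mid = np.sqrt(lo * hi)
                x_mid, chi2_mid = solve_alpha(mid)
                if chi2_mid <= threshold:
                    alpha, x, chi2 = mid, x_mid, chi2_mid
                    lo = mid
                else:
                    hi = mid
    else:
        raise InvalidInputError(f"unknown alpha_policy {alpha_policy!r}")

    # Convert loadings per grid point to a density, AU per Svedberg.
    weights = _trapezoid_weights(s_grid)
    amplitudes = x / weights
    rmsd = float(np.sqrt(chi2 / y.size))
    return CsDistribution(
        s_grid=s_grid,
        amplitudes=amplitudes,
        frictional_ratio=frictional_ratio,
        regularization_alpha=float(alpha),
        fit_rmsd=rmsd,
    )


def weight_average_s(
    dist: CsDistribution, s_range: tuple[float, float] | None = None
) -> float:
    """Signal-weighted mean s over the distribution (trapezoidal), Svedberg."""
    s = dist.s_grid
    c = dist.amplitudes
    if s_range is not None:
        lo, hi = s_range
        mask = (s >= lo) & (s <= hi)
        s, c = s[mask], c[mask]
        if s.size < 2:
            raise UndefinedResultError("s_range contains fewer than 2 grid points")
    total = np.trapezoid(c, s)
    if total <= 0:
        raise UndefinedResultError("zero integrated c(s) over the range")
    return float(np.trapezoid(s * c, s) / total)


def peak_fraction(
    dist: CsDistribution, boundary_s: float
) -> tuple[float, float]:
    """Area fractions of c(s) below and above a boundary value of s.

    The pair sums to 1 exactly; the boundary must lie inside the grid.
    """
    s = dist.s_grid
    c = dist.amplitudes
    if not (s[0] <= boundary_s <= s[-1]):
        raise InvalidInputError(
            f"boundary {boundary_s} S outside grid [{s[0]}, {s[-1]}] S"
        )
    total = np.trapezoid(c, s)
    if total <= 0:
        raise UndefinedResultError("zero total c(s) area")
    c_at = np.interp(boundary_s, s, c)
    mask = s <= boundary_s
    s_below = np.append(s[mask], boundary_s)
    c_below = np.append(c[mask], c_at)
    below = np.trapezoid(c_below, s_below)
    frac_below = float(below / total)
    frac_below = min(max(frac_below, 0.0), 1.0)
    return frac_below, 1.0 - frac_below
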