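"""Global sedimentation-equilibrium analysis with mass conservation.

At equilibrium the radial absorbance profile of an ideal mixture is a sum
of exponentials in r^2,

    A(r) = sum_i A_{r0,i} exp[ M_i (1 - vbar_i rho) w^2 / (2RT) (r^2 - r0^2) ] + b,

one exponential per species, with reference amplitudes A_{r0,i}, a baseline
offset b per profile, and the buoyant molar mass M (1 - vbar rho) setting
the curvature.  Fitting profiles from several rotor speeds globally to a
shared molar mass is what pins M; the optional mass-conservation constraint
additionally ties the amplitudes together by requiring the baseline-
subtracted, sector-integrated loading signal

    L = integral_meniscus^bottom A_i(r) r dr

of each species to be identical at every speed (the cell contents do not
change between speeds), which reparameterises the per-speed amplitudes by
one shared loading per species.

The fit is a variable-projection nonlinear least squares: molar masses are
the only nonlinear parameters (optimised on a log scale from three spread
starting values), amplitudes/loadings (bounded >= 0) and baselines are
solved linearly at each step.  Standard errors come from the Jacobian-based
covariance of the full parameter vector scaled by the reduced chi-square,
and are reported as one standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, lsq_linear

from .exceptions import (
    FitFailureError,
    InvalidInputError,
    NumericalFailureError,
)
from .lamm import CellGeometry
from .physchem import BufferState, R_GAS, buoyant_factor, omega_from_rpm

_EXP_CLIP = 600.0  # keep internal model evaluations finite during search


class DegenerateModelWarning(UserWarning):
    """Two species are indistinguishable (near-equal masses)."""


@dataclass
class SEProfile:
    """One equilibrium absorbance profile at a single rotor speed."""

    rpm: float
    radius_grid: np.ndarray  # cm
    signal: np.ndarray  # AU
    r0: float  # reference radius, cm
    geometry: CellGeometry

    def __post_init__(self):
        self.radius_grid = np.asarray(self.radius_grid, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.radius_grid) <= 0):
            raise InvalidInputError("radius_grid must be strictly increasing")
        if self.signal.shape != self.radius_grid.shape:
            raise InvalidInputError("signal and radius_grid shapes differ")
        if not (self.radius_grid[0] <= self.r0 <= self.radius_grid[-1]):
            raise InvalidInputError(
                f"reference radius r0={self.r0} outside the radius grid"
            )


@dataclass
class SEFitResult:
    """Result of a global equilibrium fit.

    ``masses`` holds (molar mass, 1-standard-error) per species (the error
    is None for species whose mass was held fixed); ``amplitudes`` is the
    (n_profiles, n_species) array of reference amplitudes A_{r0,i};
    ``baselines`` one offset per profile; ``fractions`` the species' shares
    of the total baseline-subtracted loading signal.
    """

    masses: list[tuple[float, float | None]]
    amplitudes: np.ndarray
    baselines: np.ndarray
    reduced_chisq: float
    fractions: np.ndarray
    mass_conservation: bool
    loadings: np.ndarray | None = None  # per-species sector loading, AU cm^2
    n_obs: int = 0
    n_params: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def molar_mass(self) -> float:
        """Molar mass of the first (or only) species, g/mol."""
        return self.masses[0][0]

    @property
    def molar_mass_se(self) -> float | None:
        return self.masses[0][1]


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def sigma_coefficient(
    molar_mass: float, vbar: float, buffer: BufferState, rpm: float
) -> float:
    """Reduced buoyant mass M (1 - vbar rho) w^2 / (2RT), cm^-2."""
    omega2 = omega_from_rpm(rpm) ** 2
    return (
        buoyant_factor(molar_mass, vbar, buffer.density)
        * omega2
        / (2.0 * R_GAS * buffer.temperature)
    )


def se_model(
    profile: SEProfile,
    masses,
    vbars,
    amplitudes,
    baseline: float,
    buffer: BufferState,
) -> np.ndarray:
    """Evaluate the multi-species exponential model on the profile's grid."""
    masses = np.atleast_1d(np.asarray(masses, dtype=float))
    vbars = np.atleast_1d(np.asarray(vbars, dtype=float))
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    r2 = profile.radius_grid**2 - profile.r0**2
    out = np.full_like(profile.radius_grid, float(baseline))
    for m, vb, amp in zip(masses, vbars, amplitudes, strict=True):
        exponent = sigma_coefficient(m, vb, buffer, profile.rpm) * r2
        if not np.all(np.isfinite(exponent)) or np.max(np.abs(exponent)) > 700:
            raise NumericalFailureError(
                f"non-finite or overflowing exponent for M={m:.3g} g/mol at "
                f"{profile.rpm:.0f} rpm"
            )
        out = out + amp * np.exp(exponent)
    return out


def analytic_sector_integral(
    molar_mass: float,
    vbar: float,
    buffer: BufferState,
    rpm: float,
    r0: float,
    meniscus: float,
    bottom: float,
) -> float:
    """Exact integral of exp(sigma (r^2 - r0^2)) r dr from meniscus to bottom.

    Multiplying by the reference amplitude gives the species' sector
    loading signal; this is the quantity mass conservation holds fixed
    across rotor speeds.
    """
    sig = sigma_coefficient(molar_mass, vbar, buffer, rpm)
    if abs(sig) < 1e-12:
        return 0.5 * (bottom**2 - meniscus**2)
    a = np.clip(sig * (bottom**2 - r0**2), -_EXP_CLIP, _EXP_CLIP)
    b = np.clip(sig * (meniscus**2 - r0**2), -_EXP_CLIP, _EXP_CLIP)
    return float((np.exp(a) - np.exp(b)) / (2.0 * sig))


# ---------------------------------------------------------------------------
# Global fit machinery (variable projection)
# ---------------------------------------------------------------------------


def _shape_matrix(profile, masses, vbars, buffer):
    """Columns exp(sigma_i (r^2 - r0^2)) per species, exponent clipped."""
    r2 = profile.radius_grid**2 - profile.r0**2
    cols = []
    for m, vb in zip(masses, vbars, strict=True):
        sig = sigma_coefficient(m, vb, buffer, profile.rpm)
        cols.append(np.exp(np.clip(sig * r2, -_EXP_CLIP, _EXP_CLIP)))
    return np.stack(cols, axis=1)


def _linear_solve(profiles, masses, vbars, buffer, mass_conservation):
    """Solve amplitudes/loadings (>=0) and baselines for fixed masses.

    Returns (amplitudes[n_prof, n_spec], baselines[n_prof],
    loadings[n_spec] or None, residual vector).
    """
    n_prof = len(profiles)
    n_spec = len(masses)
    n_pts = [p.radius_grid.size for p in profiles]
    n_tot = int(np.sum(n_pts))
    y = np.concatenate([p.signal for p in profiles])

    if mass_conservation:
        # columns: one shared loading per species + one baseline per profile
        design = np.zeros((n_tot, n_spec + n_prof))
        g = np.zeros((n_prof, n_spec))
        row = 0
        for j, prof in enumerate(profiles):
            shapes = _shape_matrix(prof, masses, vbars, buffer)
            for i in range(n_spec):
                integral = analytic_sector_integral(
                    masses[i], vbars[i], buffer, prof.rpm, prof.r0,
                    prof.geometry.meniscus, prof.geometry.bottom,
                )
                g[j, i] = 1.0 / integral
                design[row : row + n_pts[j], i] = g[j, i] * shapes[:, i]
            design[row : row + n_pts[j], n_spec + j] = 1.0
            row += n_pts[j]
        lb = np.r_[np.zeros(n_spec), np.full(n_prof, -np.inf)]
        ub = np.full(n_spec + n_prof, np.inf)
        sol = lsq_linear(design, y, bounds=(lb, ub), tol=1e-14)
        loadings = sol.x[:n_spec]
        baselines = sol.x[n_spec:]
        amplitudes = g * loadings[None, :]
        resid = design @ sol.x - y
        return amplitudes, baselines, loadings, resid

    # independent amplitudes per profile per species + baselines
    n_par = n_prof * n_spec + n_prof
    design = np.zeros((n_tot, n_par))
    row = 0
    for j, prof in enumerate(profiles):
        shapes = _shape_matrix(prof, masses, vbars, buffer)
        for i in range(n_spec):
            design[row : row + n_pts[j], j * n_spec + i] = shapes[:, i]
        design[row : row + n_pts[j], n_prof * n_spec + j] = 1.0
        row += n_pts[j]
    lb = np.r_[np.zeros(n_prof * n_spec), np.full(n_prof, -np.inf)]
    sol = lsq_linear(design, y, bounds=(lb, np.full(n_par, np.inf)), tol=1e-14)
    amplitudes = sol.x[: n_prof * n_spec].reshape(n_prof, n_spec)
    baselines = sol.x[n_prof * n_spec :]
    resid = design @ sol.x - y
    return amplitudes, baselines, None, resid


def _species_loadings(profiles, masses, vbars, buffer, amplitudes):
    """Mean (over profiles) sector loading per species from amplitudes."""
    n_spec = len(masses)
    loads = np.zeros(n_spec)
    for i in range(n_spec):
        per_prof = [
            amplitudes[j, i]
            * analytic_sector_integral(
                masses[i], vbars[i], buffer, p.rpm, p.r0,
                p.geometry.meniscus, p.geometry.bottom,
            )
            for j, p in enumerate(profiles)
        ]
        loads[i] = float(np.mean(per_prof))
    return loads


def _standard_errors(profiles, free_masses, fixed, vbars, buffer,
                     mass_conservation, resid):
    """1-sigma errors on the free masses by finite-difference Jacobian."""
    logm = np.log(free_masses)
    n_free = logm.size

    def residuals_of(logm_vec):
        masses = _assemble_masses(logm_vec, fixed)
        _, _, _, r = _linear_solve(
            profiles, masses, vbars, buffer, mass_conservation
        )
        return r

    n_obs = resid.size
    jac = np.empty((n_obs, n_free))
    h = 1e-6
    for k in range(n_free):
        lp = logm.copy()
        lp[k] += h
        lm = logm.copy()
        lm[k] -= h
        jac[:, k] = (residuals_of(lp) - residuals_of(lm)) / (2 * h)
    # linear parameters were re-solved at each perturbation, so this is the
    # profiled (concentrated) Jacobian — the right one for errors on M
    n_lin = (len(free_masses) + len(fixed)) * (
        1 if mass_conservation else len(profiles)
    ) + len(profiles)
    dof = max(n_obs - n_free - n_lin, 1)
    s2 = float(resid @ resid) / dof
    try:
        cov = np.linalg.inv(jac.T @ jac) * s2
        se_logm = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_logm = np.full(n_free, np.nan)
    return np.asarray(free_masses) * se_logm, dof


def _assemble_masses(logm_free, fixed):
    """Interleave optimised and fixed masses; `fixed` maps index -> mass."""
    n_spec = logm_free.size + len(fixed)
    masses = np.empty(n_spec)
    it = iter(np.exp(logm_free))
    for i in range(n_spec):
        masses[i] = fixed[i] if i in fixed else next(it)
    return masses


_MULTISTART_MASSES = (1.0e4, 7.0e4, 5.0e5)  # g/mol, spanning the plausible range
_LOGM_BOUNDS = (np.log(2.0e3), np.log(5.0e6))


def _fit_global(profiles, vbars, buffer, mass_conservation, fixed,
                n_species, starts=None):
    best = None
    start_masses = starts if starts is not None else _MULTISTART_MASSES

    def objective(logm_vec):
        masses = _assemble_masses(np.asarray(logm_vec), fixed)
        _, _, _, r = _linear_solve(
            profiles, masses, vbars, buffer, mass_conservation
        )
        return r

    n_free = n_species - len(fixed)
    last_resid = None
    for m0 in start_masses:
        x0 = np.full(n_free, np.log(m0))
        try:
            sol = least_squares(
                objective, x0, bounds=(_LOGM_BOUNDS[0], _LOGM_BOUNDS[1]),
                method="trf", xtol=1e-12, ftol=1e-14, gtol=1e-10,
            )
        except (np.linalg.LinAlgError, ValueError):
            continue
        last_resid = sol.fun
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitFailureError(
            "global equilibrium fit failed from every starting value",
            best_residuals=last_resid,
        )
    return best


def _finalize(profiles, best, fixed, vbars, buffer, mass_conservation,
              n_species):
    masses = _assemble_masses(best.x, fixed)
    amplitudes, baselines, loadings, resid = _linear_solve(
        profiles, masses, vbars, buffer, mass_conservation
    )
    if loadings is None:
        loadings = _species_loadings(profiles, masses, vbars, buffer, amplitudes)

    # unidentifiable check: fitted signal span indistinguishable from noise
    spans = []
    for j, prof in enumerate(profiles):
        shapes = _shape_matrix(prof, masses, vbars, buffer)
        model = shapes @ amplitudes[j]
        spans.append(np.ptp(model))
    rmsd = float(np.sqrt(np.mean(resid**2)))
    if max(spans) < max(1e-8, 0.5 * rmsd):
        raise FitFailureError(
            "fitted amplitudes are consistent with zero: molar mass is "
            "unidentifiable (pure-baseline data?)",
            best_residuals=resid,
        )

    free_mass_vals = np.exp(best.x)
    se_free, dof = _standard_errors(
        profiles, free_mass_vals, fixed, vbars, buffer,
        mass_conservation, resid,
    )
    mass_list: list[tuple[float, float | None]] = []
    it = iter(zip(free_mass_vals, se_free))
    for i in range(n_species):
        if i in fixed:
            mass_list.append((fixed[i], None))
        else:
            m, se = next(it)
            mass_list.append((float(m), float(se)))

    total_load = float(np.sum(loadings))
    fractions = (
        loadings / total_load if total_load > 0 else np.full(n_species, np.nan)
    )
    n_lin = n_species * (1 if mass_conservation else len(profiles)) + len(
        profiles
    )
    n_params = (n_species - len(fixed)) + n_lin
    chisq = float(resid @ resid)
    return SEFitResult(
        masses=mass_list,
        amplitudes=amplitudes,
        baselines=baselines,
        reduced_chisq=chisq / max(resid.size - n_params, 1),
        fractions=np.asarray(fractions),
        mass_conservation=mass_conservation,
        loadings=np.asarray(loadings),
        n_obs=resid.size,
        n_params=n_params,
    )


# ---------------------------------------------------------------------------
# Public fits
# ---------------------------------------------------------------------------


def fit_one_species_global(
    profiles: list[SEProfile],
    vbar: float,
    buffer: BufferState,
    mass_conservation: bool = True,
) -> SEFitResult:
    """Globally fit a single molar mass to equilibrium profiles.

    All profiles share one species mass; each keeps its own reference
    amplitude and baseline offset unless ``mass_conservation`` ties the
    amplitudes to one shared sector loading.
    """
    if mass_conservation and len(profiles) < 2:
        raise InvalidInputError(
            "mass conservation requires profiles at >= 2 rotor speeds"
        )
    if not profiles:
        raise InvalidInputError("no profiles given")
    vbars = [vbar]
    best = _fit_global(profiles, vbars, buffer, mass_conservation, {}, 1)
    return _finalize(profiles, best, {}, vbars, buffer, mass_conservation, 1)


def fit_two_species_global(
    profiles: list[SEProfile],
    vbar_1: float,
    vbar_2: float,
    buffer: BufferState,
    mass_conservation: bool = True,
    fixed_m2: float | None = None,
) -> SEFitResult:
    """Globally fit a two-species model (e.g. complex plus free DNA).

    Species 2's mass may be held fixed (``fixed_m2``), the standard control
    for quantifying how much unbound DNA a one-species dataset could hide:
    its fitted signal fraction bounds the free-DNA population.  A species
    amplitude pinned at zero is a valid boundary solution, not a failure.
    """
    if mass_conservation and len(profiles) < 2:
        raise InvalidInputError(
            "mass conservation requires profiles at >= 2 rotor speeds"
        )
    if not profiles:
        raise InvalidInputError("no profiles given")
    vbars = [vbar_1, vbar_2]
    fixed = {1: float(fixed_m2)} if fixed_m2 is not None else {}
    best = _fit_global(profiles, vbars, buffer, mass_conservation, fixed, 2)
    result = _finalize(
        profiles, best, fixed, vbars, buffer, mass_conservation, 2
    )
    m1 = result.masses[0][0]
    m2 = result.masses[1][0]
    if abs(np.log(m1 / m2)) < 0.02:
        warnings.warn(
            f"species masses {m1:.3g} and {m2:.3g} g/mol are nearly equal: "
            "amplitudes are strongly correlated and fractions unreliable",
            DegenerateModelWarning,
            stacklevel=2,
        )
    return result
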