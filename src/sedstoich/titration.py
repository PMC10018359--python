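"""Light-scattering titration analysis.

A fixed amount of ssDNA is titrated with protein while 90-degree light
scattering is monitored.  Scattering stays at baseline until the protein
binding density on the DNA crosses a critical value, then rises steeply as
large aggregates form.  Three operations quantify this:

* normalisation of raw intensities to (I_i - I_0) / I_0, so curves from
  different days/instruments are comparable;
* aggregation-onset detection, an empirical changepoint: a continuous
  two-segment (hinge) model is fit by exhaustive breakpoint search, and a
  breakpoint counts as detected only when the hinge beats a single straight
  line by an F-ratio threshold and the post-onset slope exceeds the
  pre-onset slope;
* the exact 1:1 binding saturation fraction from the quadratic in the
  complex concentration — used to verify that a chosen ligand excess keeps
  the receptor essentially saturated throughout an experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

DEFAULT_F_THRESHOLD = 4.0
DEFAULT_MIN_POINTS = 4


@dataclass
class TitrationSeries:
    """Raw titration data: molar ratios (non-decreasing) and intensities."""

    molar_ratios: np.ndarray
    intensities: np.ndarray  # counts
    initial_intensity: float  # I_0, counts, before any injection
    reference_intensities: np.ndarray | None = None  # buffer-only series
    injection_volumes: np.ndarray | None = None  # cumulative volume, any unit
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.molar_ratios = np.asarray(self.molar_ratios, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.initial_intensity <= 0:
            raise InvalidInputError("initial intensity I_0 must be > 0")
        if np.any(np.diff(self.molar_ratios) < 0):
            raise InvalidInputError("molar ratios must be non-decreasing")
        if self.intensities.shape != self.molar_ratios.shape:
            raise InvalidInputError("ratios and intensities differ in length")


@dataclass
class NormalizedSeries:
    """Normalised titration curve: values are (I_i - I_0) / I_0."""

    molar_ratios: np.ndarray
    values: np.ndarray
    initial_intensity: float


@dataclass
class OnsetResult:
    """Outcome of the hinge-model aggregation-onset search."""

    onset_ratio: float
    pre_slope: float
    post_slope: float
    detected: bool
    fit_sse: float
    f_statistic: float = float("nan")


def normalize_series(
    series: TitrationSeries, dilution_correct: bool = False
) -> NormalizedSeries:
    """Normalise raw intensities to (I_i - I_0) / I_0.

    If the series carries a buffer-only reference, the reference is
    subtracted point-by-point before normalisation.  With
    ``dilution_correct`` and recorded injection volumes, intensities are
    first rescaled by V_i / V_0 to undo dilution.
    """
    intens = series.intensities.astype(float).copy()
    i0 = float(series.initial_intensity)
    if series.reference_intensities is not None:
        ref = np.asarray(series.reference_intensities, dtype=float)
        if ref.shape != intens.shape:
            raise InvalidInputError("reference series length mismatch")
        intens = intens - ref
    if dilution_correct:
        if series.injection_volumes is None:
            raise InvalidInputError(
                "dilution correction requested but no injection volumes"
            )
        vols = np.asarray(series.injection_volumes, dtype=float)
        intens = intens * (vols / vols[0])
    return NormalizedSeries(
        molar_ratios=series.molar_ratios.copy(),
        values=(intens - i0) / i0,
        initial_intensity=i0,
    )


def unnormalize(norm: NormalizedSeries) -> np.ndarray:
    """Invert :func:`normalize_series` (no reference/dilution): raw I_i."""
    return norm.values * norm.initial_intensity + norm.initial_intensity


# ---------------------------------------------------------------------------
# Hinge-model changepoint
# ---------------------------------------------------------------------------


def hinge_model(
    x: np.ndarray, breakpoint: float, intercept: float,
    pre_slope: float, post_slope: float,
) -> np.ndarray:
    """Continuous two-segment line with a slope change at ``breakpoint``."""
    x = np.asarray(x, dtype=float)
    return (
        intercept
        + pre_slope * x
        + (post_slope - pre_slope) * np.maximum(0.0, x - breakpoint)
    )


def _hinge_sse(x, y, breakpoint):
    """Best-fit SSE and (intercept, pre, post) at a fixed breakpoint."""
    design = np.stack(
        [np.ones_like(x), x, np.maximum(0.0, x - breakpoint)], axis=1
    )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = design @ coef - y
    sse = float(resid @ resid)
    intercept, pre, delta = coef
    return sse, (float(intercept), float(pre), float(pre + delta))


def detect_onset(
    series: NormalizedSeries,
    min_points_per_segment: int = DEFAULT_MIN_POINTS,
    f_threshold: float = DEFAULT_F_THRESHOLD,
) -> OnsetResult:
    """Locate the aggregation onset by exhaustive hinge-breakpoint search.

    Every observed ratio that leaves ``min_points_per_segment`` points on
    each side is tried as the breakpoint; the best three grid SSEs get a
    parabolic refinement.  Detection requires (a) the hinge to improve on
    a single straight line by an F-ratio of at least ``f_threshold`` (two
    extra parameters), and (b) a post-onset slope exceeding the pre-onset
    slope.
    """
    x = np.asarray(series.molar_ratios, dtype=float)
    y = np.asarray(series.values, dtype=float)
    n = x.size
    if min_points_per_segment < 2:
        raise InvalidInputError("min_points_per_segment must be >= 2")
    if n < 2 * min_points_per_segment:
        raise InvalidInputError(
            f"need >= {2 * min_points_per_segment} points, got {n}"
        )

    candidates = x[min_points_per_segment - 1 : n - min_points_per_segment]
    candidates = np.unique(candidates)
    results = [(_hinge_sse(x, y, bp)[0], bp) for bp in candidates]
    results.sort()
    best_sse, best_bp = results[0]

    # parabolic refinement through the three best grid SSEs
    if len(results) >= 3:
        (s1, b1), (s2, b2), (s3, b3) = results[:3]
        bps = np.array([b1, b2, b3])
        sses = np.array([s1, s2, s3])
        order = np.argsort(bps)
        bps, sses = bps[order], sses[order]
        denom = (
            (bps[0] - bps[1]) * (bps[0] - bps[2]) * (bps[1] - bps[2])
        )
        if abs(denom) > 1e-12:
            # vertex of the parabola through the three (bp, sse) points
            a_coef = (
                bps[2] * (sses[1] - sses[0])
                + bps[1] * (sses[0] - sses[2])
                + bps[0] * (sses[2] - sses[1])
            ) / denom
            b_coef = (
                bps[2] ** 2 * (sses[0] - sses[1])
                + bps[1] ** 2 * (sses[2] - sses[0])
                + bps[0] ** 2 * (sses[1] - sses[2])
            ) / denom
            if a_coef > 0:
                vertex = -b_coef / (2 * a_coef)
                if bps[0] < vertex < bps[2]:
                    sse_v, _ = _hinge_sse(x, y, vertex)
                    if sse_v < best_sse:
                        best_sse, best_bp = sse_v, vertex

    best_sse, (intercept, pre, post) = (
        _hinge_sse(x, y, best_bp)[0],
        _hinge_sse(x, y, best_bp)[1],
    )

    # straight-line null model
    design1 = np.stack([np.ones_like(x), x], axis=1)
    coef1, *_ = np.linalg.lstsq(design1, y, rcond=None)
    resid1 = design1 @ coef1 - y
    sse1 = float(resid1 @ resid1)
    dof = max(n - 4, 1)
    if best_sse <= 0:
        f_stat = float("inf") if sse1 > best_sse else 0.0
    else:
        f_stat = ((sse1 - best_sse) / 2.0) / (best_sse / dof)
    detected = bool(f_stat >= f_threshold and post > pre)
    return OnsetResult(
        onset_ratio=float(best_bp),
        pre_slope=pre,
        post_slope=post,
        detected=detected,
        fit_sse=best_sse,
        f_statistic=f_stat,
    )


# ---------------------------------------------------------------------------
# 1:1 binding saturation
# ---------------------------------------------------------------------------


def saturation_fraction(
    binding_constant: float, total_receptor: float, total_ligand: float
) -> float:
    """Fraction of receptor bound at equilibrium for 1:1 binding, exact.

    The complex concentration C is the smaller root of
    C^2 - (R_t + L_t + 1/K) C + R_t L_t = 0; the fraction bound is C/R_t.
    Computed with the numerically stable quadratic form
    C = 2 R_t L_t / (b + sqrt(b^2 - 4 R_t L_t)).
    """
    k, r_t, l_t = binding_constant, total_receptor, total_ligand
    if k <= 0 or r_t <= 0 or l_t <= 0:
        raise InvalidInputError(
            "binding constant and total concentrations must be positive"
        )
    b = r_t + l_t + 1.0 / k
    disc = np.sqrt(b * b - 4.0 * r_t * l_t)
    complex_conc = 2.0 * r_t * l_t / (b + disc)
    return float(complex_conc / r_t)
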