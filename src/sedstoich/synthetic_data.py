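"""Synthetic datasets emulating the protein-ssDNA interaction study.

The pipeline's raw inputs (equilibrium profiles, velocity scan sets,
light-scattering titrations, the component registry) are regenerated here
from the quantities the study reports: component partial specific volumes
(0.734 ml/g RecO, 0.711 RecR, 0.704 SSB-Ct peptide, 0.56 DNA), expected
complex masses (33.8, 69.5, 121.5 kDa), rotor speeds (18/23/28 krpm
equilibrium, 42 krpm velocity), weight-average sedimentation coefficients
(0.5-6.3 S), aggregation-onset molar ratios (5.2, 6, 7.1), and sample
concentrations (0.56 uM Cy3-DNA monitored at 546 nm).

Noise models are explicit and seeded: i.i.d. Gaussian absorbance noise
(default sigma 0.005 AU) and Gaussian scattering noise on the normalised
scale (default sigma 0.02).  Equilibrium profiles are generated from the
closed-form exponential model — never from the Lamm solver — so
equilibrium round-trip tests are independent of PDE discretisation error.
Regeneration with the same scenario and seed is bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError
from .lamm import (
    CellGeometry,
    DEFAULT_SCAN_STEP_CM,
    SVScanSet,
    simulate_sv,
    species_from_s,
)
from .physchem import (
    BufferState,
    Component,
    Composition,
    composite_vbar,
    molar_mass_from_sequence,
)
from .se_analysis import SEProfile, analytic_sector_integral, sigma_coefficient
from .stoichiometry import derive_component_masses_from_complexes
from .titration import TitrationSeries, hinge_model

# ---------------------------------------------------------------------------
# Printed study constants anchoring the generator
# ---------------------------------------------------------------------------

SSB_CT_SEQUENCE = "PSNEPPMDFDDDIPF"  # last 15 residues of the SSB C-terminus

VBAR_RECO = 0.734  # ml/g, measured
VBAR_RECR = 0.711
VBAR_SSB_CT = 0.704
VBAR_DNA = 0.56

#: Expected complex masses, g/mol: one SSB-Ct-RecO on (dT)15; two on (dT)35;
#: SSB-Ct-RecR4O on (dT)15; the text variant of the latter; and the excluded
#: two-RecO/two-DNA alternative.
EXPECTED_MASS_RECO_DT15 = 33_800.0
EXPECTED_MASS_RECO2_DT35 = 69_500.0
EXPECTED_MASS_RECR4O_DT15 = 121_500.0
EXPECTED_MASS_RECR4O_DT15_TEXT = 121_200.0
EXPECTED_MASS_RECR4O2_DT15_2 = 155_600.0

SE_SPEEDS_RPM = (18_000.0, 23_000.0, 28_000.0)
SV_RPM = 42_000.0
ONSET_RATIOS = {"dT35": 5.2, "dT70": 6.0, "dT140": 7.1}
#: Printed weight-average s values, Svedberg: free Cy3-(dT)L, RecOR-bound,
#: and RecOR+SSB-Ct-bound series.
PRINTED_S_VALUES = (
    0.5, 0.7, 0.9, 1.2, 2.6, 2.9, 3.8, 4.7, 4.8, 5.4, 5.7, 6.3,
)

DNA_CONC_M = 0.56e-6  # Cy3-DNA, molecules
CY3_EXTINCTION_546 = 1.5e5  # M^-1 cm^-1, nominal cyanine-3 peak extinction
PATHLENGTH_CM = 1.2

DEFAULT_SE_GEOMETRY = CellGeometry(meniscus=6.8, bottom=7.2)
DEFAULT_SV_GEOMETRY = CellGeometry(meniscus=6.0, bottom=7.2)
DEFAULT_NOISE_AU = 0.005
DEFAULT_TITRATION_NOISE = 0.02


# ---------------------------------------------------------------------------
# Component registry
# ---------------------------------------------------------------------------


def reference_registry() -> dict[str, Component]:
    """Component registry for the RecO/RecR/SSB-Ct/(dT)L system.

    Peptide and oligo masses come from residue-table summation; RecO and
    RecR monomer masses are not printed anywhere, so they are derived from
    the expected complex masses: the 33.8 kDa single-RecO complex fixes
    RecO, and 4 x M_RecR equals the 121.5 kDa complex minus that.
    """
    m_ssbct = molar_mass_from_sequence(SSB_CT_SEQUENCE, "peptide")
    m_cy3dt15 = molar_mass_from_sequence("T" * 15, "ssDNA", adducts=["Cy3"])
    m_cy3dt35 = molar_mass_from_sequence("T" * 35, "ssDNA", adducts=["Cy3"])
    groups, _ = derive_component_masses_from_complexes(
        [
            ({"RecO_group": 1}, EXPECTED_MASS_RECO_DT15),
            ({"RecO_group": 1, "RecR": 4}, EXPECTED_MASS_RECR4O_DT15),
        ]
    )
    m_reco = groups["RecO_group"] - m_ssbct - m_cy3dt15
    m_recr = groups["RecR"]
    return {
        "RecO": Component(
            "RecO", m_reco, VBAR_RECO, {280.0: 2.44e4}, "protein"
        ),
        "RecR": Component(
            "RecR", m_recr, VBAR_RECR, {280.0: 5.96e3}, "protein"
        ),
        "SSB-Ct": Component(
            "SSB-Ct", m_ssbct, VBAR_SSB_CT, {}, "peptide",
            sequence=SSB_CT_SEQUENCE,
        ),
        "Cy3-dT15": Component(
            "Cy3-dT15", m_cy3dt15, VBAR_DNA,
            {260.0: 15 * 8.1e3, 546.0: CY3_EXTINCTION_546}, "ssDNA",
            sequence="T" * 15,
        ),
        "Cy3-dT35": Component(
            "Cy3-dT35", m_cy3dt35, VBAR_DNA,
            {260.0: 35 * 8.1e3, 546.0: CY3_EXTINCTION_546}, "ssDNA",
            sequence="T" * 35,
        ),
    }


def reference_compositions(
    registry: dict[str, Component] | None = None,
) -> dict[str, Composition]:
    """The candidate complex compositions discussed in the study."""
    reg = registry if registry is not None else reference_registry()
    return {
        "SSBCt-RecO-dT15": Composition(
            [(reg["RecO"], 1), (reg["SSB-Ct"], 1), (reg["Cy3-dT15"], 1)]
        ),
        "SSBCt2-RecO2-dT35": Composition(
            [(reg["RecO"], 2), (reg["SSB-Ct"], 2), (reg["Cy3-dT35"], 1)]
        ),
        "SSBCt-RecR4O-dT15": Composition(
            [
                (reg["RecO"], 1),
                (reg["RecR"], 4),
                (reg["SSB-Ct"], 1),
                (reg["Cy3-dT15"], 1),
            ]
        ),
        "SSBCt2-RecR4O2-dT15_2": Composition(
            [
                (reg["RecO"], 2),
                (reg["RecR"], 4),
                (reg["SSB-Ct"], 2),
                (reg["Cy3-dT15"], 2),
            ]
        ),
    }


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def gen_se_dataset(
    mass: float,
    vbar: float,
    buffer: BufferState,
    speeds=SE_SPEEDS_RPM,
    geometry: CellGeometry = DEFAULT_SE_GEOMETRY,
    noise_sigma: float = DEFAULT_NOISE_AU,
    seed: int | None = None,
    loading: float | None = None,
    r0: float | None = None,
    baseline_range: tuple[float, float] = (-0.02, 0.02),
    scan_step: float = DEFAULT_SCAN_STEP_CM,
) -> list[SEProfile]:
    """Closed-form equilibrium profiles at several rotor speeds.

    The per-speed reference amplitudes are set from one shared sector
    loading signal, so mass conservation holds exactly in the noiseless
    limit.  Baseline offsets are drawn uniformly from ``baseline_range``
    (documented instrument drift scale) and Gaussian noise added per point.

    ``loading`` is the sector-integrated loading signal (AU cm^2); the
    default corresponds to a column-average signal of 0.5 AU, a standard
    absorbance-optics equilibrium loading that keeps the signal-to-noise
    near 100 — the regime in which a two-species control fit can actually
    resolve a sub-percent second component.
    """
    speeds = tuple(float(s) for s in speeds)
    if not speeds:
        raise InvalidInputError("need at least one rotor speed")
    men, bot = geometry.meniscus, geometry.bottom
    if r0 is None:
        r0 = 0.5 * (men + bot)
    if loading is None:
        loading = 0.5 * 0.5 * (bot**2 - men**2)
    radius_grid = np.arange(men, bot + 1e-12, scan_step)
    rng = np.random.default_rng(seed)
    profiles = []
    for rpm in speeds:
        sig = sigma_coefficient(mass, vbar, buffer, rpm)
        if abs(sig) * max(bot**2 - r0**2, r0**2 - men**2) > 600:
            raise InvalidInputError(
                f"exponent overflow for M={mass:.3g} g/mol at {rpm:.0f} rpm; "
                "use a lower rotor speed"
            )
        integral = analytic_sector_integral(
            mass, vbar, buffer, rpm, r0, men, bot
        )
        amplitude = loading / integral
        baseline = rng.uniform(*baseline_range)
        signal = amplitude * np.exp(sig * (radius_grid**2 - r0**2)) + baseline
        if noise_sigma > 0:
            signal = signal + rng.normal(0.0, noise_sigma, radius_grid.size)
        profiles.append(
            SEProfile(
                rpm=rpm,
                radius_grid=radius_grid.copy(),
                signal=signal,
                r0=r0,
                geometry=geometry,
            )
        )
    return profiles


def sv_scan_times(
    s_svedberg: float,
    geometry: CellGeometry = DEFAULT_SV_GEOMETRY,
    rpm: float = SV_RPM,
    n_scans: int = 40,
    first_fraction: float = 0.02,
    last_fraction: float = 0.7,
) -> np.ndarray:
    """Scan schedule covering boundary movement for a species of given s.

    Times span the stated fractions of the meniscus-to-bottom traversal
    time ln(bottom/meniscus) / (s w^2).
    """
    from .physchem import SVEDBERG, omega_from_rpm

    rate = s_svedberg * SVEDBERG * omega_from_rpm(rpm) ** 2
    t_traverse = np.log(geometry.bottom / geometry.meniscus) / rate
    return np.linspace(
        first_fraction * t_traverse, last_fraction * t_traverse, n_scans
    )


def gen_sv_dataset(
    s_values,
    loadings,
    vbar: float,
    buffer: BufferState,
    rpm: float = SV_RPM,
    geometry: CellGeometry = DEFAULT_SV_GEOMETRY,
    times=None,
    noise_sigma: float = DEFAULT_NOISE_AU,
    seed: int | None = None,
    frictional_ratio: float = 1.2,
    n_cells: int = 400,
) -> SVScanSet:
    """Velocity scan set for ideal species at the given s values.

    Diffusion coefficients follow from s through the common frictional
    ratio; the scan schedule defaults to covering the fastest species'
    boundary traversal.
    """
    s_values = np.atleast_1d(np.asarray(s_values, dtype=float))
    loadings = np.atleast_1d(np.asarray(loadings, dtype=float))
    if s_values.size != loadings.size:
        raise InvalidInputError("s_values and loadings differ in length")
    if times is None:
        times = sv_scan_times(float(np.max(s_values)), geometry, rpm)
    species = [
        species_from_s(s, vbar, buffer, loading_signal=a,
                       frictional_ratio=frictional_ratio)
        for s, a in zip(s_values, loadings)
    ]
    return simulate_sv(
        species, geometry, rpm, buffer, times,
        noise_sigma=noise_sigma, seed=seed, n_cells=n_cells,
    )


def gen_titration_series(
    onset_ratio: float,
    post_slope: float = 0.8,
    pre_slope: float = 0.0,
    noise_sigma: float = DEFAULT_TITRATION_NOISE,
    n_points: int = 40,
    ratio_max: float = 16.0,
    initial_intensity: float = 100.0,
    seed: int | None = None,
) -> TitrationSeries:
    """Flat-then-rising titration with a sharp aggregation onset.

    The normalised curve is zero-mean below the onset and rises with the
    given slope above it; Gaussian noise (sigma on the normalised scale)
    is added, then the curve is mapped back to raw counts through the
    normalisation identity I_i = I_0 (1 + I_norm).
    """
    ratios = np.linspace(0.0, ratio_max, n_points)
    clean = hinge_model(ratios, onset_ratio, 0.0, pre_slope, post_slope)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sigma, n_points)
    raw = initial_intensity * (1.0 + noisy)
    return TitrationSeries(
        molar_ratios=ratios,
        intensities=raw,
        initial_intensity=initial_intensity,
        meta={"onset_ratio": onset_ratio, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Named scenarios mirroring the reported study conditions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """A named, fully parameterised synthetic dataset."""

    name: str
    kind: str  # "se" | "sv" | "titration"
    params: dict = field(default_factory=dict)
    seed: int = 0


def scenario_seed(base_seed: int, name: str) -> int:
    """Stable per-scenario seed below 2^31, derived from name + base."""
    return (int(base_seed) ^ zlib.crc32(name.encode())) & 0x7FFFFFFF


def scenario_table(base_seed: int = 0) -> dict[str, ScenarioSpec]:
    """All named scenarios: SE masses, SV s values, titration onsets."""
    comps = reference_compositions()
    table: dict[str, ScenarioSpec] = {}
    se_cases = {
        "SE-33.8k": (EXPECTED_MASS_RECO_DT15, "SSBCt-RecO-dT15"),
        "SE-69.5k": (EXPECTED_MASS_RECO2_DT35, "SSBCt2-RecO2-dT35"),
        "SE-121.5k": (EXPECTED_MASS_RECR4O_DT15, "SSBCt-RecR4O-dT15"),
    }
    for name, (mass, comp_name) in se_cases.items():
        table[name] = ScenarioSpec(
            name=name,
            kind="se",
            params={
                "mass": mass,
                "vbar": composite_vbar(comps[comp_name]),
                "speeds": SE_SPEEDS_RPM,
                "noise_sigma": DEFAULT_NOISE_AU,
                "composition": comp_name,
            },
            seed=scenario_seed(base_seed, name),
        )
    dna_alone = {0.5, 0.7, 0.9, 1.2}
    vbar_complex = composite_vbar(comps["SSBCt-RecR4O-dT15"])
    loading = DNA_CONC_M * CY3_EXTINCTION_546 * PATHLENGTH_CM
    for s in PRINTED_S_VALUES:
        name = f"SV-{s:g}S"
        table[name] = ScenarioSpec(
            name=name,
            kind="sv",
            params={
                "s": s,
                "vbar": VBAR_DNA if s in dna_alone else vbar_complex,
                "loading": loading,
                "rpm": SV_RPM,
                "noise_sigma": DEFAULT_NOISE_AU,
            },
            seed=scenario_seed(base_seed, name),
        )
    for dna, onset in ONSET_RATIOS.items():
        name = f"TIT-{dna}"
        table[name] = ScenarioSpec(
            name=name,
            kind="titration",
            params={
                "onset_ratio": onset,
                "post_slope": 0.8,
                "noise_sigma": DEFAULT_TITRATION_NOISE,
            },
            seed=scenario_seed(base_seed, name),
        )
    return table


def generate_scenario(
    spec: ScenarioSpec, buffer: BufferState | None = None
):
    """Materialise one scenario into its dataset object."""
    buf = buffer if buffer is not None else BufferState()
    p = spec.params
    if spec.kind == "se":
        return gen_se_dataset(
            mass=p["mass"], vbar=p["vbar"], buffer=buf,
            speeds=p.get("speeds", SE_SPEEDS_RPM),
            noise_sigma=p.get("noise_sigma", DEFAULT_NOISE_AU),
            seed=spec.seed,
        )
    if spec.kind == "sv":
        return gen_sv_dataset(
            [p["s"]], [p.get("loading", 0.1)], p["vbar"], buf,
            rpm=p.get("rpm", SV_RPM),
            noise_sigma=p.get("noise_sigma", DEFAULT_NOISE_AU),
            seed=spec.seed,
        )
    if spec.kind == "titration":
        return gen_titration_series(
            onset_ratio=p["onset_ratio"],
            post_slope=p.get("post_slope", 0.8),
            noise_sigma=p.get("noise_sigma", DEFAULT_TITRATION_NOISE),
            seed=spec.seed,
        )
    raise InvalidInputError(f"unknown scenario kind {spec.kind!r}")


def gen_study_scenarios(base_seed: int = 0, kinds=("se", "titration")):
    """Generate the named scenario bundle (SE + titration by default).

    Velocity scenarios are listed in :func:`scenario_table` but generated
    lazily via :func:`generate_scenario` because each one solves the Lamm
    equation; pass ``kinds=("se", "sv", "titration")`` to materialise all.
    """
    out = {}
    for name, spec in scenario_table(base_seed).items():
        if spec.kind not in kinds:
            continue
        out[name] = (spec, generate_scenario(spec))
    return out
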