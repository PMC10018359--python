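"""Components, compositions, buffers, and mass/buoyancy arithmetic.

Everything downstream of the raw scans is bookkeeping in four numbers per
solute: molar mass M (g/mol), partial specific volume vbar (ml/g), molar
extinction epsilon (M^-1 cm^-1) and copy number n.  This module owns those
numbers and the handful of exact formulas that combine them:

* the mass-weighted composite partial specific volume of a complex,
  vbar = sum(n_i M_i vbar_i) / sum(n_i M_i), assuming volume additivity;
* the buoyant mass factor M (1 - vbar * rho) that drives sedimentation;
* residue-table molar masses for peptides and oligodeoxynucleotides;
* Beer-Lambert concentration from absorbance.

Units are CGS throughout the package: radii in cm, time in s, mass in g/mol,
the gas constant in erg mol^-1 K^-1, and sedimentation coefficients in
Svedberg (1 S = 1e-13 s).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .exceptions import InvalidInputError

# ---------------------------------------------------------------------------
# Physical constants (CGS)
# ---------------------------------------------------------------------------

#: Gas constant, erg mol^-1 K^-1.
R_GAS = 8.31446e7
#: Boltzmann constant, erg K^-1.
K_BOLTZMANN = 1.380649e-16
#: Avogadro's number, mol^-1.
N_AVOGADRO = 6.02214076e23
#: One Svedberg in seconds.
SVEDBERG = 1e-13

COMPONENT_KINDS = ("protein", "peptide", "ssDNA", "dsDNA", "dye")


def omega_from_rpm(rpm: float) -> float:
    """Angular velocity (rad/s) of a rotor spinning at `rpm` rev/min."""
    import math

    return 2.0 * math.pi * rpm / 60.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Component:
    """One molecular species with its sedimentation-relevant constants.

    Parameters
    ----------
    name : str
        Identifier used in compositions and registry files.
    molar_mass : float
        Molar mass in g/mol; must be positive.
    vbar : float
        Partial specific volume in ml/g; physically sensible range
        (0.4, 1.0) is enforced (nucleic acids ~0.55, proteins ~0.70-0.75).
    extinction : mapping, optional
        Wavelength (nm) -> molar extinction coefficient (M^-1 cm^-1).
    kind : str
        One of protein | peptide | ssDNA | dsDNA | dye.
    sequence : str, optional
        Residue sequence the mass was derived from, if any.
    """

    name: str
    molar_mass: float
    vbar: float
    extinction: Mapping[float, float] = field(default_factory=dict)
    kind: str = "protein"
    sequence: str | None = None

    def __post_init__(self):
        if not self.name:
            raise InvalidInputError("component name must be non-empty")
        if not self.molar_mass > 0:
            raise InvalidInputError(
                f"component {self.name!r}: molar_mass must be > 0, "
                f"got {self.molar_mass}"
            )
        if not 0.4 < self.vbar < 1.0:
            raise InvalidInputError(
                f"component {self.name!r}: vbar must lie in (0.4, 1.0) ml/g, "
                f"got {self.vbar}"
            )
        for wl, eps in dict(self.extinction).items():
            if not eps > 0:
                raise InvalidInputError(
                    f"component {self.name!r}: extinction at {wl} nm must be "
                    f"> 0, got {eps}"
                )
        if self.kind not in COMPONENT_KINDS:
            raise InvalidInputError(
                f"component {self.name!r}: kind must be one of "
                f"{COMPONENT_KINDS}, got {self.kind!r}"
            )


@dataclass(frozen=True)
class Composition:
    """An integer-stoichiometry assembly of components.

    ``entries`` is a sequence of ``(component, copy_number)`` pairs with
    non-negative integer copies and at least one copy overall.
    """

    entries: tuple[tuple[Component, int], ...]

    def __init__(self, entries: Sequence[tuple[Component, int]]):
        entries = tuple((c, int(n)) for c, n in entries)
        for comp, n in entries:
            if n < 0:
                raise InvalidInputError(
                    f"copy number for {comp.name!r} must be >= 0, got {n}"
                )
        if not any(n >= 1 for _, n in entries):
            raise InvalidInputError(
                "composition must contain at least one copy of something"
            )
        object.__setattr__(self, "entries", entries)

    @property
    def molar_mass(self) -> float:
        """Total molar mass, sum(n_i * M_i), g/mol."""
        return sum(n * c.molar_mass for c, n in self.entries)

    def formula(self) -> str:
        """Human-readable stoichiometry string, e.g. ``RecO×1·RecR×4``."""
        parts = [f"{c.name}×{n}" for c, n in self.entries if n > 0]
        return "·".join(parts)


@dataclass(frozen=True)
class BufferState:
    """Solvent state entering the buoyancy and diffusion formulas.

    density in g/ml, viscosity in poise (g cm^-1 s^-1), temperature in K.
    Density and viscosity are user inputs (measured or tabulated
    externally); the package never estimates them from buffer recipes.
    """

    density: float = 1.05
    viscosity: float = 0.010
    temperature: float = 298.15

    def __post_init__(self):
        if not 0.9 < self.density < 1.3:
            raise InvalidInputError(
                f"buffer density must lie in (0.9, 1.3) g/ml, "
                f"got {self.density}"
            )
        if not self.viscosity > 0:
            raise InvalidInputError("buffer viscosity must be > 0 poise")
        if not self.temperature > 0:
            raise InvalidInputError("temperature must be > 0 K")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def composite_vbar(composition: Composition) -> float:
    """Mass-weighted partial specific volume of a complex, ml/g.

    Assumes volume additivity:
    vbar = sum(n_i M_i vbar_i) / sum(n_i M_i).  The result is bounded by
    the smallest and largest component vbar.
    """
    entries = [(c, n) for c, n in composition.entries if n > 0]
    if not entries:
        raise InvalidInputError("empty composition")
    num = sum(n * c.molar_mass * c.vbar for c, n in entries)
    den = sum(n * c.molar_mass for c, n in entries)
    return num / den


def buoyant_factor(molar_mass: float, vbar: float, density: float) -> float:
    """Buoyant molar mass M (1 - vbar * rho), g/mol.

    Positive when the solute is denser than the buffer (it sediments),
    zero at neutral buoyancy, negative when it floats.
    """
    if molar_mass <= 0 or vbar <= 0 or density <= 0:
        raise InvalidInputError(
            "molar_mass, vbar and density must all be positive"
        )
    return molar_mass * (1.0 - vbar * density)


def vbar_percent_difference(measured: float, calculated: float) -> float:
    """Percent deviation of a measured vbar from a calculated one.

    Uses the calculated value as denominator and reports one decimal:
    100 * |calculated - measured| / calculated.
    """
    if calculated == 0:
        raise InvalidInputError("calculated vbar must be nonzero")
    if measured <= 0 or calculated <= 0:
        raise InvalidInputError("vbar values must be positive")
    return round(100.0 * abs(calculated - measured) / calculated, 1)


def _load_mass_tables() -> dict:
    ref = importlib.resources.files("sedstoich.data") / "residue_masses.yaml"
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


_MASS_TABLES: dict | None = None


def mass_tables() -> dict:
    """The documented residue/adduct average-mass tables (g/mol)."""
    global _MASS_TABLES
    if _MASS_TABLES is None:
        _MASS_TABLES = _load_mass_tables()
    return _MASS_TABLES


def molar_mass_from_sequence(
    sequence: str,
    kind: str,
    adducts: Sequence[str] = (),
) -> float:
    """Average molar mass of a peptide or ssDNA oligo from its sequence.

    Sums the per-residue masses of the documented table, applies the
    terminal correction for the chain chemistry (peptide: + one water;
    ssDNA: 5'-OH/3'-OH ends), and adds any named adduct masses (e.g. the
    Cy3 label).
    """
    if kind not in ("peptide", "ssDNA"):
        raise InvalidInputError(
            f"kind must be 'peptide' or 'ssDNA', got {kind!r}"
        )
    if not sequence:
        raise InvalidInputError("sequence must be non-empty")
    tables = mass_tables()
    table = tables[kind]["residues"]
    total = 0.0
    for i, ch in enumerate(sequence.upper()):
        if ch not in table:
            raise InvalidInputError(
                f"unknown {kind} residue {ch!r} at position {i} "
                f"in {sequence!r}"
            )
        total += table[ch]
    total += tables[kind]["terminal_correction"]
    for name in adducts:
        if name not in tables["adducts"]:
            raise InvalidInputError(f"unknown adduct {name!r}")
        total += tables["adducts"][name]
    return total


def concentration_from_absorbance(
    absorbance: float, epsilon: float, pathlength: float = 1.2
) -> float:
    """Beer-Lambert molar concentration A / (epsilon * l).

    `pathlength` in cm (standard AUC centerpiece is 1.2 cm).
    """
    if epsilon <= 0 or pathlength <= 0:
        raise InvalidInputError("epsilon and pathlength must be positive")
    if absorbance < 0:
        raise InvalidInputError("absorbance must be >= 0")
    return absorbance / (epsilon * pathlength)
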