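"""Complex-stoichiometry inference from fitted molar masses.

A sedimentation-equilibrium fit delivers a molar mass M +/- SE for the
sedimenting complex.  Which integer combination of the known components
(protein protomers, peptide, labelled oligonucleotide) is consistent with
it?  This module enumerates the bounded integer lattice of copy numbers,
applies declarative biological constraints (e.g. RecR comes in dimers or
tetramers; at most one SSB-Ct peptide per RecO protomer), and ranks the
candidates by |predicted - fitted| mass.  A candidate is "within window"
when its deviation is at most ``window_k`` standard errors — the default of
2 SE corresponds to the conventional ~95% interval.

The inverse problem is also provided: given printed complex masses and
their known composition patterns, solve the linear system for the
component (or component-group) masses by least squares.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exceptions import InvalidInputError, UnidentifiableError
from .physchem import Component, Composition


@dataclass(frozen=True)
class StoichMatch:
    """One candidate composition scored against a fitted mass."""

    composition: Composition
    predicted_mass: float
    deviation: float
    within_window: bool


@dataclass(frozen=True)
class CopyRule:
    """A declarative constraint on copy numbers.

    Two forms:
      * allowed-set: ``CopyRule(component="RecR", allowed=(0, 2, 4))``
      * inequality:  ``CopyRule(component="SSB-Ct", op="<=", other="RecO")``
        meaning copies(component) <= copies(other).
    """

    component: str
    allowed: tuple[int, ...] | None = None
    op: str | None = None
    other: str | None = None

    def __post_init__(self):
        if (self.allowed is None) == (self.op is None):
            raise InvalidInputError(
                "rule must set exactly one of 'allowed' or 'op'/'other'"
            )
        if self.op is not None and self.op not in ("<=", ">=", "=="):
            raise InvalidInputError(f"unsupported rule operator {self.op!r}")
        if self.op is not None and self.other is None:
            raise InvalidInputError("inequality rule needs 'other'")

    def satisfied(self, counts: Mapping[str, int]) -> bool:
        n = counts.get(self.component, 0)
        if self.allowed is not None:
            return n in self.allowed
        m = counts.get(self.other, 0)
        if self.op == "<=":
            return n <= m
        if self.op == ">=":
            return n >= m
        return n == m


def enumerate_matches(
    fitted_mass: float,
    std_error: float,
    registry: Sequence[Component],
    bounds: Mapping[str, int],
    constraints: Sequence[CopyRule] = (),
    window_k: float = 2.0,
) -> list[StoichMatch]:
    """Rank every constrained composition by deviation from a fitted mass.

    ``bounds`` caps the copy number per component name (components absent
    from ``bounds`` get 0 copies, i.e. are excluded).  The returned list is
    totally ordered: primary key deviation, ties broken lexicographically
    by copy-number vector in registry order, so the ranking is
    deterministic.  The empty composition is not a candidate.
    """
    if not registry:
        raise InvalidInputError("component registry is empty")
    if window_k <= 0:
        raise InvalidInputError("window_k must be > 0")
    if std_error < 0:
        raise InvalidInputError("std_error must be >= 0")
    names = [c.name for c in registry]
    maxima = [int(bounds.get(n, 0)) for n in names]
    if any(m < 0 for m in maxima):
        raise InvalidInputError("bounds must be non-negative")

    matches: list[tuple[float, tuple[int, ...], StoichMatch]] = []
    for counts_vec in itertools.product(*(range(m + 1) for m in maxima)):
        if sum(counts_vec) == 0:
            continue
        counts = dict(zip(names, counts_vec))
        if not all(rule.satisfied(counts) for rule in constraints):
            continue
        comp = Composition(
            [(c, n) for c, n in zip(registry, counts_vec)]
        )
        predicted = comp.molar_mass
        deviation = abs(predicted - fitted_mass)
        match = StoichMatch(
            composition=comp,
            predicted_mass=predicted,
            deviation=deviation,
            within_window=bool(deviation <= window_k * std_error),
        )
        matches.append((deviation, counts_vec, match))
    matches.sort(key=lambda t: (t[0], t[1]))
    return [m for _, _, m in matches]


def within_window(matches: Sequence[StoichMatch]) -> list[StoichMatch]:
    """The subset of a ranking that lies inside the error window."""
    return [m for m in matches if m.within_window]


def derive_component_masses_from_complexes(
    equations: Sequence[tuple[Mapping[str, int], float]],
) -> tuple[dict[str, float], float]:
    """Solve component masses from known complex masses by least squares.

    ``equations`` is a list of (composition pattern, total mass) pairs,
    each pattern mapping component name -> copy number.  Returns the
    least-squares masses and the residual norm.  If the system cannot pin
    down every unknown individually, raises UnidentifiableError listing
    the unknowns that *are* identifiable.
    """
    if not equations:
        raise InvalidInputError("no equations given")
    names = sorted({n for pattern, _ in equations for n in pattern})
    a = np.zeros((len(equations), len(names)))
    b = np.zeros(len(equations))
    for i, (pattern, total) in enumerate(equations):
        for name, copies in pattern.items():
            a[i, names.index(name)] = copies
        b[i] = total
    rank = np.linalg.matrix_rank(a)
    if rank < len(names):
        # an unknown is identifiable iff it has no null-space component
        _, _, vt = np.linalg.svd(a)
        null = vt[rank:]
        solvable = [
            names[j]
            for j in range(len(names))
            if np.all(np.abs(null[:, j]) < 1e-10)
        ]
        raise UnidentifiableError(
            f"system of {len(equations)} equations cannot determine all of "
            f"{names}; individually solvable: {solvable or 'none'}",
            solvable=solvable,
        )
    sol, residual, *_ = np.linalg.lstsq(a, b, rcond=None)
    res_norm = float(np.sqrt(residual[0])) if residual.size else float(
        np.linalg.norm(a @ sol - b)
    )
    return dict(zip(names, sol.tolist())), res_norm
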