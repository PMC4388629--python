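"""Collective variables and harmonic restraints for coordinate driving.

Two CV families are provided, matching what reaction-coordinate driving of a
nucleophilic substitution coupled to a proton transfer needs:

* :class:`DistanceCV` — a plain interatomic distance d(i, j), Å.
* :class:`DistanceDifferenceCV` — d(i, j) − d(k, l), Å; the natural
  coordinate for coupled bond formation/dissociation (one distance shrinks
  while the other grows, so a single coordinate spans the whole event).

Harmonic restraints ``½ k (cv − target)²`` bias any energy model;
:func:`biased_model` keeps base-model and bias energies separately so scan
maps can store the unbiased physical energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import EnergyEvaluation, EnergyModel
from .structures import Structure

_MIN_PAIR_DISTANCE = 1e-8


class DegenerateGeometryError(ValueError):
    """A CV pair has (numerically) coincident atoms; unit vector undefined."""


@dataclass(frozen=True)
class DistanceCV:
    """Interatomic distance d(i, j) in Å."""

    i: int
    j: int
    name: str = ""

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("distance CV needs two distinct atoms")

    def value(self, structure: Structure) -> float:
        return _pair_distance(structure, self.i, self.j)

    def gradient(self, structure: Structure) -> np.ndarray:
        grad = np.zeros_like(structure.coords)
        u = _pair_unit(structure, self.i, self.j)
        grad[self.i] = -u
        grad[self.j] = u
        return grad


@dataclass(frozen=True)
class DistanceDifferenceCV:
    """d(i, j) − d(k, l) in Å; atoms may be shared between the two pairs."""

    i: int
    j: int
    k: int
    l: int
    name: str = ""

    def __post_init__(self):
        if self.i == self.j or self.k == self.l:
            raise ValueError("each pair needs two distinct atoms")
        if {self.i, self.j} == {self.k, self.l}:
            raise ValueError("the two pairs must differ")

    def value(self, structure: Structure) -> float:
        return _pair_distance(structure, self.i, self.j) - _pair_distance(
            structure, self.k, self.l
        )

    def gradient(self, structure: Structure) -> np.ndarray:
        grad = np.zeros_like(structure.coords)
        u1 = _pair_unit(structure, self.i, self.j)
        u2 = _pair_unit(structure, self.k, self.l)
        grad[self.i] -= u1
        grad[self.j] += u1
        grad[self.k] += u2
        grad[self.l] -= u2
        return grad


CV = DistanceCV | DistanceDifferenceCV


def _pair_distance(structure: Structure, i: int, j: int) -> float:
    d = float(np.linalg.norm(structure.coords[j] - structure.coords[i]))
    return d


def _pair_unit(structure: Structure, i: int, j: int) -> np.ndarray:
    d = structure.coords[j] - structure.coords[i]
    r = float(np.linalg.norm(d))
    if r < _MIN_PAIR_DISTANCE:
        raise DegenerateGeometryError(f"atoms {i} and {j} coincide (r = {r:g} Å)")
    return d / r


def cv_value(cv: CV, structure: Structure) -> float:
    """Evaluate a collective variable, Å."""
    return cv.value(structure)


def cv_gradient(cv: CV, structure: Structure) -> np.ndarray:
    """Per-atom gradient of the CV; nonzero only at participating atoms."""
    return cv.gradient(structure)


@dataclass(frozen=True)
class HarmonicRestraint:
    """Harmonic bias ½ k (cv − target)² with k in Hartree Å⁻²."""

    cv: CV
    target: float
    force_constant: float = 0.5

    def __post_init__(self):
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")


def restraint_terms(
    restraint: HarmonicRestraint, structure: Structure
) -> tuple[float, np.ndarray]:
    """Bias energy (Hartree) and its Cartesian gradient (Hartree Å⁻¹)."""
    delta = cv_value(restraint.cv, structure) - restraint.target
    energy = 0.5 * restraint.force_constant * delta**2
    grad = restraint.force_constant * delta * cv_gradient(restraint.cv, structure)
    return energy, grad


class BiasedModel(EnergyModel):
    """Base model plus harmonic restraints, with component bookkeeping.

    ``evaluate`` returns the total (base + bias); :meth:`evaluate_components`
    exposes the unbiased base energy, which is what scan maps store.
    """

    def __init__(self, base: EnergyModel, restraints: list[HarmonicRestraint]):
        self.base = base
        self.restraints = list(restraints)

    def check(self, structure: Structure) -> None:
        self.base.check(structure)
        n = structure.n_atoms
        for r in self.restraints:
            atoms = (
                (r.cv.i, r.cv.j)
                if isinstance(r.cv, DistanceCV)
                else (r.cv.i, r.cv.j, r.cv.k, r.cv.l)
            )
            if any(a < 0 or a >= n for a in atoms):
                raise ValueError(f"restraint references atom out of range (n={n})")

    def evaluate(self, structure: Structure) -> EnergyEvaluation:
        total, _, grad = self.evaluate_components(structure)
        return EnergyEvaluation(energy=total, gradient=grad)

    def evaluate_components(
        self, structure: Structure
    ) -> tuple[float, float, np.ndarray]:
        """Return (total energy, base energy, total gradient)."""
        ev = self.base.evaluate(structure)
        energy = ev.energy
        grad = ev.gradient.copy()
        bias = 0.0
        for r in self.restraints:
            e, g = restraint_terms(r, structure)
            bias += e
            grad += g
        return energy + bias, energy, grad


def biased_model(base: EnergyModel, *restraints: HarmonicRestraint) -> BiasedModel:
    """Convenience constructor for :class:`BiasedModel`."""
    return BiasedModel(base, list(restraints))
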