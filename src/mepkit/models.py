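"""Energy-model contract and built-in analytic benchmark surfaces.

Every stage of the toolkit (scans, NEB, transition-state refinement) talks to
an :class:`EnergyModel`: anything that can return a potential energy (Hartree)
and its analytic Cartesian gradient (Hartree Å⁻¹) for a :class:`Structure`.
Built-ins include the Müller-Brown two-dimensional benchmark surface, generic
closed-form 2D surfaces embedded as single-particle structures, and simple
bonded models used as test oracles.  The synthetic reactive molecular model
lives in :mod:`mepkit.toysni`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .structures import Structure


@dataclass
class EnergyEvaluation:
    """Energy (Hartree, or model units for abstract surfaces) and gradient."""

    energy: float
    gradient: np.ndarray  # (n_atoms, 3), Hartree Å⁻¹


class ModelError(ValueError):
    """Structure incompatible with the model (atom count, roles, geometry)."""


class EnergyModel:
    """Contract: deterministic energy + analytic gradient for a structure."""

    def evaluate(self, structure: Structure) -> EnergyEvaluation:
        raise NotImplementedError

    def check(self, structure: Structure) -> None:
        """Raise :class:`ModelError` when the structure is unusable."""
        if not np.all(np.isfinite(structure.coords)):
            raise ModelError("non-finite geometry")


def evaluate(model: EnergyModel, structure: Structure) -> EnergyEvaluation:
    """Evaluate ``model`` on ``structure`` after validating compatibility."""
    model.check(structure)
    ev = model.evaluate(structure)
    if not np.isfinite(ev.energy):
        raise ModelError("model returned non-finite energy")
    if ev.gradient.shape != structure.coords.shape:
        raise ModelError(
            f"gradient shape {ev.gradient.shape} != coords shape {structure.coords.shape}"
        )
    return ev


# ---------------------------------------------------------------------------
# Analytic 2D surfaces embedded as one-particle structures
# ---------------------------------------------------------------------------

class AnalyticSurface2D(EnergyModel):
    """A closed-form surface E(x, y) exposed through the structure contract.

    The embedding rule: a single abstract particle whose (x, y) coordinates
    are the surface coordinates; the z component is ignored (zero gradient).
    """

    def __init__(self, fn: Callable[[float, float], tuple[float, np.ndarray]]):
        self._fn = fn

    def check(self, structure: Structure) -> None:
        super().check(structure)
        if structure.n_atoms != 1:
            raise ModelError("AnalyticSurface2D expects a single-particle structure")

    def evaluate(self, structure: Structure) -> EnergyEvaluation:
        x, y = structure.coords[0, 0], structure.coords[0, 1]
        e, g2 = self._fn(x, y)
        grad = np.zeros_like(structure.coords)
        grad[0, :2] = g2
        return EnergyEvaluation(energy=float(e), gradient=grad)

    def structure_at(self, x: float, y: float) -> Structure:
        return Structure(labels=["X"], coords=np.array([[x, y, 0.0]]))


# Müller-Brown parameters as originally published.
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


def muller_brown(x: float, y: float) -> tuple[float, np.ndarray]:
    """Müller-Brown benchmark surface: energy and analytic 2-gradient.

    Sum of four Gaussian-form terms
    ``A_k exp(a_k (x-x0)^2 + b_k (x-x0)(y-y0) + c_k (y-y0)^2)``.
    Energies are in the model's own units (the deepest minimum is ≈ −146.7).
    """
    dx = x - _MB_x0
    dy = y - _MB_y0
    terms = _MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)
    e = float(terms.sum())
    gx = float(np.sum(terms * (2.0 * _MB_a * dx + _MB_b * dy)))
    gy = float(np.sum(terms * (_MB_b * dx + 2.0 * _MB_c * dy)))
    return e, np.array([gx, gy])


def muller_brown_hessian(x: float, y: float) -> np.ndarray:
    """Analytic 2×2 Hessian of the Müller-Brown surface."""
    dx = x - _MB_x0
    dy = y - _MB_y0
    t = _MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)
    px = 2.0 * _MB_a * dx + _MB_b * dy
    py = _MB_b * dx + 2.0 * _MB_c * dy
    hxx = float(np.sum(t * (px**2 + 2.0 * _MB_a)))
    hyy = float(np.sum(t * (py**2 + 2.0 * _MB_c)))
    hxy = float(np.sum(t * (px * py + _MB_b)))
    return np.array([[hxx, hxy], [hxy, hyy]])


class MullerBrown(AnalyticSurface2D):
    """The Müller-Brown surface as an :class:`EnergyModel`."""

    #: Approximate locations of the three minima (deepest first) and the two
    #: saddles; used as starting guesses only — tests refine them numerically.
    MINIMA_GUESS = ((-0.558, 1.442), (0.623, 0.028), (-0.050, 0.467))
    SADDLES_GUESS = ((-0.822, 0.624), (0.212, 0.293))

    def __init__(self) -> None:
        super().__init__(muller_brown)


# ---------------------------------------------------------------------------
# Simple bonded models (test oracles and optimizer fixtures)
# ---------------------------------------------------------------------------

class HarmonicDiatomic(EnergyModel):
    """E = ½ k (r01 − r0)² for a two-atom structure; closed-form testbed."""

    def __init__(self, k: float, r0: float):
        self.k = float(k)
        self.r0 = float(r0)

    def check(self, structure: Structure) -> None:
        super().check(structure)
        if structure.n_atoms != 2:
            raise ModelError("HarmonicDiatomic expects exactly 2 atoms")

    def evaluate(self, structure: Structure) -> EnergyEvaluation:
        d = structure.coords[1] - structure.coords[0]
        r = float(np.linalg.norm(d))
        if r < 1e-12:
            raise ModelError("coincident atoms")
        u = d / r
        e = 0.5 * self.k * (r - self.r0) ** 2
        f = self.k * (r - self.r0)
        grad = np.zeros_like(structure.coords)
        grad[0] = -f * u
        grad[1] = f * u
        return EnergyEvaluation(energy=e, gradient=grad)


class QuadraticField(EnergyModel):
    """E = ½ (x−x*)ᵀ H (x−x*) over all flattened coordinates; exact testbed."""

    def __init__(self, hessian: np.ndarray, center: np.ndarray):
        self.hessian = np.asarray(hessian, dtype=float)
        self.center = np.asarray(center, dtype=float).ravel()

    def evaluate(self, structure: Structure) -> EnergyEvaluation:
        x = structure.coords.ravel() - self.center
        g = self.hessian @ x
        return EnergyEvaluation(
            energy=0.5 * float(x @ g),
            gradient=g.reshape(structure.coords.shape),
        )


# ---------------------------------------------------------------------------
# Finite-difference gradient (oracle)
# ---------------------------------------------------------------------------

def fd_gradient(model: EnergyModel, structure: Structure, h: float = 1e-4) -> np.ndarray:
    """Symmetric central-difference gradient; the test oracle for analytic ones.

    Computes every row, including frozen/env atoms — masking is the
    optimizer's responsibility, not the differentiator's.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    grad = np.zeros_like(structure.coords)
    for i in range(structure.n_atoms):
        for d in range(3):
            plus = structure.coords.copy()
            minus = structure.coords.copy()
            plus[i, d] += h
            minus[i, d] -= h
            ep = model.evaluate(structure.with_coords(plus)).energy
            em = model.evaluate(structure.with_coords(minus)).energy
            grad[i, d] = (ep - em) / (2.0 * h)
    return grad
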