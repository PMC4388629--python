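"""Geometry minimizers: BFGS, (scaled) conjugate gradient and FIRE.

All minimizers share the same convergence contract: stop at the first
geometry whose maximum absolute gradient component over *mobile* atoms drops
below ``ConvergenceSpec.gmax`` (Hartree Å⁻¹).  Frozen and environment atoms
are never moved by the outer minimizers; environment atoms are relaxed by
:func:`nested_evaluate` / :class:`NestedModel`, which re-minimizes them to
their own (kcal mol⁻¹ Å⁻¹) tolerance before every outer gradient evaluation —
the adiabatic two-layer protocol of QM/MM geometry optimization.

Quasi-Newton (BFGS) and conjugate-gradient driving delegate to
``scipy.optimize.minimize`` with an infinity-norm gradient criterion, which
is exactly the max-component contract.  FIRE is implemented here; it is the
driver of choice for Nudged Elastic Band forces, which are non-conservative
(no symmetric Hessian exists), where quasi-Newton methods are unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .models import EnergyEvaluation, EnergyModel
from .structures import Structure
from .units import KCAL_PER_MOL_TO_HARTREE


@dataclass(frozen=True)
class ConvergenceSpec:
    """Stop when max |gradient component| over mobile atoms < gmax."""

    gmax: float = 0.01  # Hartree Å⁻¹
    max_steps: int = 2000

    def __post_init__(self):
        if self.gmax <= 0:
            raise ValueError("gmax must be positive")


@dataclass
class OptimizationResult:
    structure: Structure
    energy: float
    trace: list[tuple[float, float]]  # (energy, gmax) per accepted step
    converged: bool
    n_steps: int


class ConvergenceError(RuntimeError):
    """Raised on non-convergence; carries the best-so-far result."""

    def __init__(self, message: str, best: OptimizationResult):
        super().__init__(message)
        self.best = best


def _free_indices(structure: Structure) -> np.ndarray:
    idx = np.flatnonzero(structure.mobile_mask)
    if idx.size == 0:
        raise ValueError("no mobile atoms to optimize")
    return idx


def _gmax(gradient: np.ndarray, idx: np.ndarray) -> float:
    return float(np.abs(gradient[idx]).max())


def _scipy_drive(
    method: str,
    model: EnergyModel,
    structure: Structure,
    spec: ConvergenceSpec,
) -> OptimizationResult:
    idx = _free_indices(structure)
    coords0 = structure.coords.copy()
    work = structure.copy()

    ev0 = model.evaluate(structure)
    g0 = _gmax(ev0.gradient, idx)
    trace = [(ev0.energy, g0)]
    if g0 < spec.gmax:
        return OptimizationResult(structure.copy(), ev0.energy, trace, True, 0)

    last = {"energy": ev0.energy, "gmax": g0}

    def fun(x: np.ndarray):
        c = coords0.copy()
        c[idx] = x.reshape(-1, 3)
        work.coords = c
        ev = model.evaluate(work)
        last["energy"] = ev.energy
        last["gmax"] = _gmax(ev.gradient, idx)
        return ev.energy, ev.gradient[idx].ravel()

    def cb(xk):
        trace.append((last["energy"], last["gmax"]))

    res = _scipy_minimize(
        fun,
        coords0[idx].ravel(),
        jac=True,
        method=method,
        callback=cb,
        options={"gtol": spec.gmax, "norm": np.inf, "maxiter": spec.max_steps},
    )
    final = coords0.copy()
    final[idx] = res.x.reshape(-1, 3)
    out = structure.with_coords(final)
    ev = model.evaluate(out)
    gm = _gmax(ev.gradient, idx)
    result = OptimizationResult(out, ev.energy, trace, gm < spec.gmax, res.nit)
    if not result.converged:
        raise ConvergenceError(
            f"{method} did not reach gmax {spec.gmax:g} within "
            f"{spec.max_steps} steps (final gmax {gm:g})",
            result,
        )
    return result


def minimize_bfgs(
    model: EnergyModel, structure: Structure, spec: ConvergenceSpec | None = None
) -> OptimizationResult:
    """Quasi-Newton (BFGS Hessian updates) minimization of mobile atoms."""
    return _scipy_drive("BFGS", model, structure, spec or ConvergenceSpec())


def minimize_scg(
    model: EnergyModel,
    structure: Structure,
    gmax_kcal: float = 0.01,
    max_steps: int = 5000,
) -> OptimizationResult:
    """Conjugate-gradient minimization with threshold in kcal mol⁻¹ Å⁻¹.

    This is the environment-relaxation workhorse; its convergence criterion
    is quoted in MM-native units and converted internally.
    """
    spec = ConvergenceSpec(gmax=gmax_kcal * KCAL_PER_MOL_TO_HARTREE, max_steps=max_steps)
    return _scipy_drive("CG", model, structure, spec)


# ---------------------------------------------------------------------------
# Nested (two-layer) evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvironmentSpec:
    """Relaxation tolerance for environment atoms, kcal mol⁻¹ Å⁻¹."""

    gmax_kcal: float = 0.01
    max_steps: int = 5000


def nested_evaluate(
    model: EnergyModel,
    structure: Structure,
    env_spec: EnvironmentSpec | None = None,
) -> tuple[EnergyEvaluation, Structure]:
    """Relax ``env`` atoms fully, then evaluate at the relaxed geometry.

    Returns the evaluation and the structure with relaxed environment.  With
    no environment atoms this is a plain evaluation.
    """
    env_spec = env_spec or EnvironmentSpec()
    if not structure.env_mask.any():
        return model.evaluate(structure), structure.copy()
    inner = structure.copy()
    inner.roles = np.where(structure.env_mask, "mobile", "frozen")
    res = minimize_scg(model, inner, gmax_kcal=env_spec.gmax_kcal,
                       max_steps=env_spec.max_steps)
    relaxed = structure.with_coords(res.structure.coords)
    return model.evaluate(relaxed), relaxed


class NestedModel(EnergyModel):
    """Wraps a model so every evaluation first relaxes environment atoms.

    Keeps the last relaxed environment as the warm start for the next call,
    so outer optimizers see a smooth effective surface for the mobile atoms.
    """

    def __init__(self, base: EnergyModel, template: Structure,
                 env_spec: EnvironmentSpec | None = None):
        self.base = base
        self.env_spec = env_spec or EnvironmentSpec()
        self._template = template.copy()
        self._env_coords = template.coords[template.env_mask].copy()

    def check(self, structure: Structure) -> None:
        self.base.check(structure)

    def evaluate(self, structure: Structure) -> EnergyEvaluation:
        work = self._template.copy()
        work.coords = structure.coords.copy()
        work.coords[work.env_mask] = self._env_coords
        ev, relaxed = nested_evaluate(self.base, work, self.env_spec)
        self._env_coords = relaxed.coords[relaxed.env_mask].copy()
        grad = ev.gradient.copy()
        grad[relaxed.env_mask] = 0.0  # relaxed to its own tolerance
        return EnergyEvaluation(energy=ev.energy, gradient=grad)

    @property
    def relaxed_env_coords(self) -> np.ndarray:
        return self._env_coords.copy()


# ---------------------------------------------------------------------------
# FIRE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FIREParams:
    """Fast Inertial Relaxation Engine parameters (original defaults).

    ``dt`` carries the internal time unit (unit masses); ``max_disp`` caps
    the per-step displacement of any degree of freedom, Å.
    """

    dt_init: float = 0.1
    dt_max: float = 1.0
    n_min: int = 5
    f_inc: float = 1.1
    f_dec: float = 0.5
    alpha_start: float = 0.1
    f_alpha: float = 0.99
    max_disp: float = 0.2

    def __post_init__(self):
        if not (0 < self.f_dec < 1 < self.f_inc):
            raise ValueError("need 0 < f_dec < 1 < f_inc")
        if not (0 < self.alpha_start < 1):
            raise ValueError("need 0 < alpha_start < 1")


@dataclass
class FIREState:
    """Mutable FIRE integrator state over a flat coordinate vector."""

    positions: np.ndarray
    velocities: np.ndarray
    dt: float
    alpha: float
    steps_since_reset: int = 0

    @classmethod
    def initial(cls, positions: np.ndarray, params: FIREParams) -> "FIREState":
        x = np.asarray(positions, dtype=float).ravel().copy()
        return cls(x, np.zeros_like(x), params.dt_init, params.alpha_start)


def fire_step(state: FIREState, forces: np.ndarray, params: FIREParams) -> FIREState:
    """One FIRE update given forces (−gradient) at the current positions.

    Implements the published rules: uphill power (F·v < 0) zeroes the
    velocity, shrinks dt by ``f_dec`` and resets the mixing parameter;
    ``n_min`` consecutive downhill steps accelerate dt by ``f_inc`` (capped
    at ``dt_max``) and decay the mixing parameter by ``f_alpha``.  Velocity
    is then mixed toward the force direction and positions advance by a
    semi-implicit Euler step.
    """
    f = np.asarray(forces, dtype=float).ravel()
    v = state.velocities.copy()
    dt, alpha, n = state.dt, state.alpha, state.steps_since_reset

    power = float(f @ v)
    if power > 0.0:
        n += 1
        if n > params.n_min:
            dt = min(dt * params.f_inc, params.dt_max)
            alpha *= params.f_alpha
    else:
        n = 0
        v[:] = 0.0
        dt *= params.f_dec
        alpha = params.alpha_start

    v = v + dt * f
    vnorm = float(np.linalg.norm(v))
    fnorm = float(np.linalg.norm(f))
    if fnorm > 1e-300:
        v = (1.0 - alpha) * v + alpha * (f / fnorm) * vnorm

    dx = dt * v
    amax = float(np.abs(dx).max(initial=0.0))
    if amax > params.max_disp:
        dx *= params.max_disp / amax

    return FIREState(state.positions + dx, v, dt, alpha, n)


def fire_minimize(
    force_fn,
    x0: np.ndarray,
    conv_gmax: float,
    max_steps: int = 10000,
    params: FIREParams | None = None,
):
    """Drive a flat coordinate vector with FIRE until max |force| < conv_gmax.

    ``force_fn(x) -> (force, energy)``; ``energy`` is recorded in the trace
    (it may be a pseudo-energy for non-conservative forces such as NEB).
    Returns ``(x, trace, converged, n_steps)``.
    """
    params = params or FIREParams()
    state = FIREState.initial(x0, params)
    trace: list[tuple[float, float]] = []
    for step in range(max_steps + 1):
        force, energy = force_fn(state.positions)
        fmax = float(np.abs(force).max())
        trace.append((energy, fmax))
        if fmax < conv_gmax:
            return state.positions.copy(), trace, True, step
        if step == max_steps:
            break
        state = fire_step(state, force, params)
    return state.positions.copy(), trace, False, max_steps


def minimize_fire(
    model: EnergyModel,
    structure: Structure,
    spec: ConvergenceSpec | None = None,
    params: FIREParams | None = None,
) -> OptimizationResult:
    """FIRE relaxation of the mobile atoms of a structure."""
    spec = spec or ConvergenceSpec()
    idx = _free_indices(structure)
    coords0 = structure.coords.copy()
    work = structure.copy()

    def force_fn(x):
        c = coords0.copy()
        c[idx] = x.reshape(-1, 3)
        work.coords = c
        ev = model.evaluate(work)
        return -ev.gradient[idx].ravel(), ev.energy

    x, trace, ok, n = fire_minimize(
        force_fn, coords0[idx].ravel(), spec.gmax, spec.max_steps, params
    )
    final = coords0.copy()
    final[idx] = x.reshape(-1, 3)
    out = structure.with_coords(final)
    energy = model.evaluate(out).energy
    result = OptimizationResult(out, energy, trace, ok, n)
    if not ok:
        raise ConvergenceError(
            f"FIRE did not reach gmax {spec.gmax:g} within {spec.max_steps} steps",
            result,
        )
    return result
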