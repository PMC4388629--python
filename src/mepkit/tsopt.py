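"""Numerical Hessians, saddle refinement and harmonic mode analysis.

The transition-state workflow: starting from the highest image of a
converged band, refine to a first-order saddle with an eigenvector-following
quasi-Newton optimizer whose Hessian approximation is updated by Bofill's
mixed SR1/PSB formula (which, unlike BFGS, does not force positive
definiteness and therefore can represent negative curvature).  The refined
structure is verified by a full numerical Hessian — symmetric central
differences of analytic gradients — whose eigenvalue spectrum must contain
exactly one negative eigenvalue in both plain Cartesian and mass-weighted
(normal-mode) coordinates; the mass-weighted negative eigenvalue gives the
imaginary frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import EnergyModel
from .structures import Structure
from .units import WAVENUMBER_FACTOR

#: eigenvalues with |λ| below this (Hartree Å⁻²) count as zero modes
ZERO_EIGENVALUE_TOL = 1e-6
#: central differences at the default 0.01 Å step leave O(1e-5) truncation
#: noise on exact zero modes; curvature below this is not trusted as negative
NEGATIVE_CURVATURE_TOL = 1e-5


@dataclass
class HessianMatrix:
    """Symmetric Hessian over the mobile Cartesian coordinates."""

    matrix: np.ndarray       # (3m, 3m), Hartree Å⁻²
    step: float              # finite-difference step, Å
    mass_weighted: bool = False
    atom_indices: np.ndarray | None = None  # mobile atom indices, for bookkeeping


def numerical_hessian(
    model: EnergyModel, structure: Structure, step: float = 0.01
) -> HessianMatrix:
    """Central-difference Hessian: column j = (g(x+h eⱼ) − g(x−h eⱼ)) / 2h.

    Differentiates the analytic gradient over mobile coordinates only and
    symmetrizes the result as (H + Hᵀ)/2.  Use a :class:`NestedModel` as
    ``model`` to relax environment atoms at every displaced geometry.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    idx = np.flatnonzero(structure.mobile_mask)
    m = idx.size * 3
    H = np.empty((m, m))
    col = 0
    for a in idx:
        for d in range(3):
            plus = structure.coords.copy()
            minus = structure.coords.copy()
            plus[a, d] += step
            minus[a, d] -= step
            gp = model.evaluate(structure.with_coords(plus)).gradient[idx].ravel()
            gm = model.evaluate(structure.with_coords(minus)).gradient[idx].ravel()
            H[:, col] = (gp - gm) / (2.0 * step)
            col += 1
    H = 0.5 * (H + H.T)
    return HessianMatrix(matrix=H, step=step, atom_indices=idx)


@dataclass
class ModeAnalysis:
    """Eigenvalues, frequencies and the count of negative-curvature modes."""

    eigenvalues: np.ndarray       # ascending; Hartree Å⁻² (amu⁻¹ if weighted)
    eigenvectors: np.ndarray      # columns
    frequencies_cm: np.ndarray | None  # cm⁻¹, imaginary encoded as negative
    negative_count: int
    mass_weighted: bool


def rigid_body_modes(
    coords: np.ndarray, masses: np.ndarray | None = None
) -> np.ndarray:
    """Orthonormal basis of rigid translations and rotations, columns (3n, k).

    In mass-weighted coordinates the modes carry √m factors.  Used to
    project exact zero modes out of Hessians of isolated molecular models,
    whose energies are invariant under rigid motion.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    w = np.sqrt(np.repeat(masses, 3)) if masses is not None else np.ones(3 * n)
    modes = []
    for d in range(3):
        t = np.zeros((n, 3))
        t[:, d] = 1.0
        modes.append(t.ravel() * w)
    center = coords.mean(axis=0) if masses is None else (
        (coords * np.asarray(masses)[:, None]).sum(axis=0) / np.sum(masses)
    )
    rel = coords - center
    for axis in np.eye(3):
        r = np.cross(np.broadcast_to(axis, rel.shape), rel)
        modes.append(r.ravel() * w)
    M = np.column_stack(modes)
    u, s, _ = np.linalg.svd(M, full_matrices=False)
    return u[:, s > 1e-10 * s[0]]


def _project_out(H: np.ndarray, modes: np.ndarray) -> np.ndarray:
    P = np.eye(H.shape[0]) - modes @ modes.T
    return P @ H @ P


def mode_analysis(
    hessian: HessianMatrix,
    masses: np.ndarray | None = None,
    zero_tol: float = ZERO_EIGENVALUE_TOL,
    project_rigid_coords: np.ndarray | None = None,
) -> ModeAnalysis:
    """Eigendecompose a Hessian, optionally in mass-weighted coordinates.

    With masses, the matrix element H_ij is divided by √(m_i m_j) and the
    eigenvalues (Hartree Å⁻² amu⁻¹) are converted to wavenumbers; negative
    eigenvalues appear as negative (imaginary) frequencies.
    """
    H = hessian.matrix
    freqs = None
    weighted = masses is not None
    if weighted:
        masses = np.asarray(masses, dtype=float)
        if np.any(masses <= 0):
            raise ValueError("masses must be positive")
        if masses.size * 3 != H.shape[0]:
            raise ValueError("one mass per mobile atom required")
        w = np.repeat(masses, 3)
        H = H / np.sqrt(np.outer(w, w))
    if project_rigid_coords is not None:
        H = _project_out(H, rigid_body_modes(project_rigid_coords, masses))
    evals, evecs = np.linalg.eigh(H)
    if weighted:
        freqs = np.sign(evals) * WAVENUMBER_FACTOR * np.sqrt(np.abs(evals))
    negative = int(np.sum(evals < -zero_tol))
    return ModeAnalysis(
        eigenvalues=evals,
        eigenvectors=evecs,
        frequencies_cm=freqs,
        negative_count=negative,
        mass_weighted=weighted,
    )


def bofill_update(H: np.ndarray, dx: np.ndarray, dg: np.ndarray) -> np.ndarray:
    """Bofill's mixed SR1/PSB quasi-Newton Hessian update (symmetric).

    φ weighs the SR1 term by the squared overlap of the residual with the
    step; the PSB term fills in the rest.  Suited to saddle searches because
    it does not enforce positive definiteness.
    """
    r = dg - H @ dx
    xx = float(dx @ dx)
    rx = float(r @ dx)
    rr = float(r @ r)
    if xx < 1e-16 or rr < 1e-16:
        return H
    phi = rx**2 / (rr * xx)
    H_new = H.copy()
    if abs(rx) > 1e-12:
        H_new = H_new + phi * np.outer(r, r) / rx
    psb = (np.outer(r, dx) + np.outer(dx, r)) / xx - rx * np.outer(dx, dx) / xx**2
    H_new = H_new + (1.0 - phi) * psb
    return 0.5 * (H_new + H_new.T)


@dataclass
class TSResult:
    structure: Structure
    energy: float
    hessian: np.ndarray            # final quasi-Newton Hessian approximation
    trace: list[tuple[float, float]]  # (energy, gmax) per step
    converged: bool
    n_steps: int


class SaddleSearchError(RuntimeError):
    def __init__(self, message: str, best: TSResult | None = None):
        super().__init__(message)
        self.best = best


def _prfo_step(H: np.ndarray, g: np.ndarray, follow: int, trust: float) -> np.ndarray:
    """Partitioned rational-function step: maximize along ``follow`` mode,
    minimize along the rest; bounded by the trust radius."""
    evals, evecs = np.linalg.eigh(H)
    gt = evecs.T @ g
    step_t = np.zeros_like(gt)

    # uphill shift for the followed mode: positive root of λ² − bλ − g² = 0
    b = evals[follow]
    lam_up = 0.5 * (b + np.sqrt(b**2 + 4.0 * gt[follow] ** 2))
    denom = b - lam_up
    step_t[follow] = -gt[follow] / denom if abs(denom) > 1e-12 else 0.0

    rest = [i for i in range(len(evals)) if i != follow]
    if rest:
        br = evals[rest]
        gr = gt[rest]
        # downhill shift: lowest root of the RFO secular equation
        lam = 0.0
        lo = min(float(br.min()), 0.0) - 1.0
        hi = min(float(br.min()), 0.0)
        with np.errstate(divide="ignore", over="ignore"):
            for _ in range(200):
                lam = 0.5 * (lo + hi)
                s = lam - float(np.sum(gr**2 / (br - lam)))
                if s > 0:
                    hi = lam
                else:
                    lo = lam
        lam = 0.5 * (lo + hi)
        for i, gi, bi in zip(rest, gr, br):
            d = bi - lam
            step_t[i] = -gi / d if abs(d) > 1e-12 else 0.0

    step = evecs @ step_t
    norm = float(np.linalg.norm(step))
    if norm > trust:
        step *= trust / norm
    return step


def ts_refine(
    model: EnergyModel,
    structure: Structure,
    init_hessian: HessianMatrix | np.ndarray | None = None,
    gmax: float = 0.001,
    max_steps: int = 500,
    trust_radius: float = 0.1,
    follow_mode: int = 0,
) -> TSResult:
    """Eigenvector-following refinement to a first-order saddle point.

    Maximizes along the followed (by default lowest) Hessian eigenmode and
    minimizes along all others, with Bofill updates of the Hessian
    approximation after each accepted step, until the maximum absolute
    gradient component over mobile atoms drops below ``gmax`` (Hartree Å⁻¹).
    Raises :class:`SaddleSearchError` if the Hessian approximation loses its
    negative curvature or the step budget is exhausted.
    """
    idx = np.flatnonzero(structure.mobile_mask)
    if init_hessian is None:
        init_hessian = numerical_hessian(model, structure)
    H = init_hessian.matrix.copy() if isinstance(init_hessian, HessianMatrix) else np.array(init_hessian, dtype=float)
    if H.shape != (idx.size * 3,) * 2:
        raise ValueError("initial Hessian dimension mismatch with mobile atoms")
    if np.linalg.eigvalsh(H)[follow_mode] >= -NEGATIVE_CURVATURE_TOL and follow_mode == 0:
        raise SaddleSearchError("initial Hessian has no negative eigenvalue to follow")

    current = structure.copy()
    ev = model.evaluate(current)
    g = ev.gradient[idx].ravel()
    trace = [(ev.energy, float(np.abs(g).max()))]

    for step_i in range(1, max_steps + 1):
        if float(np.abs(g).max()) < gmax:
            return TSResult(current, ev.energy, H, trace, True, step_i - 1)
        dx = _prfo_step(H, g, follow_mode, trust_radius)
        new_coords = current.coords.copy()
        new_coords[idx] += dx.reshape(-1, 3)
        new = current.with_coords(new_coords)
        ev_new = model.evaluate(new)
        g_new = ev_new.gradient[idx].ravel()
        H = bofill_update(H, dx, g_new - g)
        if np.linalg.eigvalsh(H)[0] >= 0:
            best = TSResult(current, ev.energy, H, trace, False, step_i)
            raise SaddleSearchError(
                "Hessian approximation lost negative curvature", best
            )
        current, ev, g = new, ev_new, g_new
        trace.append((ev.energy, float(np.abs(g).max())))

    if float(np.abs(g).max()) < gmax:
        return TSResult(current, ev.energy, H, trace, True, max_steps)
    best = TSResult(current, ev.energy, H, trace, False, max_steps)
    raise SaddleSearchError(
        f"saddle search did not reach gmax {gmax:g} in {max_steps} steps", best
    )


@dataclass
class SaddleReport:
    """Saddle verification: curvature counts with and without mass weighting."""

    negative_count_plain: int
    negative_count_weighted: int
    frequency_cm: float | None      # followed-mode frequency (negative = imaginary)
    plain: ModeAnalysis
    weighted: ModeAnalysis
    passed: bool


def verify_saddle(
    model: EnergyModel,
    structure: Structure,
    step: float = 0.01,
    zero_tol: float = ZERO_EIGENVALUE_TOL,
    project_rigid: bool = False,
) -> SaddleReport:
    """First-order saddle check: exactly one negative eigenvalue both ways.

    Computes the numerical Hessian at ``structure``, analyzes it in plain
    and mass-weighted coordinates (masses of the mobile atoms) and reports
    the imaginary frequency of the reaction mode.  For isolated molecular
    models set ``project_rigid`` to remove the six exact rigid-body zero
    modes before counting (finite-difference noise can push them a hair
    below zero); leave it off for abstract surfaces that are not
    translation/rotation invariant.
    """
    hess = numerical_hessian(model, structure, step)
    rigid = structure.coords[structure.mobile_mask] if project_rigid else None
    plain = mode_analysis(hess, zero_tol=zero_tol, project_rigid_coords=rigid)
    masses = structure.masses[structure.mobile_mask]
    weighted = mode_analysis(hess, masses=masses, zero_tol=zero_tol,
                             project_rigid_coords=rigid)
    freq = float(weighted.frequencies_cm[0]) if weighted.frequencies_cm is not None else None
    passed = plain.negative_count == 1 and weighted.negative_count == 1
    return SaddleReport(
        negative_count_plain=plain.negative_count,
        negative_count_weighted=weighted.negative_count,
        frequency_cm=freq,
        plain=plain,
        weighted=weighted,
        passed=passed,
    )
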