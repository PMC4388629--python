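"""Nudged Elastic Band in full coordinate space, stabilized by switched springs.

The band is a chain of images between fixed reactant and product endpoints.
Interior images feel, per iteration:

* the *true* force component perpendicular to the path tangent,
* a spring force **parallel** to the tangent with magnitude
  ``k (|R_{i+1} − R_i| − |R_i − R_{i−1}|)`` (equalizes image spacing),
* a fraction ``f(Φ) = ½(1 + cos(π cos Φ))`` of the spring force
  **perpendicular** to the tangent, where Φ is the angle between the two
  adjacent path segments (Φ = 0 for a locally straight path, so the extra
  term vanishes there and only acts to straighten kinks).

Tangents use the improved (upwind) estimate: the segment toward the
higher-energy neighbor, with energy-weighted mixing of both segments at
local extrema.  All interior images are moved simultaneously by FIRE on the
concatenated force vector; quasi-Newton drivers are avoided because the NEB
force field is non-conservative (its Jacobian is not symmetric).

Path construction follows the coordinate-driving recipe: a parametric spline
through a handful of hand-picked collective-variable waypoints, resampled
uniformly in arclength, realized by successive restrained minimization, then
densified by midpoint insertion until every segment of the mobile-coordinate
Euclidean chain is shorter than a maximum length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import splev, splprep

from .colvars import CV, HarmonicRestraint, biased_model, cv_value
from .models import EnergyModel
from .optimize import (
    ConvergenceError,
    ConvergenceSpec,
    FIREParams,
    FIREState,
    fire_step,
    minimize_bfgs,
)
from .structures import Structure
from .units import EV_TO_HARTREE, HARTREE_TO_KCAL_PER_MOL


@dataclass
class Path:
    """An ordered chain of images with (by default) fixed endpoints."""

    images: list[Structure]
    endpoint_fixed: tuple[bool, bool] = (True, True)
    energies: np.ndarray | None = None  # Hartree, per image

    def __post_init__(self):
        if len(self.images) < 3:
            raise ValueError("a path needs at least 3 images")
        n = self.images[0].n_atoms
        if any(im.n_atoms != n for im in self.images):
            raise ValueError("images must share the atom set")
        for a, b in zip(self.images, self.images[1:]):
            if np.allclose(a.coords, b.coords):
                raise ValueError("consecutive images must be distinct")

    @property
    def n_images(self) -> int:
        return len(self.images)

    @property
    def mobile_mask(self) -> np.ndarray:
        return self.images[0].mobile_mask

    def mobile_coords(self) -> np.ndarray:
        """(n_images, n_mobile*3) array of mobile-atom coordinates."""
        m = self.mobile_mask
        return np.array([im.coords[m].ravel() for im in self.images])

    def copy(self) -> "Path":
        return Path(
            [im.copy() for im in self.images],
            self.endpoint_fixed,
            None if self.energies is None else self.energies.copy(),
        )


@dataclass(frozen=True)
class NEBConfig:
    """Band settings; the spring constant is quoted in eV Å⁻¹."""

    spring_k_ev: float = 5.0
    switch_on: bool = True
    conv_gmax: float = 0.0025        # Hartree Å⁻¹, max |total NEB force component|
    max_steps: int = 10000
    climbing: bool = False           # off by default; TS is refined separately
    fire: FIREParams = field(default_factory=FIREParams)

    def __post_init__(self):
        if self.spring_k_ev <= 0:
            raise ValueError("spring constant must be positive")

    @property
    def spring_k(self) -> float:
        """Spring constant in internal units (Hartree Å⁻¹)."""
        return self.spring_k_ev * EV_TO_HARTREE


def improved_tangent(coords: np.ndarray, energies: np.ndarray, i: int) -> np.ndarray:
    """Upwind tangent at interior image ``i`` over flattened coordinates.

    ``coords`` has shape (n_images, n_dof).  The segment toward the
    higher-energy neighbor is used where energies are monotone through the
    image; at local extrema the two segments are mixed with weights given by
    the larger/smaller neighbor energy differences.
    """
    if not 0 < i < len(coords) - 1:
        raise ValueError("tangent defined for interior images only")
    fwd = coords[i + 1] - coords[i]
    bwd = coords[i] - coords[i - 1]
    if np.linalg.norm(fwd) < 1e-14 or np.linalg.norm(bwd) < 1e-14:
        raise ValueError("zero-length path segment")
    e_prev, e_here, e_next = energies[i - 1], energies[i], energies[i + 1]
    if e_next > e_here > e_prev:
        tau = fwd
    elif e_next < e_here < e_prev:
        tau = bwd
    else:
        dmax = max(abs(e_next - e_here), abs(e_prev - e_here))
        dmin = min(abs(e_next - e_here), abs(e_prev - e_here))
        if e_next >= e_prev:
            tau = fwd * dmax + bwd * dmin
        else:
            tau = fwd * dmin + bwd * dmax
        if np.linalg.norm(tau) < 1e-14:  # flat: fall back to the chord
            tau = fwd + bwd
    return tau / np.linalg.norm(tau)


def switch_fraction(phi: float) -> float:
    """Perpendicular-spring switching function f(Φ) = ½(1 + cos(π cos Φ)).

    Φ is the angle between adjacent path segments: 0 for a straight
    continuation (f = 0, no perpendicular spring) rising to 1 at Φ = π/2.
    """
    return 0.5 * (1.0 + np.cos(np.pi * np.cos(phi)))


def neb_forces(
    coords: np.ndarray,
    energies: np.ndarray,
    gradients: np.ndarray,
    config: NEBConfig,
    endpoint_fixed: tuple[bool, bool] = (True, True),
) -> np.ndarray:
    """Per-image NEB force vectors over flattened mobile coordinates.

    ``coords``, ``gradients``: (n_images, n_dof); ``energies``: (n_images,).
    Fixed endpoints get zero force; free endpoints feel the plain true force.
    """
    n = len(coords)
    k = config.spring_k
    forces = np.zeros_like(coords)
    if not endpoint_fixed[0]:
        forces[0] = -gradients[0]
    if not endpoint_fixed[1]:
        forces[-1] = -gradients[-1]

    i_climb = int(np.argmax(energies)) if config.climbing else -1

    for i in range(1, n - 1):
        tau = improved_tangent(coords, energies, i)
        f_true = -gradients[i]
        f_perp = f_true - (f_true @ tau) * tau
        if i == i_climb and 0 < i_climb < n - 1:
            forces[i] = f_true - 2.0 * (f_true @ tau) * tau
            continue
        fwd = coords[i + 1] - coords[i]
        bwd = coords[i] - coords[i - 1]
        lf, lb = np.linalg.norm(fwd), np.linalg.norm(bwd)
        f_spring_par = k * (lf - lb) * tau
        total = f_perp + f_spring_par
        if config.switch_on:
            cos_phi = float(np.clip(fwd @ bwd / (lf * lb), -1.0, 1.0))
            phi = float(np.arccos(cos_phi))
            spring_vec = k * (fwd - bwd)
            spring_perp = spring_vec - (spring_vec @ tau) * tau
            total = total + switch_fraction(phi) * spring_perp
        forces[i] = total
    return forces


@dataclass
class NEBTrace:
    """Convergence record: per-iteration max force and energy profiles."""

    fmax: list[float] = field(default_factory=list)
    profiles: list[np.ndarray] = field(default_factory=list)  # Hartree per image

    @property
    def n_iterations(self) -> int:
        return max(len(self.fmax) - 1, 0)


def neb_optimize(path: Path, model: EnergyModel, config: NEBConfig | None = None
                 ) -> tuple[Path, NEBTrace]:
    """Relax all interior images simultaneously with FIRE.

    Stops when the maximum absolute component of the total NEB force drops
    below ``config.conv_gmax``; raises :class:`ConvergenceError` (carrying
    the best path) otherwise.  Fixed endpoint coordinates are returned
    bit-identical to the input.
    """
    config = config or NEBConfig()
    work = path.copy()
    mask = work.mobile_mask
    n_img = work.n_images
    all_coords = work.mobile_coords()
    n_dof = all_coords.shape[1]

    free = [i for i in range(n_img)
            if (0 < i < n_img - 1)
            or (i == 0 and not work.endpoint_fixed[0])
            or (i == n_img - 1 and not work.endpoint_fixed[1])]

    trace = NEBTrace()

    def eval_band(flat_free: np.ndarray):
        coords = all_coords.copy()
        coords[free] = flat_free.reshape(len(free), n_dof)
        energies = np.empty(n_img)
        gradients = np.empty((n_img, n_dof))
        for i in range(n_img):
            im = work.images[i]
            c = im.coords.copy()
            c[mask] = coords[i].reshape(-1, 3)
            im.coords = c
            ev = model.evaluate(im)
            energies[i] = ev.energy
            gradients[i] = ev.gradient[mask].ravel()
        forces = neb_forces(coords, energies, gradients, config, work.endpoint_fixed)
        return coords, energies, forces

    params = config.fire
    state = FIREState.initial(all_coords[free].ravel(), params)
    converged = False
    n_steps = 0
    for step in range(config.max_steps + 1):
        coords, energies, forces = eval_band(state.positions)
        fmax = float(np.abs(forces[free]).max())
        trace.fmax.append(fmax)
        trace.profiles.append(energies.copy())
        if fmax < config.conv_gmax:
            converged = True
            n_steps = step
            break
        if step == config.max_steps:
            n_steps = step
            break
        state = fire_step(state, forces[free].ravel(), params)

    final_coords = all_coords.copy()
    final_coords[free] = state.positions.reshape(len(free), n_dof)
    images = []
    for i in range(n_img):
        im = path.images[i].copy()
        if i in free:
            c = im.coords.copy()
            c[mask] = final_coords[i].reshape(-1, 3)
            im.coords = c
        images.append(im)
    out = Path(images, work.endpoint_fixed, energies=trace.profiles[-1].copy())
    if not converged:
        raise ConvergenceError(
            f"NEB did not reach fmax {config.conv_gmax:g} within "
            f"{config.max_steps} steps (last fmax {trace.fmax[-1]:g})",
            best=out,
        )
    return out, trace


def init_path_from_waypoints(
    model: EnergyModel,
    reactant: Structure,
    cv_pair: tuple[CV, CV],
    waypoints: list[tuple[float, float]],
    n: int = 21,
    restraint_k: float = 5.0,
    spec: ConvergenceSpec | None = None,
) -> list[Structure]:
    """Generate an initial path by restrained driving along a CV-space spline.

    A parametric spline through the waypoints (pairs of CV values) is
    resampled to ``n`` pairs uniformly spaced in arclength; structures are
    generated by successive restrained minimization, each warm-started from
    the previous one, beginning at the (pre-optimized) reactant.
    """
    wp = np.asarray(waypoints, dtype=float)
    if wp.ndim != 2 or wp.shape[1] != 2 or len(wp) < 2:
        raise ValueError("need at least 2 CV-value waypoints")
    seg = np.linalg.norm(np.diff(wp, axis=0), axis=1)
    if seg.sum() < 1e-12:
        raise ValueError("waypoints describe a zero-length curve")
    k = min(3, len(wp) - 1)
    tck, _ = splprep([wp[:, 0], wp[:, 1]], s=0.0, k=k)
    dense = np.linspace(0.0, 1.0, 512)
    xy = np.array(splev(dense, tck)).T
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(xy, axis=0), axis=1))])
    targets = np.array([
        xy[np.searchsorted(arc, a, side="left").clip(0, len(xy) - 1)]
        for a in np.linspace(0.0, arc[-1], n)
    ])

    spec = spec or ConvergenceSpec(gmax=0.001, max_steps=4000)
    cv1, cv2 = cv_pair
    structures = []
    current = reactant
    for t1, t2 in targets:
        m = biased_model(
            model,
            HarmonicRestraint(cv1, float(t1), restraint_k),
            HarmonicRestraint(cv2, float(t2), restraint_k),
        )
        res = minimize_bfgs(m, current, spec)
        current = res.structure
        structures.append(current)
    return structures


def densify(structures: list[Structure], max_segment: float = 0.25) -> Path:
    """Insert midpoints until all mobile-coordinate segments < ``max_segment`` Å.

    Segment length is the Euclidean norm over mobile-atom coordinates.  Only
    mobile atoms are interpolated; environment/frozen coordinates of an
    inserted image are copied verbatim from the earlier parent.
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    imgs = [s.copy() for s in structures]
    mask = imgs[0].mobile_mask

    def seglen(a: Structure, b: Structure) -> float:
        return float(np.linalg.norm((b.coords[mask] - a.coords[mask]).ravel()))

    changed = True
    while changed:
        changed = False
        out = [imgs[0]]
        for a, b in zip(imgs, imgs[1:]):
            if seglen(a, b) >= max_segment:
                mid = a.copy()  # environment copied from the earlier parent
                c = mid.coords.copy()
                c[mask] = 0.5 * (a.coords[mask] + b.coords[mask])
                mid.coords = c
                out.extend([mid, b])
                changed = True
            else:
                out.append(b)
        imgs = out
    return Path(imgs)


def path_maximum(path: Path) -> float:
    """Path maximum energy (Hartree or model units) along the band.

    The discrete image maximum underestimates the barrier by up to the
    curvature times the squared image spacing, so the maximum of the
    three-point parabola through the highest image and its neighbors is
    returned (the standard barrier estimate for chain-of-states profiles).
    Falls back to the image maximum at endpoints or non-concave profiles.
    """
    if path.energies is None:
        raise ValueError("path has no energies")
    e = np.asarray(path.energies, dtype=float)
    i = int(np.argmax(e))
    if 0 < i < len(e) - 1:
        y0, y1, y2 = e[i - 1], e[i], e[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            return float(y1 - 0.125 * (y0 - y2) ** 2 / denom)
    return float(e[i])


def path_profile(
    path: Path,
    model: EnergyModel | None = None,
    cvs: dict[str, CV] | None = None,
) -> pd.DataFrame:
    """Tabulate the path: image index, relative energy, named CV values.

    Energies are relative to image 0, in kcal mol⁻¹ (the Hartree values are
    kept in a separate column).  Uses stored path energies unless a model is
    given to recompute them.
    """
    if model is not None:
        energies = np.array([model.evaluate(im).energy for im in path.images])
    elif path.energies is not None:
        energies = np.asarray(path.energies, dtype=float)
    else:
        raise ValueError("path has no energies; pass a model")
    rel = (energies - energies[0]) * HARTREE_TO_KCAL_PER_MOL
    data = {
        "image": np.arange(path.n_images),
        "energy_hartree": energies,
        "rel_energy_kcal": rel,
    }
    for name, cv in (cvs or {}).items():
        data[name] = [cv_value(cv, im) for im in path.images]
    return pd.DataFrame(data)
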