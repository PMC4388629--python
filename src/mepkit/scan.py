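"""Restrained 1D/2D potential-energy-surface scans and map diagnostics.

A scan drives one or two collective variables over a rectangular grid of
targets.  Points are visited *scanline-major*: the first axis is swept once
at the starting value of the second axis, then each of those points seeds a
scanline along the second axis.  Every point is minimized under harmonic
restraints starting from the geometry of its parent point (warm start), so
the parentage graph is a tree rooted at the pre-optimized start structure —
the same protocol used for driving reaction coordinates in QM/MM scans.

The map stores the *unbiased* base-model energy at each restrained minimum
(the bias is bookkeeping, not physics), in kcal mol⁻¹ relative to the first
grid point, together with convergence flags and monitored CV values.
Diagnostics:

* :func:`flag_outliers` — the isolated-point rule: flag points whose energy
  differs by more than a threshold (default 2 kcal mol⁻¹) from the mean of
  their four direct neighbors (interior) or two neighbors along the
  boundary (edges and corners).
* :func:`detect_discontinuities` — adjacent-point jumps in a monitored,
  unsampled CV; a nonempty edge set is the signature of a hidden-coordinate
  discontinuity, an empty set certifies continuity in that monitor.
* :func:`grid_stationary_points` — discrete minima and the minimax
  (lowest-highest-point) barrier between two minima on the grid graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colvars import CV, HarmonicRestraint, biased_model, cv_value
from .models import EnergyModel
from .optimize import ConvergenceError, ConvergenceSpec, minimize_bfgs
from .structures import Structure
from .units import HARTREE_TO_KCAL_PER_MOL


@dataclass(frozen=True)
class ScanAxis:
    """Uniform sweep of one CV from start to stop (inclusive), signed step."""

    cv: CV
    start: float
    stop: float
    step: float
    name: str = ""

    def __post_init__(self):
        if self.step == 0:
            raise ValueError("step must be nonzero")
        if (self.stop - self.start) / self.step < 0:
            raise ValueError("step sign inconsistent with start/stop")

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def values(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)


@dataclass(frozen=True)
class GridPoint:
    i: int              # index along axis1
    j: int              # index along axis2
    target1: float
    target2: float
    parent: tuple[int, int] | None  # warm-start parent (None at the root)


def build_grid(axis1: ScanAxis, axis2: ScanAxis) -> list[GridPoint]:
    """Ordered scan points with warm-start parentage.

    Order: axis1 swept at axis2.start (parent = previous axis1 point), then
    for each axis1 value a scanline stepping axis2 (parent = previous point
    of that scanline).
    """
    v1, v2 = axis1.values, axis2.values
    points: list[GridPoint] = []
    for i, t1 in enumerate(v1):
        parent = None if i == 0 else (i - 1, 0)
        points.append(GridPoint(i, 0, float(t1), float(v2[0]), parent))
    for i, t1 in enumerate(v1):
        for j in range(1, len(v2)):
            points.append(GridPoint(i, j, float(t1), float(v2[j]), (i, j - 1)))
    return points


@dataclass
class PESMap:
    """Rectangular grid of restrained-minimum energies plus annotations."""

    axis1: ScanAxis
    axis2: ScanAxis
    energies: np.ndarray                 # kcal/mol relative to reference point
    converged: np.ndarray                # bool grid
    outlier: np.ndarray                  # bool grid
    monitors: dict[str, np.ndarray]      # name -> value grid (Å)
    structures: dict[tuple[int, int], Structure] = field(default_factory=dict)
    reference: tuple[int, int] = (0, 0)
    reference_energy: float = 0.0  # absolute base-model energy at the reference, Hartree

    @property
    def shape(self) -> tuple[int, int]:
        return self.energies.shape

    def interpolate(self, x1: float, x2: float) -> float:
        """Bilinear interpolation of the energy map at CV values (x1, x2)."""
        v1, v2 = self.axis1.values, self.axis2.values
        f1 = np.clip((x1 - v1[0]) / self.axis1.step, 0, len(v1) - 1)
        f2 = np.clip((x2 - v2[0]) / self.axis2.step, 0, len(v2) - 1)
        i0, j0 = int(min(np.floor(f1), len(v1) - 2)), int(min(np.floor(f2), len(v2) - 2))
        a, b = f1 - i0, f2 - j0
        e = self.energies
        return float(
            (1 - a) * (1 - b) * e[i0, j0]
            + a * (1 - b) * e[i0 + 1, j0]
            + (1 - a) * b * e[i0, j0 + 1]
            + a * b * e[i0 + 1, j0 + 1]
        )


def run_scan(
    model: EnergyModel,
    start_structure: Structure,
    axis1: ScanAxis,
    axis2: ScanAxis,
    restraint_k: float = 5.0,
    spec: ConvergenceSpec | None = None,
    monitors: dict[str, CV] | None = None,
    keep_structures: bool = True,
) -> PESMap:
    """Run a full 2D restrained scan with warm starts.

    Per-point minimization failures are recorded in the ``converged`` grid
    and the scan continues from the best-so-far geometry.  Monitors are
    arbitrary named CVs evaluated at every relaxed point (typically the
    coordinates the scan does *not* sample, to expose hidden jumps).
    """
    spec = spec or ConvergenceSpec(gmax=0.01)
    monitors = monitors or {}
    n1, n2 = axis1.n_points, axis2.n_points
    energies = np.full((n1, n2), np.nan)
    converged = np.zeros((n1, n2), dtype=bool)
    monitor_grids = {name: np.full((n1, n2), np.nan) for name in monitors}
    structures: dict[tuple[int, int], Structure] = {}

    geoms: dict[tuple[int, int], Structure] = {}
    base_energies = np.full((n1, n2), np.nan)
    for pt in build_grid(axis1, axis2):
        start = geoms[pt.parent] if pt.parent is not None else start_structure
        m = biased_model(
            model,
            HarmonicRestraint(axis1.cv, pt.target1, restraint_k),
            HarmonicRestraint(axis2.cv, pt.target2, restraint_k),
        )
        try:
            res = minimize_bfgs(m, start, spec)
            ok = True
        except ConvergenceError as err:
            res = err.best
            ok = False
        geom = res.structure
        geoms[(pt.i, pt.j)] = geom
        _, base_e, _ = m.evaluate_components(geom)
        base_energies[pt.i, pt.j] = base_e
        converged[pt.i, pt.j] = ok
        for name, cv in monitors.items():
            monitor_grids[name][pt.i, pt.j] = cv_value(cv, geom)
        if keep_structures:
            structures[(pt.i, pt.j)] = geom

    ref = base_energies[0, 0]
    energies = (base_energies - ref) * HARTREE_TO_KCAL_PER_MOL
    return PESMap(
        axis1=axis1,
        axis2=axis2,
        energies=energies,
        converged=converged,
        outlier=np.zeros((n1, n2), dtype=bool),
        monitors=monitor_grids,
        structures=structures,
        reference_energy=float(ref),
    )


def flag_outliers(pesmap: PESMap, threshold: float = 2.0) -> PESMap:
    """Flag isolated energy outliers (threshold in kcal mol⁻¹).

    Interior points are compared against the mean of their four direct
    neighbors; boundary points (corners included) against the mean of their
    two neighbors along the boundary.  Energies are left untouched; only the
    ``outlier`` flags are set, so the operation is idempotent.
    """
    e = pesmap.energies
    n1, n2 = e.shape
    if n1 < 2 or n2 < 2:
        raise ValueError("outlier rule needs at least a 2x2 map")
    flags = np.zeros_like(e, dtype=bool)
    for i in range(n1):
        for j in range(n2):
            on_b1 = i in (0, n1 - 1)
            on_b2 = j in (0, n2 - 1)
            if not on_b1 and not on_b2:
                ref = (e[i - 1, j] + e[i + 1, j] + e[i, j - 1] + e[i, j + 1]) / 4.0
            elif on_b1 and not on_b2:
                ref = (e[i, j - 1] + e[i, j + 1]) / 2.0
            elif on_b2 and not on_b1:
                ref = (e[i - 1, j] + e[i + 1, j]) / 2.0
            else:  # corner: its two boundary neighbors
                ni = 1 if i == 0 else n1 - 2
                nj = 1 if j == 0 else n2 - 2
                ref = (e[ni, j] + e[i, nj]) / 2.0
            flags[i, j] = abs(e[i, j] - ref) > threshold
    out = PESMap(
        axis1=pesmap.axis1, axis2=pesmap.axis2, energies=pesmap.energies,
        converged=pesmap.converged, outlier=flags, monitors=pesmap.monitors,
        structures=pesmap.structures, reference=pesmap.reference,
        reference_energy=pesmap.reference_energy,
    )
    return out


def detect_discontinuities(
    pesmap: PESMap, monitor_name: str, jump_threshold: float = 0.5
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Grid edges where a monitored CV jumps by more than ``jump_threshold`` Å.

    An empty list certifies continuity of that monitor over the whole map.
    """
    if monitor_name not in pesmap.monitors:
        raise KeyError(f"unknown monitor {monitor_name!r}")
    m = pesmap.monitors[monitor_name]
    n1, n2 = m.shape
    edges = []
    for i in range(n1):
        for j in range(n2):
            if i + 1 < n1 and abs(m[i + 1, j] - m[i, j]) > jump_threshold:
                edges.append(((i, j), (i + 1, j)))
            if j + 1 < n2 and abs(m[i, j + 1] - m[i, j]) > jump_threshold:
                edges.append(((i, j), (i, j + 1)))
    return edges


@dataclass
class GridStationaryPoints:
    minima: list[tuple[int, int]]                  # sorted by energy
    saddle: tuple[int, int] | None                 # minimax barrier point
    barrier: float | None                          # kcal/mol above the map reference


def grid_stationary_points(
    pesmap: PESMap,
    between: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> GridStationaryPoints:
    """Discrete minima plus the minimax saddle candidate between two minima.

    Only converged, non-outlier points participate.  A minimum is a point
    strictly below all of its existing 4-neighbors.  The saddle candidate
    between two minima is found by the lowest-maximum-over-paths (minimax)
    criterion on the grid graph: points are added in order of increasing
    energy and union-find connectivity is tracked; the point whose addition
    first connects the two minima is the discrete saddle.
    """
    e = pesmap.energies
    n1, n2 = e.shape
    valid = pesmap.converged & ~pesmap.outlier & np.isfinite(e)

    def neighbors(i, j):
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < n1 and 0 <= nj < n2 and valid[ni, nj]:
                yield ni, nj

    minima = []
    for i in range(n1):
        for j in range(n2):
            if not valid[i, j]:
                continue
            nbrs = list(neighbors(i, j))
            if nbrs and all(e[i, j] < e[ni, nj] for ni, nj in nbrs):
                minima.append((i, j))
    minima.sort(key=lambda p: e[p])
    if not minima:
        raise ValueError("no grid minima found")

    if between is None:
        if len(minima) < 2:
            return GridStationaryPoints(minima, None, None)
        between = (minima[0], minima[1])
    a, b = between

    # union-find flood by increasing energy
    parent: dict[tuple[int, int], tuple[int, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    order = sorted(
        ((i, j) for i in range(n1) for j in range(n2) if valid[i, j]),
        key=lambda p: e[p],
    )
    added = set()
    for p in order:
        parent[p] = p
        added.add(p)
        for q in neighbors(*p):
            if q in added:
                parent[find(q)] = find(p)
        if a in added and b in added and find(a) == find(b):
            return GridStationaryPoints(minima, p, float(e[p]))
    return GridStationaryPoints(minima, None, None)


def project_structures(
    structures: list[Structure], cv1: CV, cv2: CV
) -> np.ndarray:
    """Evaluate two CVs per structure for overlay on a PES map; shape (n, 2)."""
    return np.array([[cv_value(cv1, s), cv_value(cv2, s)] for s in structures]).reshape(
        -1, 2
    )
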