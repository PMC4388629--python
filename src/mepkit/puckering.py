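"""Cremer-Pople ring-puckering analysis for six-membered rings.

The Cremer-Pople construction places a unique mean plane through the ring
(weighted trigonometric sums over the ring positions), projects out the
perpendicular displacements z_j, and decomposes them into one chair-like
mode (q₃) and one degenerate boat/twist-boat mode (q₂, φ₂).  For a
six-membered ring this yields the spherical coordinates

* total amplitude  Q = √(q₂² + q₃²)  (Å),
* polar angle      θ = atan2(q₂, q₃) ∈ [0°, 180°]   (chairs at the poles),
* phase            φ = φ₂ ∈ [0°, 360°)              (pseudorotation phase).

Conformers are classified against the 38 canonical forms (2 chairs, 6
boats, 6 twist-boats, 12 envelopes, 12 half-chairs) by spherical distance
on the (θ, φ) sphere.  The canonical reference points and their IUPAC-style
labels are *generated geometrically* at import time from ideal displacement
patterns, so labels are guaranteed consistent with this module's phase
conventions rather than copied from a table.

The default atom-naming convention is the pyranose ring ordered
O5, C1, C2, C3, C4, C5 with O5 at position 1; with this anchoring the ⁴C₁
chair sits at θ = 0.  Re-anchoring the ring by one position rotates φ by
60° and flipping the traversal direction mirrors the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structures import Structure

RING_SIZE = 6
#: position labels for the default pyranose anchoring (position 1 = O5)
PYRANOSE_POSITIONS = ("O", "1", "2", "3", "4", "5")


@dataclass(frozen=True)
class RingSelection:
    """Six atom indices in ring-bond order; element 0 is position 1."""

    indices: tuple[int, ...]

    def __post_init__(self):
        if len(self.indices) != RING_SIZE or len(set(self.indices)) != RING_SIZE:
            raise ValueError("need 6 distinct atom indices in ring order")

    def validate_bonding(self, structure: Structure, max_bond: float = 1.8) -> bool:
        """Check consecutive ring atoms are within bonding distance."""
        idx = self.indices
        return all(
            structure.distance(idx[i], idx[(i + 1) % RING_SIZE]) < max_bond
            for i in range(RING_SIZE)
        )


@dataclass(frozen=True)
class PuckerParams:
    """Total amplitude Q (Å), polar angle θ and phase φ (degrees)."""

    q_total: float
    theta: float
    phi: float
    q2: float = 0.0
    q3: float = 0.0


def cremer_pople(structure: Structure, ring: RingSelection) -> PuckerParams:
    """Cremer-Pople puckering parameters of a six-membered ring.

    Raises ``ValueError`` for degenerate (collinear) rings where the mean
    plane is undefined.  At the poles (θ = 0 or 180°) φ is undefined and
    reported as 0 by convention.
    """
    coords = structure.coords[list(ring.indices)]
    center = coords.mean(axis=0)
    r = coords - center
    j = np.arange(RING_SIZE)
    # mean-plane normal from the two weighted lattice sums
    rp = (r * np.sin(2.0 * np.pi * j / RING_SIZE)[:, None]).sum(axis=0)
    rpp = (r * np.cos(2.0 * np.pi * j / RING_SIZE)[:, None]).sum(axis=0)
    # orientation chosen so the all-even-positions-up chair maps to θ = 0,
    # i.e. ⁴C₁ sits at the north pole for the O5-anchored pyranose ring
    normal = np.cross(rpp, rp)
    nn = np.linalg.norm(normal)
    if nn < 1e-10:
        raise ValueError("degenerate (collinear) ring: mean plane undefined")
    normal /= nn
    z = r @ normal

    ang = 2.0 * np.pi * 2.0 * j / RING_SIZE  # m = 2 mode
    q2c = np.sqrt(2.0 / RING_SIZE) * float(np.sum(z * np.cos(ang)))
    q2s = -np.sqrt(2.0 / RING_SIZE) * float(np.sum(z * np.sin(ang)))
    q3 = np.sqrt(1.0 / RING_SIZE) * float(np.sum(z * (-1.0) ** j))
    q2 = float(np.hypot(q2c, q2s))
    q_total = float(np.hypot(q2, q3))
    theta = float(np.degrees(np.arctan2(q2, q3)))
    if q2 < 1e-10:
        phi = 0.0  # pole: phase undefined
    else:
        phi = float(np.degrees(np.arctan2(q2s, q2c)) % 360.0)
        if phi >= 360.0:  # tiny negative angles wrap to exactly 360.0
            phi = 0.0
    return PuckerParams(q_total=q_total, theta=theta, phi=phi, q2=q2, q3=q3)


# ---------------------------------------------------------------------------
# canonical conformer table, generated from ideal displacement patterns
# ---------------------------------------------------------------------------

def _params_of_z(z: np.ndarray) -> tuple[float, float]:
    """(θ, φ) of an ideal displacement pattern via a hexagon embedding."""
    t = 2.0 * np.pi * np.arange(RING_SIZE) / RING_SIZE
    coords = np.column_stack([1.45 * np.cos(t), 1.45 * np.sin(t), z])
    s = Structure(labels=["C"] * RING_SIZE, coords=coords)
    p = cremer_pople(s, RingSelection(tuple(range(RING_SIZE))))
    return p.theta, p.phi


def _canonical_table(positions: tuple[str, ...] = PYRANOSE_POSITIONS):
    """Build the 38 canonical conformers: (label, θ, φ)."""
    table: list[tuple[str, float, float]] = []
    z0 = 0.25

    def add(label, z):
        theta, phi = _params_of_z(np.asarray(z, dtype=float))
        table.append((label, theta, phi))

    alt = np.array([(-1.0) ** j for j in range(RING_SIZE)])
    # chairs: even positions up -> 4C1 for the pyranose anchoring
    add(f"{positions[4]}C{positions[1]}", z0 * alt)
    add(f"{positions[1]}C{positions[4]}", -z0 * alt)

    for r in range(RING_SIZE):
        # envelopes: single atom out of plane
        z = np.zeros(RING_SIZE)
        z[r] = 4 * z0
        add(f"{positions[r]}E", z)
        add(f"E{positions[r]}", -z)
        # half-chairs: adjacent pair displaced to opposite sides (both signs)
        z = np.zeros(RING_SIZE)
        z[r], z[(r + 1) % RING_SIZE] = 2 * z0, -2 * z0
        add(f"{positions[r]}H{positions[(r + 1) % RING_SIZE]}", z)
        add(f"{positions[(r + 1) % RING_SIZE]}H{positions[r]}", -z)
    for r in range(3):
        # boats: para pair displaced to the same side
        z = np.full(RING_SIZE, -z0)
        z[r] = z[r + 3] = 2 * z0
        add(f"{positions[r]},{positions[r + 3]}B", z)
        add(f"B{positions[r]},{positions[r + 3]}", -z)
    # twist-boats (skew forms): the meta pair (a up, b down) out of the
    # plane of the remaining four atoms; the standard pyranose set
    for a, b in ((1, 3), (3, 1), (1, 5), (5, 1), (0, 2), (2, 0)):
        z = np.zeros(RING_SIZE)
        z[a], z[b] = 2 * z0, -2 * z0
        add(f"{positions[a]}S{positions[b]}", z)
    return table


_CANONICAL = _canonical_table()


def _sphere_distance(th1, ph1, th2, ph2) -> float:
    """Great-circle distance (degrees) on the puckering sphere."""
    t1, p1, t2, p2 = map(np.radians, (th1, ph1, th2, ph2))
    c = np.sin(t1) * np.sin(t2) * np.cos(p1 - p2) + np.cos(t1) * np.cos(t2)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class ConformerLabel:
    label: str
    distance: float          # degrees to the canonical point
    runner_up: str | None    # second-nearest label when within 15°
    runner_up_distance: float | None


def classify_conformer(
    params: PuckerParams, planarity_threshold: float = 0.1
) -> ConformerLabel:
    """Nearest canonical conformer (plus runner-up for partial character).

    Below the amplitude threshold the ring is reported as ``planar``.  The
    runner-up label is reported when its canonical point lies within 15° of
    the best match's distance, flagging e.g. an envelope with partial
    half-chair character.
    """
    if params.q_total < planarity_threshold:
        return ConformerLabel("planar", 0.0, None, None)
    dists = sorted(
        (
            _sphere_distance(params.theta, params.phi, th, ph),
            label,
        )
        for label, th, ph in _CANONICAL
    )
    best_d, best = dists[0]
    second_d, second = dists[1]
    if second_d - best_d <= 15.0:
        return ConformerLabel(best, best_d, second, second_d)
    return ConformerLabel(best, best_d, None, None)


def itinerary(
    structures: list[Structure], ring: RingSelection
) -> pd.DataFrame:
    """Per-frame puckering parameters plus pseudorotational quadrant.

    Returns a table with one row per structure: Q, θ, φ, the conformer
    label and the quadrant of the pseudorotation phase φ (1: [0°, 90°), …,
    4: [270°, 360°)), summarizing which sector of the itinerary the ring
    traverses.
    """
    if len(structures) < 1:
        raise ValueError("need at least one structure")
    rows = []
    for i, s in enumerate(structures):
        p = cremer_pople(s, ring)
        label = classify_conformer(p)
        rows.append(
            {
                "frame": i,
                "Q": p.q_total,
                "theta": p.theta,
                "phi": p.phi,
                "conformer": label.label,
                "runner_up": label.runner_up or "",
                "phi_quadrant": int(p.phi // 90.0) + 1,
            }
        )
    return pd.DataFrame(rows)


def quadrant_summary(frame_table: pd.DataFrame) -> dict[int, int]:
    """Occupancy count of pseudorotation-phase quadrants in an itinerary."""
    return frame_table["phi_quadrant"].value_counts().sort_index().to_dict()
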