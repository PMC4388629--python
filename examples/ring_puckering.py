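"""Cremer-Pople puckering analysis of six-membered rings.

Builds ideal chair and boat rings plus a chair-to-boat morph, computes the
(Q, θ, φ) puckering coordinates and classifies each frame against the 38
canonical conformers.
"""

import numpy as np

from mepkit import RingSelection, classify_conformer, cremer_pople
from mepkit.puckering import itinerary, quadrant_summary
from mepkit.structures import Structure

ring = RingSelection((0, 1, 2, 3, 4, 5))
t = 2 * np.pi * np.arange(6) / 6


def hexagon(z):
    return Structure(labels=["C"] * 6,
                     coords=np.column_stack([1.45 * np.cos(t),
                                             1.45 * np.sin(t), z]))


chair = hexagon(0.25 * (-1.0) ** np.arange(6))
p = cremer_pople(chair, ring)
print(f"ideal chair:  Q = {p.q_total:.3f} A, theta = {p.theta:.1f} deg "
      f"-> {classify_conformer(p).label}")
# theta = 0 is the northern pole of the puckering sphere: the 4C1 chair

boat = hexagon(np.array([0.3, -0.15, -0.15, 0.3, -0.15, -0.15]))
p = cremer_pople(boat, ring)
print(f"ideal boat:   Q = {p.q_total:.3f} A, theta = {p.theta:.1f} deg, "
      f"phi = {p.phi:.0f} deg -> {classify_conformer(p).label}")

# a pseudorotational itinerary: morph the chair into the boat
frames = [hexagon((1 - u) * chair.coords[:, 2] + u * boat.coords[:, 2])
          for u in np.linspace(0, 1, 6)]
table = itinerary(frames, ring)
print(table.round(2).to_string(index=False))
print("phase-quadrant occupancy:", quadrant_summary(table))
# theta runs from the pole toward the equator as chair character is lost;
# intermediate frames pick up envelope/half-chair labels with a runner-up
# marking partial character
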