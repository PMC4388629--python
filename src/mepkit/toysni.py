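"""A synthetic front-face nucleophilic-substitution (S_N_i) molecular model.

The model emulates, at desk scale, the reactive core of a glycosyl-transfer
reaction: an anomeric-like carbon C1 exchanges a leaving-group oxygen O1 for
a nucleophile oxygen OA while a proton H moves synchronously from OA to O1.
Seven atoms are used:

========  =======================================================
``C1``    electrophilic carbon (anomeric analogue)
``O1``    leaving-group oxygen (phosphate analogue), anchored to P
``OA``    nucleophile oxygen (acceptor hydroxyl analogue)
``H``     the transferred proton
``P``     anchor atom bonded to O1 (leaving-group scaffold)
``C2,C3`` spectator carbons bonded to C1 (thicken the Hessian)
========  =======================================================

The energy is a sum of closed-form terms of interatomic distances and one
angle, so it is exactly invariant under rigid motions and has analytic
gradients:

* Morse wells for the four exchangeable bonds C1-O1, C1-OA, OA-H, O1-H;
* *anti-cooperativity couplings* ``C · B(r_a) · B(r_b)`` with logistic
  bond-order switches ``B``, penalizing simultaneous bonding of C1 to both
  oxygens (and of H to both oxygens) — this is what creates two separated
  basins with a barrier between them, and what makes the unsampled C1-O1
  distance a *hidden coordinate* that jumps abruptly when a scan drives
  d(C1-OA) without controlling d(C1-O1);
* harmonic scaffold bonds (O1-P, C1-C2, C1-C3) and one angle (C2-C1-C3);
* soft exponential repulsions between non-bonded pairs;
* a one-sided harmonic pocket wall keeping the unbound nucleophile from
  drifting out of the reactive site;
* optionally a shallow Gaussian well in the (d(C1-O1), d(C1-OA)) plane
  producing a metastable dissociated (oxocarbenium-like) intermediate.

Equilibrium bond lengths follow the stationary-point distances of a
glycosyltransferase reaction (reactant C1-O1 1.513 Å, product C1-OA
1.467 Å, O-H 0.97/1.04 Å); well depths and couplings are calibrated once so
the default model shows a single dominant barrier of a few tens of
kcal mol⁻¹ in the distance-difference plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .models import EnergyEvaluation, EnergyModel, ModelError
from .optimize import ConvergenceSpec, minimize_bfgs
from .structures import Structure

ATOM_ORDER = ("C1", "O1", "OA", "H", "P", "C2", "C3")
ATOM_INDEX = {name: i for i, name in enumerate(ATOM_ORDER)}
_ELEMENTS = ("C", "O", "O", "H", "P", "C", "C")


@dataclass(frozen=True)
class MorseTerm:
    depth: float   # Hartree
    width: float   # Å⁻¹
    r0: float      # Å


@dataclass(frozen=True)
class SwitchTerm:
    """Logistic bond-order switch B(r) = 1 / (1 + exp((r - r_mid)/w))."""

    r_mid: float
    w: float


@dataclass(frozen=True)
class ToySNiParams:
    """Parameter set for :class:`ToySNiModel` (defaults are the calibrated set)."""

    morse_c1_o1: MorseTerm = MorseTerm(0.085, 2.5, 1.513)
    morse_c1_oa: MorseTerm = MorseTerm(0.070, 3.0, 1.467)
    morse_oa_h: MorseTerm = MorseTerm(0.055, 2.6, 0.972)
    morse_o1_h: MorseTerm = MorseTerm(0.060, 2.4, 1.038)
    # anti-cooperativity couplings
    c_sub: float = 0.120
    switch_c1_o1: SwitchTerm = SwitchTerm(2.00, 0.20)
    switch_c1_oa: SwitchTerm = SwitchTerm(2.00, 0.20)
    c_prot: float = 0.040
    switch_oa_h: SwitchTerm = SwitchTerm(1.30, 0.12)
    switch_o1_h: SwitchTerm = SwitchTerm(1.30, 0.12)
    #: cross-coupling: O1 turns into a good proton acceptor only once the
    #: C1-O1 bond has broken (leaving-group basicity grows on heterolysis),
    #: E = −c_cross (1 − B(d_C1O1)) B(d_O1H)
    c_cross: float = 0.040
    # scaffold
    k_bond: float = 1.5           # Hartree Å⁻², harmonic scaffold bonds
    r_o1_p: float = 1.60
    r_c_c: float = 1.52
    k_angle: float = 0.15         # Hartree, on (cos θ - cos θ0)²
    theta0_deg: float = 109.5
    # nonbonded repulsion A exp(-r/rho)
    rep_a: float = 15.0
    rep_rho: float = 0.30
    # pocket wall holding the unbound nucleophile near the site
    pocket_r: float = 3.05
    pocket_k: float = 0.08
    # optional shallow intermediate (oxocarbenium-like) well
    intermediate_depth: float = 0.0      # Hartree; 0 disables
    intermediate_center: tuple[float, float] = (2.35, 2.55)  # (d(C1-O1), d(C1-OA))
    intermediate_sigma: float = 0.25


def _morse(r: float, t: MorseTerm) -> tuple[float, float]:
    e = np.exp(-t.width * (r - t.r0))
    return t.depth * (1.0 - e) ** 2, 2.0 * t.depth * t.width * e * (1.0 - e)


def _switch(r: float, t: SwitchTerm) -> tuple[float, float]:
    b = 1.0 / (1.0 + np.exp((r - t.r_mid) / t.w))
    return b, -b * (1.0 - b) / t.w


# scaffold bonds as (i, j, r0) index pairs; repulsion pair list
_SCAFFOLD_BONDS = (("O1", "P"), ("C1", "C2"), ("C1", "C3"))
_REPULSION_PAIRS = (
    ("O1", "OA"), ("P", "OA"), ("P", "C1"), ("P", "C2"), ("P", "C3"),
    ("P", "H"), ("C2", "O1"), ("C3", "O1"), ("C2", "OA"), ("C3", "OA"),
    ("C2", "C3"), ("C2", "H"), ("C3", "H"), ("H", "C1"),
)


class ToySNiModel(EnergyModel):
    """Closed-form reactive model with analytic gradients (7 atoms)."""

    def __init__(self, params: ToySNiParams | None = None):
        self.params = params or ToySNiParams()
        self.atom_index = dict(ATOM_INDEX)

    def check(self, structure: Structure) -> None:
        super().check(structure)
        if structure.n_atoms != len(ATOM_ORDER):
            raise ModelError(
                f"ToySNiModel expects {len(ATOM_ORDER)} atoms, got {structure.n_atoms}"
            )

    # -- helpers ------------------------------------------------------------

    def _dist(self, coords, a: str, b: str) -> tuple[float, np.ndarray]:
        i, j = ATOM_INDEX[a], ATOM_INDEX[b]
        d = coords[j] - coords[i]
        r = float(np.linalg.norm(d))
        if r < 1e-10:
            raise ModelError(f"atoms {a} and {b} coincide")
        return r, d / r

    def evaluate(self, structure: Structure) -> EnergyEvaluation:
        p = self.params
        coords = structure.coords
        grad = np.zeros_like(coords)
        energy = 0.0

        def add_pair(a: str, b: str, e: float, dedr: float, unit: np.ndarray):
            nonlocal energy
            i, j = ATOM_INDEX[a], ATOM_INDEX[b]
            energy += e
            grad[i] -= dedr * unit
            grad[j] += dedr * unit

        # key distances (cached for the coupling terms)
        r1, u1 = self._dist(coords, "C1", "O1")
        r2, u2 = self._dist(coords, "C1", "OA")
        r3, u3 = self._dist(coords, "OA", "H")
        r4, u4 = self._dist(coords, "O1", "H")

        for (a, b, r, u, t) in (
            ("C1", "O1", r1, u1, p.morse_c1_o1),
            ("C1", "OA", r2, u2, p.morse_c1_oa),
            ("OA", "H", r3, u3, p.morse_oa_h),
            ("O1", "H", r4, u4, p.morse_o1_h),
        ):
            e, dedr = _morse(r, t)
            add_pair(a, b, e, dedr, u)

        # anti-cooperativity: C1 bonded to both oxygens
        b1, db1 = _switch(r1, p.switch_c1_o1)
        b2, db2 = _switch(r2, p.switch_c1_oa)
        add_pair("C1", "O1", p.c_sub * b1 * b2, p.c_sub * db1 * b2, u1)
        add_pair("C1", "OA", 0.0, p.c_sub * b1 * db2, u2)
        # anti-cooperativity: H bonded to both oxygens
        b3, db3 = _switch(r3, p.switch_oa_h)
        b4, db4 = _switch(r4, p.switch_o1_h)
        add_pair("OA", "H", p.c_prot * b3 * b4, p.c_prot * db3 * b4, u3)
        add_pair("O1", "H", 0.0, p.c_prot * b3 * db4, u4)

        # leaving-group basicity: O1-H formation favorable once C1-O1 broke
        if p.c_cross != 0.0:
            add_pair("C1", "O1", -p.c_cross * (1.0 - b1) * b4,
                     p.c_cross * db1 * b4, u1)
            add_pair("O1", "H", 0.0, -p.c_cross * (1.0 - b1) * db4, u4)

        # optional shallow dissociated intermediate
        if p.intermediate_depth > 0.0:
            c1, c2 = p.intermediate_center
            s2 = p.intermediate_sigma**2
            g = np.exp(-((r1 - c1) ** 2 + (r2 - c2) ** 2) / (2.0 * s2))
            add_pair("C1", "O1", -p.intermediate_depth * g,
                     p.intermediate_depth * g * (r1 - c1) / s2, u1)
            add_pair("C1", "OA", 0.0,
                     p.intermediate_depth * g * (r2 - c2) / s2, u2)

        # pocket wall on the nucleophile distance (one-sided harmonic)
        if r2 > p.pocket_r:
            add_pair("C1", "OA", 0.5 * p.pocket_k * (r2 - p.pocket_r) ** 2,
                     p.pocket_k * (r2 - p.pocket_r), u2)

        # scaffold bonds
        for a, b in _SCAFFOLD_BONDS:
            r0 = p.r_o1_p if a == "O1" else p.r_c_c
            r, u = self._dist(coords, a, b)
            add_pair(a, b, 0.5 * p.k_bond * (r - r0) ** 2, p.k_bond * (r - r0), u)

        # C2-C1-C3 angle (harmonic in cos θ)
        i, jc, k = ATOM_INDEX["C2"], ATOM_INDEX["C1"], ATOM_INDEX["C3"]
        va = coords[i] - coords[jc]
        vb = coords[k] - coords[jc]
        ra, rb = np.linalg.norm(va), np.linalg.norm(vb)
        cos_t = float(va @ vb / (ra * rb))
        c0 = np.cos(np.deg2rad(p.theta0_deg))
        energy += p.k_angle * (cos_t - c0) ** 2
        pref = 2.0 * p.k_angle * (cos_t - c0)
        dcos_da = vb / (ra * rb) - cos_t * va / ra**2
        dcos_db = va / (ra * rb) - cos_t * vb / rb**2
        grad[i] += pref * dcos_da
        grad[k] += pref * dcos_db
        grad[jc] -= pref * (dcos_da + dcos_db)

        # soft repulsions
        for a, b in _REPULSION_PAIRS:
            r, u = self._dist(coords, a, b)
            e = p.rep_a * np.exp(-r / p.rep_rho)
            add_pair(a, b, e, -e / p.rep_rho, u)

        return EnergyEvaluation(energy=float(energy), gradient=grad)


def _initial_geometries(params: ToySNiParams) -> tuple[np.ndarray, np.ndarray]:
    """Hand-built approximate reactant and product geometries (Å)."""
    react = np.zeros((7, 3))
    react[ATOM_INDEX["C1"]] = (0.0, 0.0, 0.0)
    react[ATOM_INDEX["O1"]] = (params.morse_c1_o1.r0, 0.0, 0.0)
    react[ATOM_INDEX["P"]] = (params.morse_c1_o1.r0 + 1.45, 0.75, 0.0)
    react[ATOM_INDEX["OA"]] = (1.50, 2.60, 0.0)
    react[ATOM_INDEX["H"]] = (1.51, 1.63, 0.0)
    react[ATOM_INDEX["C2"]] = (-1.07, 0.0, 1.07)
    react[ATOM_INDEX["C3"]] = (-1.07, 0.0, -1.07)

    prod = react.copy()
    prod[ATOM_INDEX["OA"]] = (0.73, 1.27, 0.0)
    prod[ATOM_INDEX["O1"]] = (3.30, 0.9, 0.0)
    prod[ATOM_INDEX["P"]] = (4.75, 1.6, 0.0)
    prod[ATOM_INDEX["H"]] = (2.45, 1.23, 0.0)
    return react, prod


def build_toy_sni(
    params: ToySNiParams | None = None,
    seed: int = 0,
    jitter: float = 0.0,
) -> tuple[ToySNiModel, Structure, Structure]:
    """Build the model plus locally minimized reactant and product structures.

    ``seed`` controls only the optional jitter (Å, Gaussian) applied to the
    spectator atoms P, C2, C3 before minimization; with ``jitter=0`` the
    construction is fully deterministic.  Raises :class:`ModelError` when the
    parameter set collapses the two basins into one.
    """
    params = params or ToySNiParams()
    model = ToySNiModel(params)
    react_xyz, prod_xyz = _initial_geometries(params)
    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        for name in ("P", "C2", "C3"):
            react_xyz[ATOM_INDEX[name]] += rng.normal(0.0, jitter, 3)
            prod_xyz[ATOM_INDEX[name]] += rng.normal(0.0, jitter, 3)

    spec = ConvergenceSpec(gmax=1e-7, max_steps=5000)
    out = []
    for xyz in (react_xyz, prod_xyz):
        s = Structure(labels=list(_ELEMENTS), coords=xyz,
                      names=list(ATOM_ORDER))
        out.append(minimize_bfgs(model, s, spec).structure)
    reactant, product = out

    d = lambda s, a, b: s.distance(ATOM_INDEX[a], ATOM_INDEX[b])
    if not (d(reactant, "C1", "O1") < 2.0 < d(reactant, "C1", "OA")):
        raise ModelError("reactant basin lost: C1-O1 not bound or OA collapsed")
    if not (d(product, "C1", "OA") < 2.0 < d(product, "C1", "O1")):
        raise ModelError("product basin lost: C1-OA not bound or O1 re-bound")
    return model, reactant, product


def key_cvs() -> dict:
    """The model's canonical collective variables by name.

    ``sub``  — d(C1-OA) − d(C1-O1), the nucleophilic-substitution coordinate;
    ``prot`` — d(O1-H) − d(OA-H), the proton-transfer coordinate;
    plus the four underlying distances.
    """
    from .colvars import DistanceCV, DistanceDifferenceCV

    I = ATOM_INDEX
    return {
        "sub": DistanceDifferenceCV(I["C1"], I["OA"], I["C1"], I["O1"], name="sub"),
        "prot": DistanceDifferenceCV(I["O1"], I["H"], I["OA"], I["H"], name="prot"),
        "d_c1_o1": DistanceCV(I["C1"], I["O1"], name="d_c1_o1"),
        "d_c1_oa": DistanceCV(I["C1"], I["OA"], name="d_c1_oa"),
        "d_oa_h": DistanceCV(I["OA"], I["H"], name="d_oa_h"),
        "d_o1_h": DistanceCV(I["O1"], I["H"], name="d_o1_h"),
    }


def default_waypoints(reactant: Structure, product: Structure) -> list[tuple[float, float]]:
    """Hand-picked (sub, prot) waypoints through the reaction channel.

    Chosen from the distance-difference map: the proton transfers while the
    substitution coordinate is still descending steeply, so the combined
    profile keeps a single dominant barrier.
    """
    cvs = key_cvs()
    from .colvars import cv_value

    rs, rq = cv_value(cvs["sub"], reactant), cv_value(cvs["prot"], reactant)
    ps, pq = cv_value(cvs["sub"], product), cv_value(cvs["prot"], product)
    return [(rs, rq), (0.6, 0.42), (0.0, 0.40), (-0.7, 0.10), (-1.2, -0.30), (ps, pq)]


#: Parameter preset with the shallow metastable intermediate enabled:
#: the band profile develops a local minimum about 0.8 kcal mol⁻¹ deep in
#: the dissociated oxocarbenium-like region near the barrier top.
INTERMEDIATE_PRESET = replace(ToySNiParams(), intermediate_depth=0.008)

PRESETS = {
    "toy-sni": ToySNiParams(),
    "toy-sni-intermediate": INTERMEDIATE_PRESET,
}
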