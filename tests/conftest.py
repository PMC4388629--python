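"""Shared fixtures: the synthetic reactive system, its scans and paths.

Heavy artifacts (2D scans, converged bands, steepest-descent oracles) are
session-scoped: they are deterministic and read-only for the tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import fsolve

from mepkit.models import MullerBrown, muller_brown, muller_brown_hessian
from mepkit.neb import NEBConfig, Path, densify, init_path_from_waypoints, neb_optimize
from mepkit.optimize import ConvergenceSpec, FIREParams, minimize_bfgs
from mepkit.scan import ScanAxis, run_scan
from mepkit.toysni import build_toy_sni, default_waypoints, key_cvs

SCAN_SPEC = ConvergenceSpec(gmax=1e-4, max_steps=4000)


@pytest.fixture(scope="session")
def toy_system():
    """Default-parameter synthetic S_N_i model with optimized endpoints."""
    return build_toy_sni()


@pytest.fixture(scope="session")
def toy_cvs():
    return key_cvs()


@pytest.fixture(scope="session")
def toy_dd_map(toy_system, toy_cvs):
    """Distance-difference 2D scan over the standard axes (18 × 12 grid)."""
    model, reactant, _ = toy_system
    ax1 = ScanAxis(toy_cvs["sub"], 1.60, -1.80, -0.20, name="sub")
    ax2 = ScanAxis(toy_cvs["prot"], 0.80, -0.30, -0.10, name="prot")
    return run_scan(
        model, reactant, ax1, ax2, restraint_k=5.0, spec=SCAN_SPEC,
        monitors={"d_c1_o1": toy_cvs["d_c1_o1"], "d_oa_h": toy_cvs["d_oa_h"]},
    )


@pytest.fixture(scope="session")
def toy_distance_map(toy_system, toy_cvs):
    """Distance-based 2D scan (the coordinate system with hidden jumps)."""
    model, reactant, _ = toy_system
    ax1 = ScanAxis(toy_cvs["d_c1_oa"], 3.00, 1.50, -0.15, name="d_c1_oa")
    ax2 = ScanAxis(toy_cvs["d_o1_h"], 1.80, 1.05, -0.15, name="d_o1_h")
    return run_scan(
        model, reactant, ax1, ax2, restraint_k=5.0, spec=SCAN_SPEC,
        monitors={"d_c1_o1": toy_cvs["d_c1_o1"]}, keep_structures=False,
    )


@pytest.fixture(scope="session")
def toy_neb(toy_system, toy_cvs):
    """Converged switched band for the synthetic model."""
    model, reactant, product = toy_system
    structures = init_path_from_waypoints(
        model, reactant, (toy_cvs["sub"], toy_cvs["prot"]),
        default_waypoints(reactant, product), n=21, restraint_k=5.0,
    )
    path = densify(structures, 0.25)
    initial = path.copy()
    final, trace = neb_optimize(path, model, NEBConfig())
    return final, trace, initial


@pytest.fixture(scope="session")
def mb():
    return MullerBrown()


@pytest.fixture(scope="session")
def mb_stationary(mb):
    """Numerically refined Müller-Brown minima and saddles (the oracle)."""
    minima = []
    for guess in mb.MINIMA_GUESS:
        res = minimize_bfgs(mb, mb.structure_at(*guess),
                            ConvergenceSpec(gmax=1e-9, max_steps=2000))
        minima.append((res.structure.coords[0, :2].copy(), res.energy))
    saddles = []
    for guess in mb.SADDLES_GUESS:
        xy = fsolve(lambda p: muller_brown(*p)[1], np.array(guess), xtol=1e-13)
        saddles.append((xy, muller_brown(*xy)[0]))
    return {"minima": minima, "saddles": saddles}


@pytest.fixture(scope="session")
def mb_mep(mb_stationary):
    """Fine-step steepest-descent path through both saddles (dense polyline)."""
    segments = []
    for xy, _ in mb_stationary["saddles"]:
        H = muller_brown_hessian(*xy)
        w, v = np.linalg.eigh(H)
        down = v[:, 0]
        for sign in (1.0, -1.0):
            p = xy + sign * 1e-3 * down
            pts = [p.copy()]
            for _ in range(20000):
                _, g = muller_brown(*p)
                gn = np.linalg.norm(g)
                if gn < 0.05:  # within ~1e-3 of a minimum at these curvatures
                    break
                p = p - 1e-3 * g / gn
                pts.append(p.copy())
            segments.append(np.array(pts))
    segments.append(np.array([xy for xy, _ in mb_stationary["minima"]]))
    return np.vstack(segments)


@pytest.fixture(scope="session")
def mb_neb(mb, mb_stationary):
    """Converged 15-image switched band between the two outer minima."""
    (a, _), (b, _), _ = mb_stationary["minima"]
    images = [mb.structure_at(*((1 - t) * a + t * b)) for t in np.linspace(0, 1, 15)]
    cfg = NEBConfig(
        conv_gmax=0.1, max_steps=40000,
        fire=FIREParams(dt_init=0.01, dt_max=0.05, max_disp=0.05),
    )
    return neb_optimize(Path(images), mb, cfg)
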