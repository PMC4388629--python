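"""Band machinery: tangents, switching, forces, densification, optimization."""

import numpy as np
import pytest

from mepkit.models import AnalyticSurface2D, QuadraticField
from mepkit.neb import (
    NEBConfig,
    Path,
    densify,
    improved_tangent,
    init_path_from_waypoints,
    neb_forces,
    neb_optimize,
    path_maximum,
    path_profile,
    switch_fraction,
)
from mepkit.structures import Structure
from mepkit.colvars import cv_value
from mepkit.units import EV_TO_HARTREE


def _chain(points):
    """Flattened-coordinate array from a list of 2D points."""
    return np.array([[x, y, 0.0] for x, y in points])


class TestImprovedTangent:
    def test_monotone_energies_pick_forward_segment(self):
        coords = _chain([(0, 0), (1, 0.2), (2, 0)])
        tau = improved_tangent(coords, np.array([0.0, 1.0, 2.0]), 1)
        fwd = coords[2] - coords[1]
        assert tau == pytest.approx(fwd / np.linalg.norm(fwd))

    def test_monotone_decreasing_pick_backward_segment(self):
        coords = _chain([(0, 0), (1, 0.2), (2, 0)])
        tau = improved_tangent(coords, np.array([2.0, 1.0, 0.0]), 1)
        bwd = coords[1] - coords[0]
        assert tau == pytest.approx(bwd / np.linalg.norm(bwd))

    def test_local_maximum_mixes_segments_by_energy_weights(self):
        coords = _chain([(0, 0), (1, 0), (2, 1)])
        energies = np.array([0.0, 3.0, 1.0])  # maximum at the middle image
        tau = improved_tangent(coords, energies, 1)
        # E_next (1.0) exceeds E_prev (0.0): the forward segment carries the
        # larger energy difference |E_prev - E_here| = 3, the backward the
        # smaller |E_next - E_here| = 2
        dmax, dmin = 3.0, 2.0
        expected = (coords[2] - coords[1]) * dmax + (coords[1] - coords[0]) * dmin
        assert tau == pytest.approx(expected / np.linalg.norm(expected))

    def test_collinear_equal_spacing_gives_common_direction(self):
        coords = _chain([(0, 0), (1, 0), (2, 0)])
        for energies in ([0, 1, 2], [2, 1, 0], [0, 2, 0], [1, 1, 1]):
            tau = improved_tangent(coords, np.array(energies, dtype=float), 1)
            assert np.abs(tau) == pytest.approx([1.0, 0.0, 0.0])

    def test_interior_only_and_zero_segment_rejected(self):
        coords = _chain([(0, 0), (1, 0), (2, 0)])
        with pytest.raises(ValueError):
            improved_tangent(coords, np.zeros(3), 0)
        dup = _chain([(0, 0), (0, 0), (2, 0)])
        with pytest.raises(ValueError):
            improved_tangent(dup, np.zeros(3), 1)


class TestSwitchFraction:
    @pytest.mark.parametrize(
        "phi,expected",
        [(0.0, 0.0), (np.pi / 2, 1.0), (np.pi / 3, 0.5)],
    )
    def test_exact_values(self, phi, expected):
        """f(0)=0 (straight), f(π/2)=1 (right angle), f(π/3)=½."""
        assert switch_fraction(phi) == pytest.approx(expected, abs=1e-15)

    def test_range_bounded(self):
        phis = np.linspace(0.0, np.pi, 181)
        f = np.array([switch_fraction(p) for p in phis])
        assert (f >= 0).all() and (f <= 1).all()


def _flat_model():
    return AnalyticSurface2D(lambda x, y: (0.0, np.array([0.0, 0.0])))


class TestNEBForces:
    def test_straight_equidistant_band_is_in_equilibrium(self):
        coords = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        f = neb_forces(coords, np.zeros(5), np.zeros((5, 3)), NEBConfig())
        assert np.abs(f).max() == pytest.approx(0.0, abs=1e-14)

    def test_unequal_spacing_produces_parallel_spring_only(self):
        coords = np.array([[0.0, 0, 0], [0.8, 0, 0], [2.0, 0, 0]])
        cfg = NEBConfig(spring_k_ev=5.0)
        f = neb_forces(coords, np.zeros(3), np.zeros((3, 3)), cfg)
        expected = cfg.spring_k * (1.2 - 0.8)
        assert f[1] == pytest.approx([expected, 0.0, 0.0])

    def test_kinked_band_feels_straightening_force(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0.6, 0], [2.0, 0, 0]])
        f = neb_forces(coords, np.zeros(3), np.zeros((3, 3)), NEBConfig())
        assert f[1, 1] < -1e-4  # pushes the kink down toward the chord
        moved = coords.copy()
        moved[1] += 0.1 * f[1] / np.linalg.norm(f[1])

        def kink_angle(c):
            a, b = c[1] - c[0], c[2] - c[1]
            return np.degrees(np.arccos(a @ b / (np.linalg.norm(a) * np.linalg.norm(b))))

        assert kink_angle(moved) < kink_angle(coords)

    def test_force_decomposition_identities(self, toy_neb):
        """Parallel component equals the spring term; the true-force part
        carries no tangential projection (to 1e-10)."""
        path, _, _ = toy_neb
        from mepkit.neb import improved_tangent as tangent

        coords = path.mobile_coords()
        energies = path.energies
        model_forces = neb_forces(
            coords, energies,
            np.zeros_like(coords),  # spring-only forces
            NEBConfig(switch_on=False),
        )
        cfg = NEBConfig(switch_on=False)
        for i in (1, path.n_images // 2, path.n_images - 2):
            tau = tangent(coords, energies, i)
            lf = np.linalg.norm(coords[i + 1] - coords[i])
            lb = np.linalg.norm(coords[i] - coords[i - 1])
            assert model_forces[i] @ tau == pytest.approx(cfg.spring_k * (lf - lb),
                                                          abs=1e-10)
            # true-force nudging: perpendicular part has zero tangent overlap
            g = np.sin(np.arange(coords.shape[1]))  # arbitrary gradient
            f_true = -g
            f_perp = f_true - (f_true @ tau) * tau
            assert f_perp @ tau == pytest.approx(0.0, abs=1e-10)

    def test_spring_constant_unit_conversion(self):
        assert NEBConfig(spring_k_ev=5.0).spring_k == pytest.approx(5.0 * EV_TO_HARTREE)


class TestDensify:
    def _two_points(self, gap):
        a = Structure(labels=["X"], coords=np.array([[0.0, 0, 0]]))
        b = Structure(labels=["X"], coords=np.array([[gap, 0, 0]]))
        return [a, b]

    def test_binary_subdivision_arithmetic(self):
        """0.9 Å apart → 3 midpoint insertions → 4 segments < 0.25 Å."""
        path = densify(self._two_points(0.9), 0.25)
        assert path.n_images == 5
        coords = path.mobile_coords()
        seg = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        assert (seg < 0.25).all()
        assert seg == pytest.approx(np.full(4, 0.225))

    def test_short_segments_left_unchanged(self, toy_system):
        _, reactant, product = toy_system
        mid = reactant.with_coords(0.5 * (reactant.coords + product.coords))
        path = densify([reactant, mid, product], max_segment=1e6)
        assert path.n_images == 3

    def test_environment_copied_from_earlier_parent(self, toy_system):
        _, reactant, product = toy_system
        a, b = reactant.copy(), product.copy()
        for s in (a, b):
            s.roles = np.array(
                ["mobile"] * 5 + ["env", "env"], dtype=object)
        path = densify([a, b], 0.25)
        env = a.roles == "env"
        for im in path.images[1:-1]:
            assert np.array_equal(im.coords[env], a.coords[env])

    def test_needs_two_structures(self, toy_system):
        _, reactant, _ = toy_system
        with pytest.raises(ValueError):
            densify([reactant])


class TestWaypointInitialization:
    def test_two_waypoints_interpolate_linearly(self, toy_system, toy_cvs):
        model, reactant, _ = toy_system
        cv1, cv2 = toy_cvs["sub"], toy_cvs["prot"]
        a = (cv_value(cv1, reactant), cv_value(cv2, reactant))
        b = (a[0] - 0.4, a[1] - 0.2)
        structs = init_path_from_waypoints(model, reactant, (cv1, cv2), [a, b], n=3)
        mid = structs[1]
        assert cv_value(cv1, mid) == pytest.approx((a[0] + b[0]) / 2, abs=0.01)
        assert cv_value(cv2, mid) == pytest.approx((a[1] + b[1]) / 2, abs=0.01)

    def test_driven_structures_hit_their_targets(self, toy_system, toy_cvs):
        model, reactant, product = toy_system
        from mepkit.toysni import default_waypoints

        cv1, cv2 = toy_cvs["sub"], toy_cvs["prot"]
        wps = default_waypoints(reactant, product)
        structs = init_path_from_waypoints(model, reactant, (cv1, cv2), wps, n=21)
        assert len(structs) == 21
        assert cv_value(cv1, structs[-1]) == pytest.approx(wps[-1][0], abs=0.01)
        assert cv_value(cv2, structs[-1]) == pytest.approx(wps[-1][1], abs=0.01)

    def test_degenerate_waypoints_rejected(self, toy_system, toy_cvs):
        model, reactant, _ = toy_system
        a = (1.0, 0.5)
        with pytest.raises(ValueError):
            init_path_from_waypoints(model, reactant,
                                     (toy_cvs["sub"], toy_cvs["prot"]), [a, a])


class TestNEBOptimization:
    def test_toy_band_single_barrier_profile(self, toy_neb, toy_system):
        """The band shows one dominant maximum: a monotone rise, then a
        monotone fall, with no secondary feature above 0.5 kcal/mol."""
        path, _, _ = toy_neb
        from mepkit.units import HARTREE_TO_KCAL_PER_MOL

        e = (path.energies - path.energies[0]) * HARTREE_TO_KCAL_PER_MOL
        imax = int(np.argmax(e))
        assert 0 < imax < path.n_images - 1
        assert np.max(np.maximum(0.0, -np.diff(e[: imax + 1]))) < 0.5
        assert np.max(np.maximum(0.0, np.diff(e[imax:]))) < 0.5

    def test_fixed_endpoints_bit_identical(self, toy_neb):
        """Optimization never touches the fixed endpoint images."""
        path, _, initial = toy_neb
        assert np.array_equal(path.images[0].coords, initial.images[0].coords)
        assert np.array_equal(path.images[-1].coords, initial.images[-1].coords)

    def test_restart_from_converged_band_finishes_immediately(self, toy_neb, toy_system):
        path, _, _ = toy_neb
        model, _, _ = toy_system
        _, trace = neb_optimize(path, model, NEBConfig())
        assert trace.n_iterations <= 1

    def test_kink_suppression_on_flat_valley(self):
        """On a flat-bottomed valley a zigzag band stays kinked (>60°)
        without the switched perpendicular spring but straightens (<30°)
        with it."""
        # valley: harmonic in z, exactly flat in the (x, y) plane
        H = np.zeros((3, 3))
        H[2, 2] = 1.0

        class FlatValley(QuadraticField):
            def __init__(self):
                super().__init__(H, np.zeros(3))

        model = FlatValley()
        n = 9
        zig = [
            Structure(labels=["X"],
                      coords=np.array([[i * 1.0, 0.8 * (i % 2), 0.0]]))
            for i in range(n)
        ]

        def max_angle(p):
            coords = p.mobile_coords()
            segs = np.diff(coords, axis=0)
            angles = []
            for a, b in zip(segs, segs[1:]):
                c = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
                angles.append(np.degrees(np.arccos(np.clip(c, -1, 1))))
            return max(angles)

        assert max_angle(Path([s.copy() for s in zig])) > 60.0

        unswitched, _ = neb_optimize(
            Path([s.copy() for s in zig]), model,
            NEBConfig(switch_on=False, conv_gmax=1e-4, max_steps=20000))
        switched, _ = neb_optimize(
            Path([s.copy() for s in zig]), model,
            NEBConfig(switch_on=True, conv_gmax=1e-4, max_steps=20000))
        assert max_angle(unswitched) > 60.0
        assert max_angle(switched) < 30.0


class TestPathProfile:
    def test_reference_and_maximum(self, toy_neb, toy_cvs):
        path, _, _ = toy_neb
        table = path_profile(path, cvs={"sub": toy_cvs["sub"]})
        assert table.loc[0, "rel_energy_kcal"] == 0.0
        assert table["rel_energy_kcal"].idxmax() not in (0, len(table) - 1)

    def test_cv_columns_match_recompute(self, toy_neb, toy_cvs):
        path, _, _ = toy_neb
        table = path_profile(path, cvs={"sub": toy_cvs["sub"]})
        recomputed = [cv_value(toy_cvs["sub"], im) for im in path.images]
        assert table["sub"].to_numpy() == pytest.approx(recomputed)

    def test_interpolated_maximum_at_least_image_maximum(self, toy_neb):
        path, _, _ = toy_neb
        assert path_maximum(path) >= path.energies.max()
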