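"""Scan grids, outlier flagging, discontinuity detection, map analysis."""

import numpy as np
import pytest

from mepkit.colvars import DistanceCV, cv_value
from mepkit.models import muller_brown
from mepkit.scan import (
    PESMap,
    ScanAxis,
    build_grid,
    detect_discontinuities,
    flag_outliers,
    grid_stationary_points,
    project_structures,
)


def _axes_like_study():
    """The standard distance-difference axes: 18 × 12 points."""
    cv1, cv2 = DistanceCV(0, 2), DistanceCV(1, 3)
    ax1 = ScanAxis(cv1, 1.60, -1.80, -0.20)
    ax2 = ScanAxis(cv2, 0.80, -0.30, -0.10)
    return ax1, ax2


def _synthetic_map(energies, monitors=None):
    ax1 = ScanAxis(DistanceCV(0, 1), 0.0, float(energies.shape[0] - 1), 1.0)
    ax2 = ScanAxis(DistanceCV(0, 2), 0.0, float(energies.shape[1] - 1), 1.0)
    e = np.asarray(energies, dtype=float)
    return PESMap(
        axis1=ax1, axis2=ax2, energies=e,
        converged=np.ones_like(e, dtype=bool),
        outlier=np.zeros_like(e, dtype=bool),
        monitors=monitors or {},
    )


class TestGridConstruction:
    def test_study_axes_give_216_points(self):
        ax1, ax2 = _axes_like_study()
        assert ax1.n_points == 18
        assert ax2.n_points == 12
        assert len(build_grid(ax1, ax2)) == 216

    def test_scanline_major_parentage(self):
        ax1, ax2 = _axes_like_study()
        points = build_grid(ax1, ax2)
        # first sweep: axis1 at axis2.start, chained along axis1
        first = points[: ax1.n_points]
        assert [p.parent for p in first] == [None] + [
            (i, 0) for i in range(ax1.n_points - 1)
        ]
        # scanlines: each subsequent point hangs off its axis2 predecessor
        rest = points[ax1.n_points:]
        assert all(p.parent == (p.i, p.j - 1) for p in rest)

    def test_parentage_is_a_tree_rooted_at_origin(self):
        ax1, ax2 = _axes_like_study()
        points = build_grid(ax1, ax2)
        seen = set()
        for p in points:
            assert p.parent is None or p.parent in seen
            seen.add((p.i, p.j))
        assert sum(p.parent is None for p in points) == 1

    def test_single_point_axes(self):
        ax = ScanAxis(DistanceCV(0, 1), 1.0, 1.0, 0.5)
        assert ax.n_points == 1
        pts = build_grid(ax, ax)
        assert len(pts) == 1 and pts[0].parent is None

    def test_invalid_axes_rejected(self):
        with pytest.raises(ValueError):
            ScanAxis(DistanceCV(0, 1), 0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            ScanAxis(DistanceCV(0, 1), 0.0, 1.0, -0.5)


class TestOutlierRule:
    def test_single_spike_on_flat_grid(self):
        e = np.zeros((5, 5))
        e[2, 2] = 5.0
        flagged = flag_outliers(_synthetic_map(e))
        expected = np.zeros((5, 5), dtype=bool)
        expected[2, 2] = True
        assert np.array_equal(flagged.outlier, expected)

    def test_flat_grid_has_no_flags(self):
        flagged = flag_outliers(_synthetic_map(np.full((6, 4), 3.7)))
        assert not flagged.outlier.any()

    def test_boundary_uses_two_edge_neighbors(self):
        e = np.zeros((5, 5))
        e[0, 2] = 5.0   # edge point: compared to (0,1), (0,3) along the edge
        flagged = flag_outliers(_synthetic_map(e))
        assert flagged.outlier[0, 2]
        # its interior neighbor sees mean (5+0+0+0)/4 = 1.25 < 2: unflagged
        assert not flagged.outlier[1, 2]

    def test_corner_uses_its_two_boundary_neighbors(self):
        # a 3.5 spike flags the corner (vs 0-mean of its two edge neighbors)
        # but not those neighbors themselves (3.5/2 = 1.75 < 2)
        e = np.zeros((4, 4))
        e[0, 0] = 3.5
        flagged = flag_outliers(_synthetic_map(e))
        assert flagged.outlier[0, 0]
        assert flagged.outlier.sum() == 1

    def test_smooth_quadratic_surface_unflagged(self):
        x, y = np.meshgrid(np.linspace(-1, 1, 12), np.linspace(-1, 1, 10),
                           indexing="ij")
        flagged = flag_outliers(_synthetic_map(3.0 * x**2 + 2.0 * y**2 + x * y))
        assert not flagged.outlier.any()

    def test_idempotent_and_energy_preserving(self):
        e = np.zeros((5, 5))
        e[1, 3] = 9.0
        once = flag_outliers(_synthetic_map(e))
        twice = flag_outliers(once)
        assert np.array_equal(once.outlier, twice.outlier)
        assert np.array_equal(once.energies, twice.energies)

    def test_needs_at_least_2x2(self):
        with pytest.raises(ValueError):
            flag_outliers(_synthetic_map(np.zeros((1, 5))))


class TestDiscontinuityDetection:
    def test_constant_monitor_is_continuous(self):
        m = _synthetic_map(np.zeros((4, 4)), monitors={"d": np.full((4, 4), 1.5)})
        assert detect_discontinuities(m, "d", 0.5) == []

    def test_jump_edges_located(self):
        d = np.full((4, 4), 1.5)
        d[2:, :] = 3.2  # hidden coordinate snaps between rows 1 and 2
        m = _synthetic_map(np.zeros((4, 4)), monitors={"d": d})
        edges = detect_discontinuities(m, "d", 0.5)
        assert edges == [((1, j), (2, j)) for j in range(4)]

    def test_threshold_is_respected(self):
        d = np.full((3, 3), 1.0)
        d[2, :] = 1.4
        m = _synthetic_map(np.zeros((3, 3)), monitors={"d": d})
        assert detect_discontinuities(m, "d", 0.5) == []
        assert len(detect_discontinuities(m, "d", 0.3)) == 3

    def test_unknown_monitor_raises(self):
        m = _synthetic_map(np.zeros((3, 3)))
        with pytest.raises(KeyError):
            detect_discontinuities(m, "nope", 0.5)


class TestGridStationaryPoints:
    def test_quadratic_bowl_single_minimum(self):
        x, y = np.meshgrid(np.linspace(-1, 1, 9), np.linspace(-1, 1, 9),
                           indexing="ij")
        sp = grid_stationary_points(_synthetic_map((x - 0.1) ** 2 + (y + 0.2) ** 2))
        assert len(sp.minima) == 1
        i, j = sp.minima[0]
        assert abs(np.linspace(-1, 1, 9)[i] - 0.1) <= 0.25
        assert abs(np.linspace(-1, 1, 9)[j] + 0.2) <= 0.25

    def test_monotone_plane_has_no_interior_minima(self):
        x, y = np.meshgrid(np.arange(6.0), np.arange(5.0), indexing="ij")
        surface = 2.0 * x + y
        sp = grid_stationary_points(_synthetic_map(surface))
        # the global corner is the only descent sink on the grid graph
        assert sp.minima == [(0, 0)]

    def test_muller_brown_grid_minima_and_minimax_barrier(self, mb_stationary):
        """A 40×40 sampling shows 3 minima; the minimax barrier between the
        outer basins agrees with the true saddle to one grid-cell energy."""
        xs = np.linspace(-1.6, 1.1, 40)
        ys = np.linspace(-0.3, 2.0, 40)
        e = np.array([[min(muller_brown(x, y)[0], 300.0) for y in ys] for x in xs])
        m = _synthetic_map(e)
        sp = grid_stationary_points(m)
        assert len(sp.minima) == 3
        a, b = sp.minima[0], sp.minima[1]  # two deepest basins
        sp2 = grid_stationary_points(m, between=(a, b))
        true_saddle = mb_stationary["saddles"][0][1]
        cell = max(abs(np.diff(e, axis=0)).max(initial=0), 1.0)
        assert sp2.barrier is not None
        # one-grid-cell tolerance estimated from local energy variation
        i, j = sp2.saddle
        local = abs(e[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2] - e[i, j]).max()
        assert abs(sp2.barrier - true_saddle) <= local + 1e-9


class TestProjection:
    def test_projected_cv_values_match_recompute(self, toy_system, toy_cvs):
        _, reactant, product = toy_system
        pts = project_structures([reactant, product], toy_cvs["sub"], toy_cvs["prot"])
        assert pts.shape == (2, 2)
        assert pts[0, 0] == pytest.approx(cv_value(toy_cvs["sub"], reactant))
        assert pts[1, 1] == pytest.approx(cv_value(toy_cvs["prot"], product))

    def test_empty_list_gives_empty_output(self, toy_cvs):
        assert project_structures([], toy_cvs["sub"], toy_cvs["prot"]).shape == (0, 2)

    def test_scan_points_sit_on_their_grid_targets(self, toy_dd_map):
        """Self-consistency: re-projecting scan structures reproduces the
        grid targets within the restraint tracking tolerance."""
        m = toy_dd_map
        for (i, j), s in list(m.structures.items())[:: 17]:
            assert cv_value(m.axis1.cv, s) == pytest.approx(m.axis1.values[i], abs=0.02)
            assert cv_value(m.axis2.cv, s) == pytest.approx(m.axis2.values[j], abs=0.02)


class TestToyScans:
    def test_distance_difference_scan_converges_everywhere(self, toy_dd_map):
        assert toy_dd_map.converged.all()

    def test_reference_point_energy_is_zero(self, toy_dd_map):
        assert toy_dd_map.energies[0, 0] == 0.0

    def test_monitored_dissociation_distance_increases_along_scan(self, toy_dd_map):
        """d(C1-O1) grows monotonically (within grid noise) as the
        substitution coordinate is driven from reactant to product."""
        d = toy_dd_map.monitors["d_c1_o1"]
        col = d[:, 0]
        assert np.all(np.diff(col) > -0.05)
        assert col[-1] > col[0] + 1.0

    def test_scan_order_hysteresis_detector(self, toy_system, toy_cvs, toy_dd_map):
        """Scanning substitution-then-proton vs proton-then-substitution
        agrees within 1 kcal/mol everywhere on the smooth (single-valued)
        distance-difference surface; disagreement would localize a
        discontinuity."""
        from conftest import SCAN_SPEC
        from mepkit.scan import run_scan

        model, reactant, _ = toy_system
        swapped = run_scan(
            model, reactant,
            toy_dd_map.axis2, toy_dd_map.axis1,
            restraint_k=5.0, spec=SCAN_SPEC, keep_structures=False)
        # align references: both maps relative to their own first point,
        # which is the same (sub, prot) target in both orders
        diff = np.abs(toy_dd_map.energies - swapped.energies.T)
        assert diff.max() < 1.0
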