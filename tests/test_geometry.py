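"""Unit and property tests for the 3-D geometric primitives."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from brimplan.errors import DegenerateInputError, GeometryError, NoIntersectionError
from brimplan.geometry import (
    Plane,
    Polyline3,
    fit_circle_3d,
    fit_plane,
    plane_polyline_intersections,
    polyline_arc_length,
    project_point_to_polyline,
    ray_polyline_intersection,
    resample_polyline,
)
from helpers import random_rotation


def circle_arc(center, radius, normal, arc_deg, n, phase_deg=0.0):
    """Exact points on a circular arc in the plane with the given normal."""
    normal = np.asarray(normal, float) / np.linalg.norm(normal)
    seed = np.array([1.0, 0, 0]) if abs(normal[0]) < 0.9 else np.array([0.0, 1, 0])
    u = seed - (seed @ normal) * normal
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    ang = np.radians(phase_deg + np.linspace(0.0, arc_deg, n))
    return np.asarray(center) + radius * (
        np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v
    )


class TestFitPlane:
    def test_coplanar_square(self):
        pts = [(0, 0, 7), (1, 0, 7), (1, 1, 7), (0, 1, 7)]
        plane = fit_plane(pts)
        assert np.allclose(plane.normal, [0, 0, 1])
        assert plane.point[2] == pytest.approx(7.0)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateInputError):
            fit_plane([(0, 0, 0), (1, 1, 1), (2, 2, 2)])

    def test_too_few_points_raises(self):
        with pytest.raises(DegenerateInputError):
            fit_plane([(0, 0, 0), (1, 0, 0)])

    def test_noisy_plane_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        true_n = np.array([0.3, -0.4, 0.866])
        true_n /= np.linalg.norm(true_n)
        u = np.cross(true_n, [0, 0, 1.0])
        u /= np.linalg.norm(u)
        v = np.cross(true_n, u)
        coeff = rng.uniform(-30, 30, size=(50, 2))
        pts = coeff[:, :1] * u + coeff[:, 1:] * v + rng.normal(0, 0.1, size=(50, 3))

        plane = fit_plane(pts)
        angle_to_truth = np.degrees(np.arccos(abs(plane.normal @ true_n)))
        assert angle_to_truth < 0.5

        # independent oracle: smallest eigenvector of the covariance matrix
        centered = pts - pts.mean(axis=0)
        w, vecs = np.linalg.eigh(centered.T @ centered)
        oracle_n = vecs[:, 0]
        assert abs(plane.normal @ oracle_n) > 1 - 1e-10


class TestFitCircle:
    def test_exact_circle_recovered(self):
        pts = circle_arc((10, 20, 30), 95.0, (0, 0, 1), 360.0 * 99 / 100, 100)
        circle = fit_circle_3d(pts)
        assert np.linalg.norm(circle.center - [10, 20, 30]) < 1e-6
        assert circle.radius == pytest.approx(95.0, abs=1e-6)
        assert abs(circle.normal @ [0, 0, 1]) > 1 - 1e-9

    def test_collinear_raises(self):
        with pytest.raises(DegenerateInputError):
            fit_circle_3d([(0, 0, 0), (1, 0, 0), (2, 0, 0)])

    @pytest.mark.parametrize("arc_deg", [30, 60, 120, 300])
    def test_consistency_on_exact_arcs(self, arc_deg):
        rng = np.random.default_rng(arc_deg)
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        center = rng.uniform(-50, 50, size=3)
        pts = circle_arc(center, 47.0, normal, arc_deg, 25, phase_deg=rng.uniform(0, 360))
        circle = fit_circle_3d(pts)
        assert np.linalg.norm(circle.center - center) < 1e-6
        assert circle.radius == pytest.approx(47.0, abs=1e-6)
        assert abs(circle.normal @ normal) > 1 - 1e-9

    def test_noisy_arc_radius_and_gridsearch_oracle(self):
        # in-plane noise so a 2-D brute-force oracle applies exactly
        rng = np.random.default_rng(42)
        ang = np.radians(np.linspace(0, 60, 60))
        xy = 70.0 * np.column_stack([np.cos(ang), np.sin(ang)])
        xy += rng.normal(0, 0.2, size=xy.shape)
        pts = np.column_stack([xy, np.full(60, 5.0)])

        circle = fit_circle_3d(pts)
        assert circle.radius == pytest.approx(70.0, abs=1.0)

        # oracle: coarse grid over the center; radius closed-form per center
        best = (np.inf, None)
        for cx in np.arange(-3, 3.01, 0.05):
            for cy in np.arange(-3, 3.01, 0.05):
                d = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy)
                r = d.mean()
                rss = np.sum((d - r) ** 2)
                if rss < best[0]:
                    best = (rss, r)
        assert circle.radius == pytest.approx(best[1], abs=0.2)


class TestArcLength:
    def test_straight_segment(self):
        curve = Polyline3([(0, 0, 0), (10, 0, 0)])
        assert polyline_arc_length(curve, 0, 10) == pytest.approx(10.0)
        assert polyline_arc_length(curve, 3, 3) == 0.0

    def test_quarter_circle_closed_form(self):
        pts = circle_arc((0, 0, 0), 50.0, (0, 0, 1), 90.0, 2000)
        curve = resample_polyline(Polyline3(pts), 0.1)
        assert curve.total_length == pytest.approx(np.pi * 50 / 2, abs=0.01)

    def test_out_of_range_raises(self):
        curve = Polyline3([(0, 0, 0), (10, 0, 0)])
        with pytest.raises(GeometryError):
            polyline_arc_length(curve, -1, 5)
        with pytest.raises(GeometryError):
            polyline_arc_length(curve, 5, 11)
        with pytest.raises(GeometryError):
            polyline_arc_length(curve, 6, 5)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_additivity(self, f0, f1, f2):
        curve = Polyline3([(0, 0, 0), (3, 4, 0), (3, 4, 12), (9, 4, 12)])
        total = curve.total_length
        s0, s1, s2 = sorted([f0 * total, f1 * total, f2 * total])
        assert polyline_arc_length(curve, s0, s2) == pytest.approx(
            polyline_arc_length(curve, s0, s1) + polyline_arc_length(curve, s1, s2),
            abs=1e-12,
        )


class TestResample:
    def test_segment_vertex_count(self):
        curve = resample_polyline(Polyline3([(0, 0, 0), (10, 0, 0)]), 1.0)
        assert len(curve.vertices) == 11
        assert np.allclose(curve.vertices[-1], [10, 0, 0])

    def test_arc_length_within_01_percent(self):
        pts = circle_arc((0, 0, 0), 44.0, (0, 1, 0), 180.0, 4000)
        curve = resample_polyline(Polyline3(pts), 0.2)
        analytic = np.pi * 44.0
        assert abs(curve.total_length - analytic) / analytic < 1e-3

    def test_chordal_convergence_order(self):
        analytic = np.pi * 50 / 2
        pts = circle_arc((0, 0, 0), 50.0, (0, 0, 1), 90.0, 20000)
        base = Polyline3(pts)
        err = {}
        for h in (1.0, 0.5):
            err[h] = analytic - resample_polyline(base, h).total_length
        assert err[1.0] / err[0.5] > 3.0  # O(h^2): exact ratio would be 4

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 2 * np.pi, 500)
        pts = np.column_stack([40 * np.cos(t), 30 * np.sin(t), 5 * np.sin(2 * t)])
        pts += 0  # smooth closed-ish curve
        once = resample_polyline(Polyline3(pts), 0.2)
        twice = resample_polyline(once, 0.2)
        assert abs(once.total_length - twice.total_length) < 1e-3
        assert np.allclose(once.vertices[0], twice.vertices[0])
        assert np.allclose(once.vertices[-1], twice.vertices[-1])

    def test_bad_spacing_raises(self):
        curve = Polyline3([(0, 0, 0), (10, 0, 0)])
        with pytest.raises(GeometryError):
            resample_polyline(curve, 0.0)
        with pytest.raises(GeometryError):
            resample_polyline(curve, 10.0)


def brute_force_crossings(plane: Plane, curve: Polyline3):
    """Independent per-segment sign-change scan."""
    d = plane.signed_distance(curve.vertices)
    out = [curve.arc_positions[i] for i in range(len(d)) if abs(d[i]) < 1e-9]
    for i in range(len(d) - 1):
        if abs(d[i]) >= 1e-9 and abs(d[i + 1]) >= 1e-9 and d[i] * d[i + 1] < 0:
            t = d[i] / (d[i] - d[i + 1])
            out.append(
                curve.arc_positions[i]
                + t * (curve.arc_positions[i + 1] - curve.arc_positions[i])
            )
    return sorted(out)


class TestPlanePolyline:
    @pytest.fixture()
    def rising_chain(self):
        # z rises linearly 0 -> 10 over 20 mm of curve (unit-speed chain)
        s = np.linspace(0, 20, 21)
        return Polyline3(np.column_stack([s * np.sqrt(3) / 2, np.zeros_like(s), s * 0.5]))

    def test_single_crossing(self, rising_chain):
        hits = plane_polyline_intersections(Plane((0, 0, 5), (0, 0, 1)), rising_chain)
        assert len(hits) == 1
        assert hits[0] == pytest.approx(10.0)

    def test_no_crossing(self, rising_chain):
        assert plane_polyline_intersections(Plane((0, 0, 99), (0, 0, 1)), rising_chain) == []

    def test_vertex_on_plane_reported_once(self):
        curve = Polyline3([(0, 0, -1), (1, 0, 0), (2, 0, -1)])  # touches z=0 at one vertex
        hits = plane_polyline_intersections(Plane((0, 0, 0), (0, 0, 1)), curve)
        assert len(hits) == 1

    @given(st.integers(0, 1000))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(0, 1.0, size=(30, 3)), axis=0)
        curve = Polyline3(pts)
        plane = Plane(rng.normal(0, 2, 3), rng.normal(size=3))
        assert plane_polyline_intersections(plane, curve) == pytest.approx(
            brute_force_crossings(plane, curve)
        )


class TestRayPolyline:
    def test_direct_hit_through_vertex(self):
        curve = Polyline3([(50, -5, 0), (50, 0, 0), (50, 5, 0)])
        s = ray_polyline_intersection((0, 0, 0), (1, 0, 0), curve, capture_radius=1.0)
        assert s == pytest.approx(5.0)

    def test_ray_pointing_away_raises(self):
        curve = Polyline3([(50, -5, 0), (50, 5, 0)])
        with pytest.raises(NoIntersectionError):
            ray_polyline_intersection((0, 0, 0), (-1, 0, 0), curve, capture_radius=1.0)

    def test_skew_approach_matches_dense_sampling_oracle(self):
        # curve offset 0.4 mm in z from the ray's plane
        s = np.linspace(-10, 10, 201)
        curve = Polyline3(np.column_stack([np.full_like(s, 30.0) + 0.05 * s**2, s,
                                           np.full_like(s, 0.4)]))
        got = ray_polyline_intersection((0, 0, 0), (1, 0, 0), curve, capture_radius=1.0)

        dense = np.linspace(0, curve.total_length, 200001)
        pts = np.array([curve.point_at(x) for x in dense[:: len(dense) // 4000 or 1]])
        # oracle: distance of sampled curve points to the ray {x >= 0 along +x}
        proj = np.clip(pts[:, 0], 0, None)
        d = np.linalg.norm(pts - np.column_stack([proj, np.zeros(len(pts)), np.zeros(len(pts))]), axis=1)
        oracle_s = dense[:: len(dense) // 4000 or 1][np.argmin(d)]
        assert got == pytest.approx(oracle_s, abs=0.05)
        assert np.min(d) <= 1.0


class TestProjectPoint:
    def test_point_on_vertex(self):
        curve = Polyline3([(0, 0, 0), (10, 0, 0), (10, 10, 0)])
        assert project_point_to_polyline((10, 0, 0), curve) == pytest.approx(10.0)

    def test_equidistant_tie_prefers_smaller_position(self):
        curve = Polyline3([(0, 0, 0), (10, 0, 0), (10, 10, 0), (0, 10, 0)])
        # (5, 5, 0) is equidistant from the first and third segments
        assert project_point_to_polyline((5, 5, 0), curve) == pytest.approx(5.0)

    def test_random_points_match_dense_oracle(self):
        rng = np.random.default_rng(11)
        pts = np.cumsum(rng.normal(0, 2.0, size=(20, 3)), axis=0)
        curve = Polyline3(pts)
        dense = np.linspace(0, curve.total_length, 200001)
        sampled = np.array([curve.point_at(x) for x in dense])
        for _ in range(10):
            p = rng.normal(0, 10, size=3)
            s = project_point_to_polyline(p, curve)
            oracle = dense[np.argmin(np.linalg.norm(sampled - p, axis=1))]
            assert s == pytest.approx(oracle, abs=1e-3)


class TestRigidMotion:
    def test_circle_fit_equivariant(self):
        rng = np.random.default_rng(5)
        pts = circle_arc((4, -3, 8), 44.0, (0.2, 0.3, 0.93), 180.0, 80)
        circle = fit_circle_3d(pts)
        R = random_rotation(rng)
        t = rng.uniform(-40, 40, 3)
        moved = fit_circle_3d(pts @ R.T + t)
        assert np.linalg.norm(moved.center - (R @ circle.center + t)) < 1e-6
        assert moved.radius == pytest.approx(circle.radius, abs=1e-9)
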