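"""Tracker geometry, sensor transforms, and skew-line closest approach."""

import numpy as np
import pytest
from scipy.optimize import minimize

from fragmon.geometry import (
    Line3,
    TrackerGeometry,
    acceptance_solid_angle,
    closest_approach,
    closest_approach_batch,
    rotate_about_axis,
)


def brute_force_closest(a: Line3, b: Line3):
    """Independent oracle: numerical minimisation of the squared distance."""
    def f(p):
        return np.sum((a.point_at(p[0]) - b.point_at(p[1])) ** 2)

    best = None
    for t0 in (-100.0, 0.0, 100.0):
        r = minimize(f, [t0, -t0], method="Nelder-Mead",
                     options=dict(xatol=1e-12, fatol=1e-24, maxiter=5000))
        if best is None or r.fun < best.fun:
            best = r
    return best.x, np.sqrt(max(best.fun, 0.0))


class TestClosestApproach:
    def test_coplanar_lines_intersect_at_midpoint(self):
        a = Line3([0, 0, 0], [0, 0, 1])
        b = Line3([10, 0, 50], [0.5, 0, 0.86603])
        r = closest_approach(a, b)
        assert not r.degenerate
        assert r.distance == pytest.approx(0.0, abs=1e-9)
        assert r.midpoint == pytest.approx([0.0, 0.0, 32.6794], abs=1e-3)

    def test_skew_lines_unit_distance(self):
        r = closest_approach(Line3([0, 0, 0], [0, 0, 1]), Line3([1, 0, 0], [0, 1, 0]))
        assert r.point_on_a == pytest.approx([0, 0, 0])
        assert r.point_on_b == pytest.approx([1, 0, 0])
        assert r.midpoint == pytest.approx([0.5, 0, 0])
        assert r.distance == pytest.approx(1.0)

    def test_identical_lines_return_shared_origin(self):
        line = Line3([1, 2, 3], [0, 0, 1.0])
        r = closest_approach(line, line)
        assert r.degenerate
        assert r.distance == 0.0
        assert r.point_on_a == pytest.approx([1, 2, 3])

    def test_parallel_lines_flagged_with_separation(self):
        r = closest_approach(Line3([0, 0, 0], [0, 0, 1]), Line3([1, 0, 0], [0, 0, 1]))
        assert r.degenerate
        assert r.midpoint is None
        assert r.distance == pytest.approx(1.0)

    def test_symmetric_under_swap(self, rng):
        for _ in range(20):
            a = Line3(rng.normal(size=3) * 50, rng.normal(size=3))
            b = Line3(rng.normal(size=3) * 50, rng.normal(size=3))
            r1 = closest_approach(a, b)
            r2 = closest_approach(b, a)
            assert r1.distance == pytest.approx(r2.distance, abs=1e-9)
            if not r1.degenerate:
                assert r1.midpoint == pytest.approx(r2.midpoint, abs=1e-9)

    def test_matches_brute_force_on_random_pairs(self, rng):
        n_checked = 0
        for _ in range(200):
            a = Line3(rng.normal(size=3) * 50, rng.normal(size=3))
            b = Line3(rng.normal(size=3) * 50, rng.normal(size=3))
            r = closest_approach(a, b)
            if r.degenerate:
                continue
            _, d_oracle = brute_force_closest(a, b)
            assert r.distance == pytest.approx(d_oracle, abs=1e-4)
            n_checked += 1
        assert n_checked > 150

    def test_batch_agrees_with_scalar(self, rng):
        oa = rng.normal(size=(50, 3)) * 30
        da = rng.normal(size=(50, 3))
        da /= np.linalg.norm(da, axis=1, keepdims=True)
        ob = rng.normal(size=(50, 3)) * 30
        db = rng.normal(size=(50, 3))
        db /= np.linalg.norm(db, axis=1, keepdims=True)
        mid, dist, deg = closest_approach_batch(oa, da, ob, db)
        for i in range(50):
            r = closest_approach(Line3(oa[i], da[i]), Line3(ob[i], db[i]))
            assert deg[i] == r.degenerate
            assert dist[i] == pytest.approx(r.distance, abs=1e-9)
            if not r.degenerate:
                assert mid[i] == pytest.approx(r.midpoint, abs=1e-9)

    def test_connection_orthogonal_to_both_lines(self, rng):
        for _ in range(50):
            a = Line3(rng.normal(size=3) * 50, rng.normal(size=3))
            b = Line3(rng.normal(size=3) * 50, rng.normal(size=3))
            r = closest_approach(a, b)
            if r.degenerate or r.distance < 1e-9:
                continue
            seg = (r.point_on_a - r.point_on_b) / r.distance
            assert abs(np.dot(seg, a.direction)) < 1e-6
            assert abs(np.dot(seg, b.direction)) < 1e-6


class TestSensorTransforms:
    def test_front_layer_center_at_nominal_distance(self):
        g = TrackerGeometry(tilt_deg=0.0)
        nc, nr = g.pixels_per_layer
        p = g.sensor_to_room((nc - 1) / 2, (nr - 1) / 2, "front")
        assert np.linalg.norm(p) == pytest.approx(167.0, abs=1e-9)
        assert np.dot(p / np.linalg.norm(p), g.focus_direction) == pytest.approx(1.0)

    def test_adjacent_columns_one_pitch_apart(self, geom):
        p1 = geom.sensor_to_room(100, 50, "front")
        p2 = geom.sensor_to_room(101, 50, "front")
        assert np.linalg.norm(p2 - p1) == pytest.approx(0.055, abs=1e-12)

    def test_tilt_rotation_is_invertible(self):
        g0 = TrackerGeometry(tilt_deg=0.0)
        g1 = TrackerGeometry(tilt_deg=1.6)
        p0 = g0.sensor_to_room(0, 0, "front")
        p1 = g1.sensor_to_room(0, 0, "front")
        assert not np.allclose(p0, p1)
        back = rotate_about_axis(
            p1 - g1.layer_center("front"), g1.focus_direction, -np.radians(1.6)
        ) + g1.layer_center("front")
        assert back == pytest.approx(p0, abs=1e-9)

    def test_roundtrip_identity_on_random_points(self, geom, rng):
        nc, nr = geom.pixels_per_layer
        cols = rng.uniform(-0.5, nc - 0.5, 1000)
        rows = rng.uniform(-0.5, nr - 0.5, 1000)
        for layer in ("front", "back"):
            pts = geom.sensor_to_room(cols, rows, layer)
            c2, r2 = geom.room_to_sensor(pts, layer)
            np.testing.assert_allclose(c2, cols, atol=1e-9 / 0.055)
            np.testing.assert_allclose(r2, rows, atol=1e-9 / 0.055)

    def test_out_of_range_pixel_rejected(self, geom):
        with pytest.raises(ValueError):
            geom.sensor_to_room(600, 10, "front")
        with pytest.raises(ValueError):
            geom.sensor_to_room(10, -3, "back")

    def test_layer_separation_along_focus_line(self, geom):
        d = geom.layer_center("back") - geom.layer_center("front")
        assert np.linalg.norm(d) == pytest.approx(20.3)
        assert np.dot(d / np.linalg.norm(d), geom.focus_direction) == pytest.approx(1.0)

    def test_focus_line_at_thirty_degrees_to_beam(self, geom):
        cos = geom.focus_direction @ np.array([0.0, 0.0, 1.0])
        assert np.degrees(np.arccos(cos)) == pytest.approx(30.0)


class TestSolidAngle:
    def test_single_front_layer_matches_small_angle_estimate(self, geom):
        est = acceptance_solid_angle(geom, n_samples=200_000, seed=3, layers="front")
        # analytic small-angle value: area / distance^2 = 392 / 167^2
        assert est.omega_sr == pytest.approx(28 * 14 / 167.0**2, rel=0.03)
        assert est.std_error_sr < 1e-4

    def test_inverse_square_scaling(self, geom):
        far = TrackerGeometry(front_layer_distance=334.0)
        e1 = acceptance_solid_angle(geom, n_samples=100_000, seed=4, layers="front")
        e2 = acceptance_solid_angle(far, n_samples=100_000, seed=4, layers="front")
        assert e2.omega_sr == pytest.approx(e1.omega_sr / 4.0, rel=0.05)

    def test_coincidence_acceptance_not_larger_than_single_layer(self, geom):
        both = acceptance_solid_angle(geom, n_samples=100_000, seed=5, layers="both")
        front = acceptance_solid_angle(geom, n_samples=100_000, seed=5, layers="front")
        assert both.omega_sr <= front.omega_sr + 3 * front.std_error_sr

    def test_origin_on_layer_plane_rejected(self, geom):
        with pytest.raises(ValueError):
            acceptance_solid_angle(geom, origin=geom.layer_center("front"), n_samples=10)
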