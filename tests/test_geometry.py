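"""Per-fiber geometry: rotations, filters, resampling, statistics."""

import math

import numpy as np
import pytest

import walltomo as wt
from walltomo.geometry import (
    mean_menger_radius,
    mean_slope,
    menger_radius,
    orientation_tensor,
    out_of_plane_angle_deg,
    polyline_length,
)


def trace(*pts, tid=0):
    return wt.FiberTrace(tid, np.asarray(pts, dtype=float))


def arc_points(radius, arc_len, spacing=1.0):
    n = int(round(arc_len / spacing))
    th = np.linspace(0.0, arc_len / radius, n + 1)
    return np.column_stack(
        [radius * np.cos(th), radius * np.sin(th), np.zeros_like(th)]
    )


class TestMillingRotation:
    def test_zero_angle_is_identity(self, random_traceset):
        out = wt.apply_milling_rotation(random_traceset, 0.0)
        for a, b in zip(random_traceset, out):
            np.testing.assert_allclose(a.points, b.points)

    def test_axis_aligned_90_degrees(self):
        ts = wt.TraceSet([trace((1, 5, 0), (2, 5, 0))])
        out = wt.apply_milling_rotation(ts, 90.0)
        np.testing.assert_allclose(out.traces[0].points[0], [0, 5, -1], atol=1e-12)

    def test_rotation_preserves_pairwise_distances(self, random_traceset):
        cloud = np.concatenate([t.points for t in random_traceset])
        out = wt.apply_milling_rotation(random_traceset, 33.7)
        cloud2 = np.concatenate([t.points for t in out])
        d1 = np.linalg.norm(cloud[:, None] - cloud[None, :], axis=-1)
        d2 = np.linalg.norm(cloud2[:, None] - cloud2[None, :], axis=-1)
        np.testing.assert_allclose(d1, d2, rtol=1e-9, atol=1e-9)

    def test_rotation_preserves_length_and_curvature(self, random_traceset):
        out = wt.apply_milling_rotation(random_traceset, 17.0)
        for a, b in zip(random_traceset, out):
            assert polyline_length(a.points) == pytest.approx(
                polyline_length(b.points), rel=1e-6
            )
            ra, rb = mean_menger_radius(a.points), mean_menger_radius(b.points)
            if math.isfinite(ra):
                assert ra == pytest.approx(rb, rel=1e-6)


class TestOutOfPlaneFilter:
    def test_vertical_fiber_removed(self):
        ts = wt.TraceSet([trace((0, 0, 0), (0, 0, 100))])
        kept, report = wt.filter_out_of_plane(ts)
        assert len(kept) == 0
        assert report.removed[0] == (0, pytest.approx(90.0))

    def test_horizontal_fiber_kept(self):
        ts = wt.TraceSet([trace((0, 0, 0), (100, 0, 0))])
        kept, report = wt.filter_out_of_plane(ts)
        assert len(kept) == 1 and report.n_removed == 0

    def test_matches_bruteforce_chord_criterion(self):
        rng = np.random.default_rng(11)
        traces = []
        for i in range(1000):
            p0 = rng.uniform(0, 100, 3)
            p1 = p0 + rng.normal(0, 20, 3)
            while np.linalg.norm(p1 - p0) == 0:
                p1 = p0 + rng.normal(0, 20, 3)
            traces.append(wt.FiberTrace(i, np.stack([p0, p1])))
        ts = wt.TraceSet(traces)
        kept, _ = wt.filter_out_of_plane(ts, 70.0)
        kept_ids = {t.trace_id for t in kept}
        expect = set()
        for t in traces:
            chord = t.points[-1] - t.points[0]
            ang = math.degrees(math.asin(abs(chord[2]) / np.linalg.norm(chord)))
            if ang <= 70.0:
                expect.add(t.trace_id)
        assert kept_ids == expect


class TestVerticalArtifactTrim:
    def test_exactly_vertical_removed_horizontal_kept(self):
        ts = wt.TraceSet(
            [trace((0, 0, 0), (0, 0, 50), tid=0), trace((0, 0, 0), (50, 0, 0), tid=1)]
        )
        kept, report = wt.trim_vertical_artifacts(ts)
        assert [t.trace_id for t in kept] == [1]
        assert report.removed[0][0] == 0

    def test_matches_bruteforce_tensor(self):
        rng = np.random.default_rng(3)
        traces = []
        for i in range(200):
            n = int(rng.integers(3, 8))
            pts = np.cumsum(rng.normal(0, 5, (n, 3)), axis=0)
            traces.append(wt.FiberTrace(i, pts))
        ts = wt.TraceSet(traces)
        kept, _ = wt.trim_vertical_artifacts(ts, zz_max=0.5, xz_abs_max=0.3)
        kept_ids = {t.trace_id for t in kept}
        expect = set()
        for t in traces:
            seg = np.diff(t.points, axis=0)
            tang = seg / np.linalg.norm(seg, axis=1, keepdims=True)
            m = tang.T @ tang / len(tang)
            if m[2, 2] <= 0.5 and abs(m[0, 2]) <= 0.3:
                expect.add(t.trace_id)
        assert kept_ids == expect


class TestCanonicalize:
    def test_ascending_y_unchanged_descending_reversed(self):
        up = trace((0, 0, 0), (1, 5, 0))
        down = trace((1, 5, 0), (0, 0, 0))
        np.testing.assert_array_equal(wt.canonicalize_direction(up).points, up.points)
        np.testing.assert_array_equal(
            wt.canonicalize_direction(down).points, up.points
        )

    def test_y_tie_broken_by_x_then_z_and_idempotent(self):
        t = trace((5, 2, 0), (0, 2, 3))  # same y: lower x must come first
        c = wt.canonicalize_direction(t)
        assert c.points[0][0] < c.points[-1][0]
        rng = np.random.default_rng(9)
        for i in range(50):
            pts = np.cumsum(rng.normal(0, 3, (5, 3)), axis=0)
            tr = wt.FiberTrace(i, pts)
            once = wt.canonicalize_direction(tr)
            twice = wt.canonicalize_direction(once)
            np.testing.assert_array_equal(once.points, twice.points)


class TestResample:
    def test_straight_segment_spacing(self):
        t = trace((0, 0, 0), (10, 0, 0))
        r = wt.resample_cubic_spline(t, 1.0)
        assert r.n_points == 11
        np.testing.assert_allclose(
            np.linalg.norm(np.diff(r.points, axis=0), axis=1), 1.0, rtol=1e-6
        )
        np.testing.assert_array_equal(r.points[0], t.points[0])
        np.testing.assert_array_equal(r.points[-1], t.points[-1])

    def test_quarter_circle_arc_length(self):
        pts = arc_points(100.0, 100.0 * math.pi / 2.0, spacing=10.0)
        r = wt.resample_cubic_spline(wt.FiberTrace(0, pts), 1.0)
        L = polyline_length(r.points)
        assert L == pytest.approx(100.0 * math.pi / 2.0, rel=0.005)

    def test_idempotent_within_tolerance(self):
        pts = arc_points(200.0, 150.0, spacing=7.0)
        r1 = wt.resample_cubic_spline(wt.FiberTrace(0, pts), 1.0)
        r2 = wt.resample_cubic_spline(r1, 1.0)
        n = min(r1.n_points, r2.n_points)
        rms = np.sqrt(np.mean(np.sum((r1.points[:n] - r2.points[:n]) ** 2, axis=1)))
        assert rms < 0.05

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            wt.resample_cubic_spline(trace((0, 0, 0), (0.5, 0, 0)), 1.0)


class TestFiberMetrics:
    def test_length_345(self):
        m = wt.compute_fiber_metrics(trace((0, 0, 0), (3, 4, 0)))
        assert m.length_nm == pytest.approx(5.0)

    def test_menger_radius_unit_circumcircle(self):
        r = menger_radius(
            np.array([0.0, 0, 0]), np.array([1.0, 1, 0]), np.array([2.0, 0, 0])
        )
        assert r == pytest.approx(1.0)

    def test_slope_and_mean_z(self):
        m = wt.compute_fiber_metrics(trace((0, 0, 0), (3, 4, 1)))
        assert m.mean_slope == pytest.approx(0.2)
        assert m.mean_z_nm == pytest.approx(0.5)

    @pytest.mark.parametrize("radius", [50.0, 100.0, 225.0, 500.0])
    def test_menger_on_analytic_arcs(self, radius):
        pts = arc_points(radius, min(3 * radius, 500.0), spacing=1.0)
        est = mean_menger_radius(pts)
        assert abs(est - radius) / radius < 0.01

    def test_collinear_fiber_flagged_infinite(self):
        m = wt.compute_fiber_metrics(trace((0, 0, 0), (1, 0, 0), (2, 0, 0)))
        assert math.isinf(m.mean_menger_radius_nm)

    def test_two_points_curvature_unavailable(self):
        m = wt.compute_fiber_metrics(trace((0, 0, 0), (1, 1, 1)))
        assert math.isnan(m.mean_menger_radius_nm)
        assert m.length_nm > 0

    def test_z_symmetric_trace_has_zero_mean_slope(self):
        pts = np.array([[0, 0, 0], [1, 1, 2], [2, 2, 0]], dtype=float)
        assert mean_slope(pts) == pytest.approx(0.0)


class TestAngleToAxis:
    def test_diagonal_and_mirror(self):
        c = (0.0, 1.0)
        assert wt.angle_to_axis(trace((0, 0, 0), (10, 10, 0)), c) == pytest.approx(45.0)
        assert wt.angle_to_axis(trace((0, 0, 0), (-10, 10, 0)), c) == pytest.approx(135.0)

    def test_parallel_gives_zero(self):
        assert wt.angle_to_axis(trace((0, 0, 0), (0, 10, 0)), (0, 1)) == pytest.approx(0.0)

    def test_matches_signed_angle_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(1000):
            beta = rng.uniform(0, 2 * math.pi)
            c = (math.cos(beta), math.sin(beta))
            f = rng.normal(0, 1, 3)
            while math.hypot(f[0], f[1]) < 1e-6:
                f = rng.normal(0, 1, 3)
            t = wt.FiberTrace(0, np.stack([np.zeros(3), f]))
            got = wt.angle_to_axis(t, c)
            cross = c[0] * f[1] - c[1] * f[0]
            dot = c[0] * f[0] + c[1] * f[1]
            expect = (-math.degrees(math.atan2(cross, dot))) % 180.0
            assert got == pytest.approx(expect, abs=1e-9)

    def test_invariant_under_point_order_after_canonicalization(self):
        rng = np.random.default_rng(4)
        for i in range(100):
            pts = np.cumsum(rng.normal(0, 3, (4, 3)), axis=0)
            t = wt.FiberTrace(i, pts)
            a1 = wt.angle_to_axis(wt.canonicalize_direction(t), (0, 1))
            a2 = wt.angle_to_axis(wt.canonicalize_direction(t.reversed()), (0, 1))
            assert a1 == pytest.approx(a2)

    def test_equivariant_under_global_rotation(self):
        rng = np.random.default_rng(5)
        beta = 25.0
        rot = np.array(
            [
                [math.cos(math.radians(beta)), -math.sin(math.radians(beta))],
                [math.sin(math.radians(beta)), math.cos(math.radians(beta))],
            ]
        )
        c = np.array([0.3, 0.8])
        c /= np.linalg.norm(c)
        for i in range(100):
            pts = np.cumsum(rng.normal(0, 3, (3, 3)), axis=0)
            t = wt.canonicalize_direction(wt.FiberTrace(i, pts))
            pts2 = pts.copy()
            pts2[:, :2] = pts[:, :2] @ rot.T
            t2 = wt.canonicalize_direction(wt.FiberTrace(i, pts2))
            a1 = wt.angle_to_axis(t, tuple(c))
            a2 = wt.angle_to_axis(t2, tuple(rot @ c))
            assert a1 == pytest.approx(a2, abs=1e-6)


class TestDepth:
    def test_zero_angle(self):
        assert wt.tomogram_depth(1.0, 0.0) == 0.0

    def test_45_degrees(self):
        assert wt.tomogram_depth(1.0, 45.0) == pytest.approx(1.0)

    def test_trig_evaluation(self):
        assert wt.tomogram_depth(1.36, 17.0) == pytest.approx(
            1.36 * math.tan(math.radians(17.0))
        )

    def test_sin_mode_and_bad_angle(self):
        assert wt.tomogram_depth(2.0, 30.0, mode="sin") == pytest.approx(1.0)
        with pytest.raises(ValueError):
            wt.tomogram_depth(1.0, 90.0)


def test_out_of_plane_zero_chord_flagged():
    # closed contour: chord length 0 treated as maximally out-of-plane
    t = wt.FiberTrace(0, np.array([[0, 0, 0], [1, 0, 0], [0, 0, 0.0]], dtype=float))
    assert out_of_plane_angle_deg(t) == 90.0


def test_orientation_tensor_is_unit_trace(random_traceset):
    for t in random_traceset:
        m = orientation_tensor(t)
        assert np.trace(m) == pytest.approx(1.0)


def test_process_traceset_runs_end_to_end(random_traceset):
    metrics, ts, reports = wt.process_traceset(random_traceset)
    assert len(metrics) == len(ts)
    assert {r.stage for r in reports} == {"out_of_plane", "vertical_artifact"}
    assert len(metrics) + sum(r.n_removed for r in reports) == len(random_traceset)
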