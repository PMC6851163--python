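"""Midline resampling, landmarks, angles, amplitudes and velocities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fincrawl.axial_kinematics import (
    LandmarkSet,
    Midline,
    amplitudes,
    analyze_recording,
    estimate_travel_direction,
    extract_landmarks,
    interpolate_midline,
    segment_angles,
    velocities,
)


def straight_midline(length=50.0, n=20):
    x = np.linspace(0.0, length, n)
    return np.column_stack([x, np.zeros(n)])


def arc_midline(radius=40.0, sweep=1.2, n=20):
    t = np.linspace(0.0, sweep, n)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t)])


class TestInterpolation:
    def test_straight_line_exact_spacing(self):
        """20 collinear points over 50 mm resample to 0.5 mm spacing."""
        res = interpolate_midline(Midline(straight_midline()))
        assert res.points.shape == (101, 2)
        gaps = np.linalg.norm(np.diff(res.points, axis=0), axis=1)
        assert np.allclose(gaps, 0.5, rtol=1e-9)
        assert res.arc_length == pytest.approx(50.0, rel=1e-9)

    def test_output_always_101_points(self, rng):
        pts = straight_midline() + 0.3 * rng.standard_normal((20, 2))
        pts = pts[np.argsort(pts[:, 0])]
        res = interpolate_midline(Midline(pts))
        assert res.points.shape == (101, 2)

    def test_circular_arc_matches_dense_polyline_oracle(self):
        """Equal-arc resampling agrees with a 1e5-subdivision polyline oracle."""
        pts = arc_midline()
        res = interpolate_midline(Midline(pts))

        # oracle: resample a very dense spline polyline by cumulative length
        from scipy.interpolate import CubicSpline

        chord = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
        )
        spline = CubicSpline(chord, pts, axis=0, bc_type="natural")
        dense = spline(np.linspace(0, chord[-1], 100001))
        seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        targets = np.linspace(0.0, arc[-1], 101)
        idx = np.searchsorted(arc, targets)
        oracle = dense[np.clip(idx, 0, len(dense) - 1)]
        assert np.allclose(res.points, oracle, atol=2e-3)

        gaps = np.linalg.norm(np.diff(res.points, axis=0), axis=1)
        assert gaps.std() / gaps.mean() < 1e-4  # chords of equal arcs

    def test_arc_length_gaps_equal_within_tolerance(self):
        """Successive arc-length gaps agree to 1e-6 relative."""
        from scipy.interpolate import CubicSpline

        pts = arc_midline()
        res = interpolate_midline(Midline(pts))
        chord = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
        )
        spline = CubicSpline(chord, pts, axis=0, bc_type="natural")
        # measure arc between successive resampled points on a fine grid
        dense_u = np.linspace(0, chord[-1], 200001)
        dense = spline(dense_u)
        arc = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))]
        )
        # locate each resampled point on the dense curve by nearest vertex
        pos = np.empty(101)
        for i, p in enumerate(res.points):
            pos[i] = arc[np.argmin(((dense - p) ** 2).sum(axis=1))]
        gaps = np.diff(pos)
        assert np.abs(gaps - gaps.mean()).max() / gaps.mean() < 1e-3

    def test_duplicate_and_nonfinite_points_rejected(self):
        pts = straight_midline()
        bad = pts.copy()
        bad[5] = bad[4]
        with pytest.raises(ValueError):
            Midline(bad)
        bad2 = pts.copy()
        bad2[3, 0] = np.nan
        with pytest.raises(ValueError):
            Midline(bad2)


class TestLandmarks:
    def test_eleven_points_ten_segments(self):
        res = interpolate_midline(Midline(arc_midline()))
        lm = extract_landmarks(res)
        assert lm.points.shape == (11, 2)
        assert lm.segments.shape == (10, 2, 2)
        assert np.array_equal(lm.points, res.points[::10])

    def test_straight_body_segments_each_ten_percent(self):
        res = interpolate_midline(Midline(straight_midline(100.0)))
        lm = extract_landmarks(res)
        seglen = np.linalg.norm(np.diff(lm.points, axis=0), axis=1)
        assert np.allclose(seglen, 10.0, rtol=1e-9)


class TestTravelDirection:
    @pytest.mark.parametrize(
        "step,expected",
        [((1.0, 0.0), (1.0, 0.0)), ((0.0, -1.0), (0.0, -1.0))],
    )
    def test_straight_paths(self, step, expected):
        pts = np.cumsum(np.tile(step, (50, 1)), axis=0)
        assert np.allclose(estimate_travel_direction(pts), expected, atol=1e-12)

    def test_sinuous_path_matches_principal_axis_oracle(self, rng):
        """Mean direction of a noisy sinuous path recovered within 1 degree."""
        theta = 0.4
        t = np.linspace(0.0, 60.0, 400)
        lateral = 2.0 * np.sin(2 * np.pi * t / 10.0)
        d = np.array([np.cos(theta), np.sin(theta)])
        n = np.array([-np.sin(theta), np.cos(theta)])
        pts = t[:, None] * d + lateral[:, None] * n
        got = estimate_travel_direction(pts)
        ang = np.degrees(np.arctan2(got[1], got[0]))
        assert ang == pytest.approx(np.degrees(theta), abs=1.0)
        # oracle: largest-eigenvalue direction of the covariance
        c = pts - pts.mean(0)
        w, v = np.linalg.eigh(c.T @ c)
        oracle = v[:, -1] * np.sign(v[:, -1] @ d)
        assert np.allclose(got, oracle, atol=1e-9)

    def test_stationary_rejected_and_small_net_falls_back(self):
        with pytest.raises(ValueError, match="stationary"):
            estimate_travel_direction(np.zeros((10, 2)))
        wob = 0.01 * np.column_stack([np.sin(np.linspace(0, 6, 30)), np.zeros(30)])
        got = estimate_travel_direction(wob + 5.0, head_axis=(0.0, 2.0))
        assert np.allclose(got, (0.0, 1.0))


class TestSegmentAngles:
    def test_parallel_and_perpendicular(self):
        lm = extract_landmarks(interpolate_midline(Midline(straight_midline())))
        assert np.allclose(segment_angles(lm, (1.0, 0.0)), 0.0, atol=1e-9)
        assert np.allclose(segment_angles(lm, (0.0, 1.0)), 90.0, atol=1e-9)

    def test_handbuilt_zigzag_exact_arctangents(self):
        """Zigzag landmark chain reproduces hand-computed angles to 1e-9."""
        slopes = [0.0, 1.0, -2.0, 0.5, 3.0, -1.0, 0.25, -0.75, 2.0, -0.5]
        pts = [np.zeros(2)]
        for s in slopes:
            pts.append(pts[-1] + np.array([1.0, s]))
        lm = LandmarkSet(np.array(pts))
        got = segment_angles(lm, (1.0, 0.0))
        expected = np.degrees(np.arctan(np.abs(slopes)))
        assert np.allclose(got, expected, atol=1e-9)

    def test_angles_folded_to_acute(self):
        pts = np.column_stack([np.linspace(0, -10, 11), np.zeros(11)])  # anti-parallel
        lm = LandmarkSet(pts)
        assert np.allclose(segment_angles(lm, (1.0, 0.0)), 0.0, atol=1e-9)


class TestAmplitudes:
    def test_points_on_axis_zero(self):
        lm = extract_landmarks(interpolate_midline(Midline(straight_midline())))
        amp = amplitudes(lm, np.zeros(2), (1.0, 0.0))
        assert np.allclose(amp, 0.0, atol=1e-9)

    def test_perpendicular_offset_recovered(self):
        pts = straight_midline()
        pts[:, 1] += 3.0
        lm = extract_landmarks(interpolate_midline(Midline(pts)))
        amp = amplitudes(lm, np.zeros(2), (1.0, 0.0))
        assert np.allclose(amp, 3.0, atol=1e-9)

    def test_simulated_forward_cycle_envelope_grows_tailward(self, forward_profile):
        """Max amplitude increases along the body; tail/head ratio > 7."""
        env = np.abs(forward_profile.amplitudes_mm).max(axis=0)
        assert env[10] / env[0] > 7.0
        assert env[10] > env[8] > env[6]  # posterior growth


class TestVelocities:
    def test_stationary_landmarks_zero_velocity(self):
        series = np.tile(straight_midline()[None, ::2][:, :11], (31, 1, 1))
        v = velocities(series, 0.01, (1.0, 0.0), 50.0)
        assert np.allclose(v["axial_mm_s"], 0.0, atol=1e-9)
        assert np.allclose(v["lateral_mm_s"], 0.0, atol=1e-9)

    def test_rigid_translation_pure_axial(self):
        base = straight_midline()[::2][:11]
        times = np.arange(41) * 0.01
        series = base[None] + times[:, None, None] * np.array([12.0, 0.0])
        v = velocities(series, 0.01, (1.0, 0.0), 50.0)
        inner = slice(6, -6)  # away from gradient edge effects
        assert np.allclose(v["axial_mm_s"][inner], 12.0, atol=1e-6)
        assert np.allclose(v["lateral_mm_s"][inner], 0.0, atol=1e-6)

    def test_sinusoid_peak_matches_analytic_derivative(self):
        """Peak lateral speed of A sin(2 pi f t) is 2 pi f A (to SG attenuation)."""
        f, A, dt = 5.0, 2.0, 1.0 / 500.0
        t = np.arange(0, 1.0, dt)
        base = straight_midline()[::2][:11]
        series = np.tile(base, (t.size, 1, 1))
        series[:, :, 1] += A * np.sin(2 * np.pi * f * t)[:, None]
        v = velocities(series, dt, (1.0, 0.0), 50.0)
        peak = np.abs(v["lateral_mm_s"]).max()
        assert peak == pytest.approx(2 * np.pi * f * A, rel=5e-3)

    def test_resultant_is_hypotenuse(self, forward_profile):
        p = forward_profile
        assert np.allclose(
            p.v_resultant_mm_s,
            np.hypot(p.v_axial_mm_s, p.v_lateral_mm_s),
            atol=1e-9,
        )

    def test_nonuniform_dt_rejected(self, forward_recording):
        rec = forward_recording
        import copy

        bad = copy.copy(rec)
        bad.frames = [copy.copy(f) for f in rec.frames[:20]]
        bad.frames[10].time += 0.05
        with pytest.raises(ValueError, match="1%"):
            analyze_recording(bad)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(phi=st.floats(-np.pi, np.pi))
def test_rotation_equivariance(phi):
    """Rotating the world rotates travel but leaves angles/amplitudes alone."""
    pts = arc_midline()
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    lm = extract_landmarks(interpolate_midline(Midline(pts)))
    lm_rot = extract_landmarks(interpolate_midline(Midline(pts @ rot.T)))
    travel = np.array([1.0, 0.0])
    a = segment_angles(lm, travel)
    b = segment_angles(lm_rot, rot @ travel)
    assert np.allclose(a, b, atol=1e-6)
    amp_a = amplitudes(lm, pts[0], travel)
    amp_b = amplitudes(lm_rot, rot @ pts[0], rot @ travel)
    assert np.allclose(amp_a, amp_b, atol=1e-6)


def test_pipeline_consistent_with_generator(forward_recording, forward_profile):
    """Pipeline-measured peak lateral velocity at the 80%-BL landmark matches
    a direct finite-difference on the generator's own midline samples within 2%."""
    times = forward_recording.times
    mids = forward_recording.midlines()
    # the 80%-BL landmark (array index 8); generator midline points are
    # equally spaced in arc length, so 0.8 L falls between points 15 & 16
    y9 = 0.8 * mids[:, 15, 1] + 0.2 * mids[:, 16, 1]
    truth = np.abs(np.gradient(y9, times)).max()
    measured = np.abs(forward_profile.v_lateral_mm_s[:, 8]).max()
    assert measured == pytest.approx(truth, rel=0.02)
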