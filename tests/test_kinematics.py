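"""Filtering, midline resampling, and angle/angular-velocity extraction."""

import numpy as np
import pytest
from scipy import signal

import turnkin as tk
from turnkin.errors import (
    DegenerateGeometryError,
    InvalidArgumentError,
    ShortSeriesError,
)
from turnkin.kinematics import AngleSeries

from conftest import straight_track


def _sine_track(freq, frame_rate=60.0, n=240, amp=1.0):
    times = np.arange(n) / frame_rate
    x = amp * np.sin(2 * np.pi * freq * times)
    landmarks = np.zeros((n, 7, 2))
    landmarks[:, :, 0] = x[:, None] + np.arange(7)[::-1][None, :]
    return tk.MidlineTrack(times=times, landmarks=landmarks, frame_rate=frame_rate)


class TestSmoothPositions:
    def test_constant_track_passes_unchanged(self):
        track = straight_track()
        out = tk.smooth_positions(track, cutoff=8.0)
        assert np.allclose(out.landmarks, track.landmarks, atol=1e-9)

    @pytest.mark.parametrize(
        "freq, cutoff, keep",
        [(1.0, 8.0, True), (25.0, 4.0, False)],
    )
    def test_frequency_response(self, freq, cutoff, keep):
        """Passband sinusoids keep their amplitude; stopband ones vanish.

        The oracle is the designed filter's own frequency response (applied
        twice for the forward-backward pass).
        """
        track = _sine_track(freq)
        out = tk.smooth_positions(track, cutoff=cutoff)
        mid = slice(60, 180)  # avoid edge transients
        gain = np.ptp(out.landmarks[mid, 0, 0]) / np.ptp(track.landmarks[mid, 0, 0])
        sos = signal.butter(9, cutoff, btype="low", fs=60.0, output="sos")
        _, h = signal.sosfreqz(sos, worN=[freq], fs=60.0)
        expected = np.abs(h[0]) ** 2  # zero-phase = squared magnitude
        if keep:
            assert gain == pytest.approx(1.0, abs=0.01)
            assert expected > 0.99
        else:
            assert gain < 0.01
            assert expected < 0.01

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(InvalidArgumentError):
            tk.smooth_positions(straight_track(), cutoff=30.0)

    def test_short_series_rejected(self):
        with pytest.raises(ShortSeriesError):
            tk.smooth_positions(straight_track(n_frames=20), cutoff=8.0, order=9)


class TestResampleMidline:
    def test_collinear_landmarks_resample_to_uniform_spacing(self):
        track = straight_track(n_frames=3, spacing=1.0)
        out = tk.resample_midline(track, n_points=13)
        d = np.diff(out.landmarks[0], axis=0)
        assert np.allclose(np.linalg.norm(d, axis=1), 0.5, atol=1e-9)
        assert np.allclose(out.landmarks[0][:, 1], 0.0, atol=1e-12)

    def test_circular_arc_recovered(self):
        """Resampled points stay within 1e-3 L of the true arc."""
        R, L = 12.0, 15.0
        s = np.linspace(0.0, L, 7)
        phi = s / R
        pts = np.stack([R * np.sin(phi), R * (1 - np.cos(phi))], axis=1)
        track = tk.MidlineTrack(
            times=np.array([0.0]), landmarks=pts[None], frame_rate=60.0
        )
        out = tk.resample_midline(track, n_points=25)
        r = np.linalg.norm(out.landmarks[0] - np.array([0.0, R]), axis=1)
        assert np.max(np.abs(r - R)) < 1e-3 * L

    def test_near_identity_on_straight_body(self):
        track = straight_track(n_frames=2)
        out = tk.resample_midline(track, n_points=7)
        assert np.allclose(out.landmarks, track.landmarks, atol=1e-6)

    def test_spacing_uniform_to_half_percent_on_bent_body(self, fast_noiseless):
        _, track, _ = fast_noiseless
        out = tk.resample_midline(track, n_points=20)
        seg = np.linalg.norm(np.diff(out.landmarks, axis=1), axis=2)
        rel_spread = np.ptp(seg, axis=1) / seg.mean(axis=1)
        assert rel_spread.max() < 5e-3

    def test_degenerate_midline_rejected(self):
        pts = np.zeros((1, 7, 2))
        track = tk.MidlineTrack(times=np.array([0.0]), landmarks=pts, frame_rate=60.0)
        with pytest.raises(DegenerateGeometryError):
            tk.resample_midline(track, n_points=10)


class TestSegmentAngle:
    @pytest.mark.parametrize(
        "front, back, expected",
        [((1, 0), (0, 0), 0.0), ((0, 1), (0, 0), 90.0), ((-1, -1), (0, 0), -135.0)],
    )
    def test_quadrants(self, front, back, expected):
        assert tk.segment_angle(front, back) == pytest.approx(expected)

    def test_angle_range_excludes_minus_180(self):
        assert tk.segment_angle((-1, 0), (0, 0)) == 180.0

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            tk.segment_angle((1, 1), (1, 1))


class TestAngularVelocity:
    def _series(self, theta, frame_rate=60.0):
        times = np.arange(theta.size) / frame_rate
        return AngleSeries(times=times, angle=theta, frame_rate=frame_rate)

    def test_linear_ramp_recovered_exactly(self):
        t = np.arange(120) / 60.0
        out = tk.angular_velocity(self._series(100.0 * t), smooth_cutoff=None)
        assert np.allclose(out.omega[1:-1], 100.0, atol=1e-9)

    def test_constant_angle_gives_zero(self):
        out = tk.angular_velocity(self._series(np.full(60, 33.0)), smooth_cutoff=None)
        assert np.allclose(out.omega, 0.0, atol=1e-9)

    def test_central_difference_exact_on_quadratic(self):
        t = np.arange(90) / 60.0
        theta = 3.0 + 10.0 * t + 40.0 * t**2
        out = tk.angular_velocity(self._series(theta), smooth_cutoff=None)
        assert np.allclose(out.omega[1:-1], 10.0 + 80.0 * t[1:-1], rtol=1e-12)

    def test_sinusoid_matches_analytic_derivative(self):
        t = np.arange(240) / 60.0
        theta = 90.0 * np.sin(2 * np.pi * 0.5 * t)
        out = tk.angular_velocity(self._series(theta), smooth_cutoff=None, turn_direction=1)
        expected = 90.0 * np.pi * np.cos(2 * np.pi * 0.5 * t)
        sel = slice(1, -1)
        assert np.max(np.abs(out.omega[sel] - expected[sel])) < 0.005 * 90.0 * np.pi

    def test_direction_orientation_makes_omega_positive(self):
        t = np.arange(120) / 60.0
        out = tk.angular_velocity(self._series(-100.0 * t), smooth_cutoff=None)
        assert out.turn_direction == -1
        assert np.all(out.omega[1:-1] > 0)

    def test_endpoints_flagged(self):
        t = np.arange(60) / 60.0
        out = tk.angular_velocity(self._series(10 * t), smooth_cutoff=None)
        assert out.endpoint_flags[0] and out.endpoint_flags[-1]
        assert not out.endpoint_flags[1:-1].any()

    def test_too_short_series_rejected(self):
        with pytest.raises(ShortSeriesError):
            tk.angular_velocity(self._series(np.array([0.0, 1.0])), smooth_cutoff=None)


class TestFrameInvariance:
    def test_rotation_shifts_angle_translation_does_not(self, fast_noiseless):
        _, track, _ = fast_noiseless
        base = tk.landmark_angle_series(track, "snout")
        phi, shift = 37.0, np.array([5.0, -3.0])
        c, s = np.cos(np.radians(phi)), np.sin(np.radians(phi))
        R = np.array([[c, -s], [s, c]])
        rotated = tk.MidlineTrack(
            times=track.times,
            landmarks=track.landmarks @ R.T + shift,
            frame_rate=track.frame_rate,
            arclengths=track.arclengths,
        )
        out = tk.landmark_angle_series(rotated, "snout")
        assert np.allclose(out.angle - base.angle, phi, atol=1e-9)
        w0 = tk.angular_velocity(base, smooth_cutoff=None, turn_direction=1)
        w1 = tk.angular_velocity(out, smooth_cutoff=None, turn_direction=1)
        assert np.allclose(w0.omega, w1.omega, atol=1e-9)


def test_tail_angle_landmark_choice_changes_rear_reference(fast_noiseless):
    _, track, _ = fast_noiseless
    a = tk.landmark_angle_series(track, "tail", tail_landmarks="peduncle")
    b = tk.landmark_angle_series(track, "tail", tail_landmarks="anal")
    assert a.angle.shape == b.angle.shape
    assert not np.allclose(a.angle, b.angle)
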