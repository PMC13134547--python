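"""Center of mass, moment of inertia, torque, and momenta against oracles."""

import numpy as np
import pytest

import turnkin as tk
from turnkin.body_model import partition_masses
from turnkin.dynamics import segment_centroids
from turnkin.errors import AlignmentError, DegenerateMassError, InvalidArgumentError
from turnkin.kinematics import resample_midline


class TestCenterOfMass:
    def test_equal_masses_midpoint(self):
        c = np.array([[[0.0, 0.0], [2.0, 0.0]]])
        assert np.allclose(tk.center_of_mass(c, [1.0, 1.0]), [[1.0, 0.0]])

    def test_weighted_mean(self):
        c = np.array([[[0.0, 0.0], [4.0, 0.0]]])
        assert np.allclose(tk.center_of_mass(c, [1.0, 3.0]), [[3.0, 0.0]])

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(7)
        c = rng.normal(size=(5, 10, 2))
        m = rng.uniform(0.1, 2.0, 10)
        com = tk.center_of_mass(c, m)
        brute = np.array(
            [[np.sum(m * c[f, :, k]) / m.sum() for k in (0, 1)] for f in range(5)]
        )
        assert np.allclose(com, brute, rtol=1e-12)

    def test_zero_mass_rejected(self):
        with pytest.raises(DegenerateMassError):
            tk.center_of_mass(np.zeros((1, 2, 2)), [0.0, 0.0])


class TestMomentOfInertia:
    def test_two_point_masses(self):
        c = np.array([[[-1.0, 0.0], [1.0, 0.0]]])
        com = np.array([[0.0, 0.0]])
        assert tk.moment_of_inertia(c, [1.0, 1.0], com)[0] == pytest.approx(2.0)

    def test_thin_rod_limit(self):
        n = 200
        centers = np.linspace(0, 10, n + 1)
        c = 0.5 * (centers[:-1] + centers[1:])
        cents = np.stack([c, np.zeros(n)], axis=1)[None]
        m = np.full(n, 1.0 / n)
        com = tk.center_of_mass(cents, m)
        moi = tk.moment_of_inertia(cents, m, com)[0]
        assert moi == pytest.approx(1.0 * 10.0**2 / 12.0, rel=5e-3)

    def test_bent_body_has_lower_moi_than_straight(self):
        s = np.linspace(0, 10, 50)
        straight = np.stack([s, np.zeros_like(s)], axis=1)[None]
        R = 10.0 / np.pi  # semicircle
        phi = s / R
        bent = np.stack([R * np.sin(phi), R * (1 - np.cos(phi))], axis=1)[None]
        m = np.full(50, 0.2)
        for pts in (straight, bent):
            pass
        I_s = tk.moment_of_inertia(straight, m, tk.center_of_mass(straight, m))[0]
        I_b = tk.moment_of_inertia(bent, m, tk.center_of_mass(bent, m))[0]
        assert I_b < I_s

    def test_com_minimizes_moi_over_candidate_centers(self):
        """Parallel-axis check: any other rotation center gives larger I."""
        rng = np.random.default_rng(3)
        cents = rng.normal(size=(1, 12, 2))
        m = rng.uniform(0.5, 1.5, 12)
        com = tk.center_of_mass(cents, m)
        I_com = tk.moment_of_inertia(cents, m, com)[0]
        for dx in (-0.5, 0.3):
            for dy in (-0.4, 0.6):
                I_other = tk.moment_of_inertia(cents, m, com + [dx, dy])[0]
                assert I_other > I_com


class TestNormalizedMoi:
    def test_straight_body_normalizes_to_one(self, uniform_profile):
        bounds = np.linspace(0, 10, 20)
        centers = 0.5 * (bounds[:-1] + bounds[1:])
        cents = np.stack([centers, np.zeros_like(centers)], axis=1)[None]
        m = partition_masses(uniform_profile, bounds)
        moi = tk.moment_of_inertia(cents, m, tk.center_of_mass(cents, m))
        out = tk.normalize_moi(moi, uniform_profile, bounds=bounds)
        assert out[0] == pytest.approx(1.0, abs=1e-6)

    def test_semicircular_bend_matches_analytic_arc_ratio(self, uniform_profile):
        """Uniform body bent to a semicircle: I/I_straight = 12(1-4/pi^2)/pi^2."""
        bounds = np.linspace(0, 10, 400)
        centers = 0.5 * (bounds[:-1] + bounds[1:])
        R = 10.0 / np.pi
        phi = centers / R
        cents = np.stack([R * np.sin(phi), R * (1 - np.cos(phi))], axis=1)[None]
        m = partition_masses(uniform_profile, bounds)
        moi = tk.moment_of_inertia(cents, m, tk.center_of_mass(cents, m))
        out = tk.normalize_moi(moi, uniform_profile, bounds=bounds)
        analytic = 12.0 * (1.0 - 4.0 / np.pi**2) / np.pi**2
        assert out[0] == pytest.approx(analytic, rel=1e-4)

    def test_density_change_leaves_normalized_moi_unchanged(self, uniform_profile):
        heavy = tk.MorphometricProfile(
            arclengths=uniform_profile.arclengths,
            widths=uniform_profile.widths,
            heights=uniform_profile.heights,
            landmark_arclengths=uniform_profile.landmark_arclengths,
            density=2.0,
            total_mass=uniform_profile.total_mass,
            body_length=uniform_profile.body_length,
        )
        bounds = np.linspace(0, 10, 20)
        centers = 0.5 * (bounds[:-1] + bounds[1:])
        cents = np.stack([centers, np.zeros_like(centers)], axis=1)[None]
        for prof in (uniform_profile, heavy):
            m = partition_masses(prof, bounds)
            moi = tk.moment_of_inertia(cents, m, tk.center_of_mass(cents, m))
            assert tk.normalize_moi(moi, prof, bounds=bounds)[0] == pytest.approx(1.0, abs=1e-9)


class TestTorque:
    @staticmethod
    def _rigid_rotation_series(omega_deg_s, omega_dot=0.0, n=120, fps=240.0):
        """Straight 5-point body rotating about its COM (no filtering)."""
        t = np.arange(n) / fps
        theta = np.radians(omega_deg_s * t + 0.5 * omega_dot * t**2)
        s = np.linspace(-2, 2, 5)
        pts = s[None, :, None] * np.stack([np.cos(theta), np.sin(theta)], axis=-1)[:, None, :]
        m = np.ones(4)
        cents = 0.5 * (pts[:, :-1] + pts[:, 1:])
        com = tk.center_of_mass(cents, m)
        moi = tk.moment_of_inertia(cents, m, com)
        tau = tk.whole_body_torque(cents, m, com, 1.0 / fps)
        return moi, tau

    def test_constant_rotation_gives_zero_torque(self):
        moi, tau = self._rigid_rotation_series(300.0)
        assert np.max(np.abs(tau[2:-2])) < 1e-6 * moi[0] * 300.0

    def test_prescribed_acceleration_matches_I_omega_dot(self):
        moi, tau = self._rigid_rotation_series(50.0, omega_dot=500.0)
        expected = moi[2:-2] * 500.0
        assert np.allclose(np.abs(tau[2:-2]), expected, rtol=0.02)

    def test_pure_translation_gives_zero_torque(self):
        t = np.arange(60) / 60.0
        s = np.linspace(-2, 2, 5)
        pts = np.stack([np.add.outer(10.0 * t, s), np.zeros((60, 5))], axis=-1)
        m = np.ones(4)
        cents = 0.5 * (pts[:, :-1] + pts[:, 1:])
        com = tk.center_of_mass(cents, m)
        tau = tk.whole_body_torque(cents, m, com, 1.0 / 60)
        assert np.max(np.abs(tau)) < 1e-8

    def test_product_rule_identity_on_smooth_motion(self, fast_noiseless, profile):
        """Direct differencing of sum(I_i w_i) agrees with the expanded form."""
        _, track, _ = fast_noiseless
        res = resample_midline(track, 20)
        m = partition_masses(profile, res.arclengths)
        cents = segment_centroids(res)
        com = tk.center_of_mass(cents, m)
        tau = tk.whole_body_torque(cents, m, com, res.dt)
        rel = cents - com[:, None, :]
        r2 = np.einsum("fij,fij->fi", rel, rel)
        theta = np.degrees(np.unwrap(np.arctan2(rel[..., 1], rel[..., 0]), axis=0))
        w = np.gradient(theta, res.dt, axis=0)
        Lspin = (m[None, :] * r2 * w).sum(axis=1)
        tau_direct = np.gradient(Lspin, res.dt)
        sel = slice(4, -4)
        scale = np.max(np.abs(tau_direct))
        assert np.max(np.abs(tau[sel] - tau_direct[sel])) < 0.05 * scale

    def test_snout_omega_convention_requires_series(self):
        cents = np.zeros((6, 3, 2))
        cents[:, 0, 0] = 1.0
        cents[:, 2, 0] = -1.0
        with pytest.raises(InvalidArgumentError):
            tk.whole_body_torque(cents, np.ones(3), np.zeros((6, 2)), 0.01, omega_convention="snout")


class TestMomenta:
    def test_fixed_com_zero_linear_momentum(self):
        com = np.tile([2.0, 3.0], (10, 1))
        p, pn = tk.linear_momentum(com, 100.0, 1 / 60, 15.0)
        assert np.allclose(p, 0.0) and np.allclose(pn, 0.0)

    def test_steady_translation_values(self):
        t = np.arange(10) / 60.0
        com = np.stack([15.0 * t, np.zeros(10)], axis=1)
        p, pn = tk.linear_momentum(com, 100.0, 1 / 60, 15.0)
        assert np.allclose(p, 1500.0, rtol=1e-9)
        assert np.allclose(pn, 1.0, rtol=1e-9)

    def test_sinusoidal_path_speed_matches_analytic(self):
        t = np.arange(240) / 60.0
        com = np.stack([3.0 * np.sin(2 * np.pi * 0.5 * t), np.zeros(240)], axis=1)
        p, _ = tk.linear_momentum(com, 1.0, 1 / 60, 1.0)
        expected = np.abs(3.0 * np.pi * np.cos(2 * np.pi * 0.5 * t))
        sel = (expected > 1.0)
        sel[0] = sel[-1] = False
        assert np.max(np.abs(p[sel] - expected[sel]) / expected[sel]) < 0.005

    def test_angular_momentum_substitution(self):
        p, pn = tk.angular_momentum(np.array([2.0]), np.array([300.0]), 1.0, 1.0)
        assert p[0] == pytest.approx(600.0)
        assert pn[0] == pytest.approx(600.0)

    def test_zero_omega_zero_angular_momentum(self):
        p, _ = tk.angular_momentum(np.array([5.0, 5.0]), np.zeros(2), 2.0, 3.0)
        assert np.allclose(p, 0.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(AlignmentError):
            tk.angular_momentum(np.ones(3), np.ones(4), 1.0, 1.0)


class TestConceptualTailModel:
    def test_unit_case(self):
        assert tk.tail_torque_alpha(tk.ConceptualTailModel(1.0, 1.0, 1.0)) == 1.0

    def test_geometric_scaling(self):
        """Scaling distances by k scales alpha by 1/k: bending pays off."""
        base = tk.ConceptualTailModel(2.0, 3.0, 5.0)
        k = 4.0
        scaled = tk.ConceptualTailModel(k * 2.0, 3.0, k**2 * 5.0)
        assert tk.tail_torque_alpha(scaled) == pytest.approx(tk.tail_torque_alpha(base) / k)

    def test_zero_moment_arm(self):
        assert tk.tail_torque_alpha(tk.ConceptualTailModel(0.0, 9.0, 1.0)) == 0.0

    def test_invalid_moi_rejected(self):
        with pytest.raises(InvalidArgumentError):
            tk.ConceptualTailModel(1.0, 1.0, 0.0)


class TestRigidTransformInvariance:
    def test_dynamics_invariant_under_lab_frame_change(self, fast_noiseless, profile):
        _, track, _ = fast_noiseless
        rng = np.random.default_rng(11)
        phi = rng.uniform(0, 360)
        shift = rng.uniform(-20, 20, 2)
        c, s = np.cos(np.radians(phi)), np.sin(np.radians(phi))
        R = np.array([[c, -s], [s, c]])

        def run(tr):
            res = resample_midline(tr, 20)
            m = partition_masses(profile, res.arclengths)
            cents = segment_centroids(res)
            com = tk.center_of_mass(cents, m)
            moi = tk.moment_of_inertia(cents, m, com)
            tau = tk.whole_body_torque(cents, m, com, res.dt)
            p_l, _ = tk.linear_momentum(com, m.sum(), res.dt, profile.body_length)
            return moi, np.abs(tau), np.abs(p_l)

        moved = tk.MidlineTrack(
            times=track.times,
            landmarks=track.landmarks @ R.T + shift,
            frame_rate=track.frame_rate,
            arclengths=track.arclengths,
        )
        for a, b in zip(run(track), run(moved)):
            scale = np.max(np.abs(a)) + 1e-30
            assert np.max(np.abs(a - b)) / scale < 1e-9
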