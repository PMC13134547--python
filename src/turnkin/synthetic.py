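"""Synthetic turning maneuvers with exact, independently computed ground truth.

The generator builds planar landmark tracks of a flexible body performing a
180-degree (configurable) turn, emulating the experimental protocol: seven
midline landmarks filmed at 60 fps, a raised-cosine angular-velocity pulse
whose integral equals the turn angle, a single C-shaped body bend with a
uniform-curvature bump schedule, and a center-of-mass path whose speed ramps
between prescribed pre- and post-turn values while its direction follows the
body heading.  Digitization error is modeled as seeded i.i.d. Gaussian
position noise.

Ground truth is produced by an *oracle* that is independent of the analysis
pipeline: the exact (noise-free) midline is sampled on a time grid ten times
finer than the frame rate and at a fine arclength partition, and the defining
sums (center of mass, sum m_i r_i^2, the product-rule torque expansion) are
evaluated with central differences at that fine resolution — no filtering, no
spline resampling.  Event truths (turn start/end, times of maximum angular
velocity, minimum moment of inertia, maximum torque) come from the dense
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .body_model import MorphometricProfile, partition_masses, straight_body_moi
from .dynamics import center_of_mass, moment_of_inertia, whole_body_torque
from .errors import InvalidArgumentError
from .kinematics import MidlineTrack

__all__ = [
    "bluegill_profile",
    "SyntheticTurnSpec",
    "GroundTruth",
    "slow_turn_spec",
    "fast_turn_spec",
    "generate_bending_turn",
    "generate_rigid_rotation",
    "add_landmark_noise",
    "generate_fin_strokes",
]

#: Landmark positions as fractions of body length (ventral digitizing scheme).
_LANDMARK_FRACTIONS = np.array([0.0, 0.22, 0.40, 0.51, 0.62, 0.76, 0.90])


def bluegill_profile(
    body_length: float = 15.6,
    total_mass: float = 85.0,
    density: float = 1.0,
    n_lines: int = 13,
) -> MorphometricProfile:
    """Morphometric profile of a deep-bodied sunfish-like swimmer.

    Defaults emulate the study animals (adults around 15.6 cm total length).
    The width/height taper is a smooth deep-bodied shape: height peaks at
    about 0.35 L near 40% of the body with a narrow caudal peduncle; width
    peaks at about 0.14 L.  With ``rescale_to_total`` downstream, only the
    *shape* of the taper matters, so the profile doubles as a generic
    percomorph body plan.
    """
    s = np.linspace(0.0, 0.95 * body_length, n_lines)
    x = s / body_length  # fraction of body length
    envelope = np.sin(np.pi * np.clip(x / 0.95, 0.0, 1.0) ** 0.8) ** 1.2
    heights = 0.35 * body_length * envelope * (1.0 - 0.55 * np.clip((x - 0.4) / 0.55, 0, 1) ** 2)
    widths = 0.14 * body_length * envelope
    # keep the snout/peduncle lines slightly open so no slab has zero volume
    heights = np.maximum(heights, 0.02 * body_length)
    widths = np.maximum(widths, 0.01 * body_length)
    return MorphometricProfile(
        arclengths=s,
        widths=widths,
        heights=heights,
        landmark_arclengths=_LANDMARK_FRACTIONS * body_length,
        density=density,
        total_mass=total_mass,
        body_length=body_length,
    )


def _hann_bump(t: NDArray[np.float64], duration: float, peak_frac: float) -> NDArray[np.float64]:
    """Asymmetric raised-cosine bump on [0, duration], peak 1 at peak_frac*duration.

    Both halves are half-cosines, so the bump is C^1 and its integral is
    duration/2 independent of the peak position.
    """
    tp = peak_frac * duration
    out = np.zeros_like(t)
    rise = (t >= 0) & (t <= tp)
    fall = (t > tp) & (t <= duration)
    if tp > 0:
        out[rise] = 0.5 * (1.0 - np.cos(np.pi * t[rise] / tp))
    if duration - tp > 0:
        out[fall] = 0.5 * (1.0 + np.cos(np.pi * (t[fall] - tp) / (duration - tp)))
    return out


@dataclass(frozen=True)
class SyntheticTurnSpec:
    """Parameters of one synthetic turning maneuver.

    The turn occupies ``[pre_roll, pre_roll + duration]`` within the generated
    series; the pre-roll provides the straight-gliding history that turn
    detection and the pre-turn momentum window require.

    ``omega_waveform`` selects the heading-rate schedule inside the turn:

    * ``"raised_cosine"`` (default): asymmetric Hann pulse peaking at
      ``omega_peak_frac`` of the duration with amplitude ``2*turn_angle /
      duration`` so the integral equals ``turn_angle`` exactly;
    * ``"linear_ramp"``: ``omega = omega_start + omega_rate * t`` in the
      window interior (rigid-body torque oracle; ``turn_angle`` is then
      emergent);
    * ``"constant"``: ``omega = omega_start`` in the window interior.

    The ramp and constant waveforms switch on and off through C^1
    raised-cosine transitions of length ``ramp_smooth_s`` at the window
    edges; a hard velocity step would be unphysical and would ring through
    any low-pass position filter.  Between the transitions the angular
    acceleration is exactly ``omega_rate`` (or zero).

    ``bend_angle`` is the total tangent-angle change (deg) along the body at
    peak bend; curvature is uniform along the body and follows a Hann bump in
    time peaking at ``bend_peak_frac``.  A bend angle of ~150 deg reproduces
    the observed minimum normalized moment of inertia of about 0.9 for this
    body plan (the default).
    """

    profile: MorphometricProfile = field(default_factory=bluegill_profile)
    frame_rate: float = 60.0
    duration: float = 1.5
    turn_angle: float = 180.0
    direction: int = 1
    omega_waveform: str = "raised_cosine"
    omega_peak_frac: float = 0.5
    omega_start: float = 0.0
    omega_rate: float = 0.0
    ramp_smooth_s: float = 0.25
    bend_angle: float = 150.0
    bend_peak_frac: float = 0.5
    initial_speed: float = 5.0
    final_speed: float = 5.0
    initial_heading: float = 0.0
    pre_roll: float = 0.5
    post_roll: float = 0.3
    noise_sigma: float = 0.0
    seed: int = 0
    oracle_refine: int = 10
    oracle_points: int = 50

    def __post_init__(self) -> None:
        if self.duration * self.frame_rate < 30:
            raise InvalidArgumentError("turn must span at least 30 frames")
        if self.direction not in (-1, 1):
            raise InvalidArgumentError("direction must be +1 or -1")
        if not 0.0 < self.omega_peak_frac < 1.0 or not 0.0 < self.bend_peak_frac < 1.0:
            raise InvalidArgumentError("peak fractions must lie in (0, 1)")
        if self.noise_sigma < 0:
            raise InvalidArgumentError("noise sigma must be non-negative")
        if np.radians(abs(self.bend_angle)) >= 2.0 * np.pi * 0.999:
            raise InvalidArgumentError("bend angle would self-intersect the midline")
        if self.omega_waveform not in ("raised_cosine", "linear_ramp", "constant"):
            raise InvalidArgumentError("unknown omega waveform")

    @property
    def omega_peak(self) -> float:
        """Peak of the raised-cosine angular-velocity pulse, deg/s."""
        return 2.0 * self.turn_angle / self.duration

    @property
    def total_time(self) -> float:
        return self.pre_roll + self.duration + self.post_roll


@dataclass(frozen=True)
class GroundTruth:
    """Dense oracle series and event truths for one synthetic maneuver.

    All series are on ``times`` (oracle resolution, ``oracle_refine`` times
    the frame rate).  ``t_*`` are absolute times in the same base as the
    generated track; ``omega`` is direction-oriented (positive = into the
    turn).  ``prescribed_omega_peak`` is the analytic pulse amplitude.
    """

    times: NDArray[np.float64]
    theta_snout: NDArray[np.float64]
    omega: NDArray[np.float64]
    moi: NDArray[np.float64]
    moi_norm: NDArray[np.float64]
    tau: NDArray[np.float64]
    com: NDArray[np.float64]
    p_l_norm: NDArray[np.float64]
    p_theta_norm: NDArray[np.float64]
    t_start: float
    t_end: float
    t_max_omega: float
    t_min_moi: float
    t_max_tau: float
    prescribed_omega_peak: float
    prescribed_turn_start: float
    prescribed_turn_end: float
    prescribed_bend_peak_time: float
    direction: int

    @property
    def dt_tau_minus_moi(self) -> float:
        """Positive when the moment of inertia is minimized before torque peaks."""
        return self.t_max_tau - self.t_min_moi

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "theta_snout": self.theta_snout,
                "omega": self.omega,
                "I": self.moi,
                "I_norm": self.moi_norm,
                "tau": self.tau,
                "com_x": self.com[:, 0],
                "com_y": self.com[:, 1],
                "p_l_norm": self.p_l_norm,
                "p_theta_norm": self.p_theta_norm,
            }
        )


def _omega_series(spec: SyntheticTurnSpec, t: NDArray[np.float64]) -> NDArray[np.float64]:
    """Signed heading rate (deg/s) at absolute times t.

    The raised-cosine pulse is zero outside the turn window.  The ramp and
    constant waveforms switch on through a C^1 raised-cosine rise of length
    ``ramp_smooth_s`` and then *continue* (holding the window-end value
    through the post-roll): these are torque-oracle stimuli, and an abrupt
    stop would put a velocity step through the position filter.
    """
    tt = t - spec.pre_roll
    if spec.omega_waveform == "raised_cosine":
        return spec.direction * spec.omega_peak * _hann_bump(tt, spec.duration, spec.omega_peak_frac)
    t_r = min(spec.ramp_smooth_s, spec.duration / 2.0)
    if t_r > 0:
        u = np.clip(tt / t_r, 0.0, 1.0)
        rise = u**3 * (10.0 - 15.0 * u + 6.0 * u**2)  # C^2 smoothstep
    else:
        rise = np.ones_like(tt)
    rise = np.where(tt < 0, 0.0, rise)
    level = spec.omega_start + spec.omega_rate * np.clip(tt, 0.0, spec.duration)
    if spec.omega_waveform == "constant":
        level = np.full_like(tt, spec.omega_start)
    return spec.direction * level * rise


def _curvature_series(spec: SyntheticTurnSpec, t: NDArray[np.float64]) -> NDArray[np.float64]:
    span = spec.profile.landmark_arclengths[-1] - spec.profile.landmark_arclengths[0]
    kappa_max = np.radians(spec.bend_angle) / span
    return spec.direction * kappa_max * _hann_bump(t - spec.pre_roll, spec.duration, spec.bend_peak_frac)


def _speed_series(spec: SyntheticTurnSpec, t: NDArray[np.float64]) -> NDArray[np.float64]:
    tt = np.clip((t - spec.pre_roll) / spec.duration, 0.0, 1.0)
    ramp = 0.5 * (1.0 - np.cos(np.pi * tt))
    return spec.initial_speed + (spec.final_speed - spec.initial_speed) * ramp


def _arc_points(s: NDArray[np.float64], kappa: float, s_mid: float) -> NDArray[np.float64]:
    """Unit-speed uniform-curvature curve sampled at arclengths s (body frame).

    The tangent angle is ``kappa * (s - s_mid)`` so the bend is symmetric
    about mid-body; arclength along the curve is exact by construction
    (inextensible body).
    """
    if abs(kappa) < 1e-12:
        return np.column_stack([s, np.zeros_like(s)])
    beta0 = -kappa * s_mid
    beta = kappa * (s - s_mid)
    x = (np.sin(beta) - np.sin(beta0)) / kappa
    y = (-np.cos(beta) + np.cos(beta0)) / kappa
    return np.column_stack([x, y])


def _shape_at(
    spec: SyntheticTurnSpec,
    kappa: float,
    sample_arcs: NDArray[np.float64],
    com_partition: NDArray[np.float64],
    com_masses: NDArray[np.float64],
) -> NDArray[np.float64]:
    """Body-frame midline at the given curvature, centered on its mass COM.

    Points are expressed with the body axis along +x (snout at the most
    positive x for a straight body) before heading rotation.
    """
    s0 = spec.profile.landmark_arclengths[0]
    s_mid = 0.5 * (com_partition[0] + com_partition[-1])
    pts = _arc_points(sample_arcs - s0, kappa, s_mid - s0)
    # mass COM of the shape from the fine partition
    fine = _arc_points(com_partition - s0, kappa, s_mid - s0)
    cents = 0.5 * (fine[:-1] + fine[1:])
    com = (com_masses[:, None] * cents).sum(axis=0) / com_masses.sum()
    pts = pts - com
    # snout (s=0, at x=0 going to +x for tail) should point forward: flip
    return -pts


def _rotate(points: NDArray[np.float64], angle_deg: NDArray[np.float64] | float) -> NDArray[np.float64]:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    x, y = points[..., 0], points[..., 1]
    return np.stack([c * x - s * y, s * x + c * y], axis=-1)


def _generate(spec: SyntheticTurnSpec) -> tuple[MidlineTrack, GroundTruth]:
    refine = spec.oracle_refine
    dt_frame = 1.0 / spec.frame_rate
    n_frames = int(round(spec.total_time / dt_frame)) + 1
    n_dense = (n_frames - 1) * refine + 1
    t_dense = np.arange(n_dense) * (dt_frame / refine)
    frame_idx = np.arange(n_frames) * refine

    omega = _omega_series(spec, t_dense)  # signed deg/s
    kappa = _curvature_series(spec, t_dense)
    speed = _speed_series(spec, t_dense)

    heading = spec.initial_heading + np.concatenate(
        ([0.0], np.cumsum(0.5 * (omega[1:] + omega[:-1]) * np.diff(t_dense)))
    )
    psi = np.radians(heading)
    vel = speed[:, None] * np.column_stack([np.cos(psi), np.sin(psi)])
    com_path = np.concatenate(
        ([[0.0, 0.0]], np.cumsum(0.5 * (vel[1:] + vel[:-1]) * np.diff(t_dense)[:, None], axis=0))
    )

    lm_arcs = spec.profile.landmark_arclengths
    com_partition = np.linspace(lm_arcs[0], lm_arcs[-1], 201)
    com_masses = partition_masses(spec.profile, com_partition)

    # frame-rate landmark track (sampled from the dense schedule, no re-integration)
    landmarks = np.empty((n_frames, lm_arcs.size, 2))
    for f, k in enumerate(frame_idx):
        shape = _shape_at(spec, kappa[k], lm_arcs, com_partition, com_masses)
        landmarks[f] = _rotate(shape, heading[k]) + com_path[k]
    track = MidlineTrack(
        times=t_dense[frame_idx],
        landmarks=landmarks,
        frame_rate=spec.frame_rate,
        arclengths=lm_arcs.copy(),
    )
    if spec.noise_sigma > 0:
        track = add_landmark_noise(track, spec.noise_sigma, spec.seed)

    truth = _dense_truth(spec, t_dense, omega, kappa, heading, com_path, com_partition, com_masses)
    return track, truth


def _dense_truth(
    spec: SyntheticTurnSpec,
    t_dense: NDArray[np.float64],
    omega_sched: NDArray[np.float64],
    kappa: NDArray[np.float64],
    heading: NDArray[np.float64],
    com_path: NDArray[np.float64],
    com_partition: NDArray[np.float64],
    com_masses: NDArray[np.float64],
) -> GroundTruth:
    """Finite-difference oracle on the noiseless, oversampled midline."""
    arcs = np.linspace(
        spec.profile.landmark_arclengths[0],
        spec.profile.landmark_arclengths[-1],
        spec.oracle_points,
    )
    masses = partition_masses(spec.profile, arcs)
    n = t_dense.size
    pts = np.empty((n, arcs.size, 2))
    for k in range(n):
        shape = _shape_at(spec, kappa[k], arcs, com_partition, com_masses)
        pts[k] = _rotate(shape, heading[k]) + com_path[k]
    cents = 0.5 * (pts[:, :-1] + pts[:, 1:])
    com = center_of_mass(cents, masses)
    moi = moment_of_inertia(cents, masses, com)
    moi_ref = straight_body_moi(spec.profile, bounds=arcs)
    dt = t_dense[1] - t_dense[0]
    tau = whole_body_torque(cents, masses, com, dt)

    # snout angle from the snout and pelvic landmark arclengths on the exact curve
    pair_arcs = np.array(
        [spec.profile.landmark_arclengths[0], spec.profile.landmark_arclengths[2]]
    )
    pair = np.empty((n, 2, 2))
    for k in range(n):
        shape = _shape_at(spec, kappa[k], pair_arcs, com_partition, com_masses)
        pair[k] = _rotate(shape, heading[k]) + com_path[k]
    d = pair[:, 0, :] - pair[:, 1, :]
    theta = np.degrees(np.unwrap(np.arctan2(d[:, 1], d[:, 0])))
    omega_raw = np.gradient(theta, dt)
    omega = omega_raw * spec.direction  # direction-oriented

    m_t = float(masses.sum())
    L = spec.profile.body_length
    v = np.linalg.norm(np.gradient(com, dt, axis=0), axis=1)
    p_l_norm = v / L
    p_theta_norm = moi * omega / (m_t * L**2)

    # event truths from the dense series using the standard detection rules
    t0, t1 = spec.pre_roll, spec.pre_roll + spec.duration
    start_idx = None
    above = omega > 15.0
    sustain = max(1, 3 * spec.oracle_refine)
    run = 0
    for k in range(n):
        run = run + 1 if above[k] else 0
        if run >= sustain:
            start_idx = k - sustain + 1
            break
    if start_idx is None:
        start_idx = int(np.searchsorted(t_dense, t0))
    moved = spec.direction * (theta - theta[start_idx])
    past = np.flatnonzero(moved >= 175.0)
    end_idx = int(past[0]) if past.size else n - 1

    window = slice(start_idx, end_idx + 1)
    idx_w = np.arange(n)[window]
    t_max_omega = float(t_dense[idx_w[np.argmax(omega[window])]])
    t_min_moi = float(t_dense[idx_w[np.argmin(moi[window])]])
    # exclude the one-sided endpoint frames of the full series from tau timing
    tau_abs = np.abs(tau)
    interior = idx_w[(idx_w > 1) & (idx_w < n - 2)]
    t_max_tau = float(t_dense[interior[np.argmax(tau_abs[interior])]])

    return GroundTruth(
        times=t_dense,
        theta_snout=theta,
        omega=omega,
        moi=moi,
        moi_norm=moi / moi_ref,
        tau=tau,
        com=com,
        p_l_norm=p_l_norm,
        p_theta_norm=p_theta_norm,
        t_start=float(t_dense[start_idx]),
        t_end=float(t_dense[end_idx]),
        t_max_omega=t_max_omega,
        t_min_moi=t_min_moi,
        t_max_tau=t_max_tau,
        prescribed_omega_peak=spec.omega_peak,
        prescribed_turn_start=t0,
        prescribed_turn_end=t1,
        prescribed_bend_peak_time=t0 + spec.bend_peak_frac * spec.duration,
        direction=spec.direction,
    )


def generate_bending_turn(spec: SyntheticTurnSpec) -> tuple[MidlineTrack, GroundTruth]:
    """Landmark track and dense ground truth for a bending turn."""
    return _generate(spec)


def generate_rigid_rotation(spec: SyntheticTurnSpec) -> tuple[MidlineTrack, GroundTruth]:
    """Rigid (straight-body) rotation: the bend amplitude is forced to zero.

    With no bend, the moment of inertia is constant, the torque reduces to
    ``I * omega_dot``, and the angular momentum to ``I * omega`` — the
    closed-form oracle for the torque pipeline.
    """
    return _generate(replace(spec, bend_angle=0.0))


def add_landmark_noise(track: MidlineTrack, sigma: float, seed: int) -> MidlineTrack:
    """I.i.d. zero-mean Gaussian perturbation of every landmark coordinate."""
    if sigma < 0:
        raise InvalidArgumentError("noise sigma must be non-negative")
    if sigma == 0:
        return track
    rng = np.random.default_rng(seed)
    noisy = track.landmarks + rng.normal(0.0, sigma, size=track.landmarks.shape)
    return replace(track, landmarks=noisy)


def slow_turn_spec(**overrides) -> SyntheticTurnSpec:
    """Study-condition slow turn: low approach speed, torque before bend.

    Duration 1.9 s gives a mean heading rate of ~95 deg/s over the 180-degree
    turn (the slow-group mean).  The approach speed is low (~0.3 L/s, the
    slow car runs near 1 L/s and fish lag it) and rises out of the turn; the
    rotation pulse peaks before the bend so torque is maximized first.
    """
    L = overrides.get("profile", bluegill_profile()).body_length
    defaults = dict(
        duration=1.9,
        omega_peak_frac=0.35,
        bend_peak_frac=0.62,
        initial_speed=0.3 * L,
        final_speed=0.8 * L,
    )
    defaults.update(overrides)
    return SyntheticTurnSpec(**defaults)


def fast_turn_spec(**overrides) -> SyntheticTurnSpec:
    """Study-condition fast turn: high approach speed, bend before torque.

    Duration 1.0 s gives a mean heading rate of ~180 deg/s (the fast-group
    mean).  The fish approaches at ~2.5 L/s, decelerates through the turn
    (converting linear to angular momentum), and bends early so the moment
    of inertia is minimized before torque peaks.
    """
    L = overrides.get("profile", bluegill_profile()).body_length
    defaults = dict(
        duration=1.0,
        omega_peak_frac=0.65,
        bend_peak_frac=0.32,
        initial_speed=2.5 * L,
        final_speed=0.5 * L,
    )
    defaults.update(overrides)
    return SyntheticTurnSpec(**defaults)


def generate_fin_strokes(
    track: MidlineTrack,
    frames: NDArray[np.int64] | list[int],
    sides: list[str],
    amplitudes: NDArray[np.float64] | list[float],
    fin_length: float = 1.5,
    base_offset: float = 0.4,
) -> pd.DataFrame:
    """Digitized-stroke rows (frame, side, base, tip) with prescribed amplitudes.

    The fin base sits at the pectoral girdle (midpoint of the gill and pelvic
    landmarks) offset laterally to the stroke's side; the tip is placed so the
    angle between the base->tip vector and the posterior local body axis
    (gill->pelvic direction) equals the prescribed amplitude.  Feeding the
    returned rows through the fin-analysis module recovers the amplitudes,
    which makes the prescribed values an exact classification oracle.
    """
    rows = []
    for frame, side, amp in zip(frames, sides, amplitudes, strict=True):
        if side not in ("L", "R"):
            raise InvalidArgumentError("fin side must be 'L' or 'R'")
        gill = track.point("gill")[frame]
        pelvic = track.point("pelvic")[frame]
        posterior = pelvic - gill
        posterior = posterior / np.linalg.norm(posterior)
        left = np.array([posterior[1], -posterior[0]])  # fish-left normal of posterior axis
        lateral = left if side == "L" else -left
        base = 0.5 * (gill + pelvic) + base_offset * lateral
        # rotate the posterior axis toward the fin's side by the amplitude
        sign = -1.0 if side == "L" else 1.0
        a = np.radians(sign * amp)
        c, s = np.cos(a), np.sin(a)
        tip_dir = np.array([c * posterior[0] - s * posterior[1], s * posterior[0] + c * posterior[1]])
        tip = base + fin_length * tip_dir
        rows.append(
            {
                "frame": int(frame),
                "side": side,
                "base_x": base[0],
                "base_y": base[1],
                "tip_x": tip[0],
                "tip_y": tip[1],
                "amplitude_deg": float(amp),
            }
        )
    return pd.DataFrame(rows)
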