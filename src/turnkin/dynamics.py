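"""Whole-body dynamics of a flexible swimmer from midline positions and masses.

Each midline segment is treated as a point mass at its centroid (the midpoint
of consecutive midline points).  With segment masses ``m_i`` and centroid
distances ``r_i`` from the instantaneous whole-body center of mass:

* center of mass:      X_M = sum(x_i m_i) / m_t,  Y_M likewise
* moment of inertia:   I = sum(m_i r_i^2)
* whole-body torque:   tau = sum(d/dt (I_i w_i)) = sum(m_i (2 r_i w_i rdot_i + r_i^2 wdot_i))
* linear momentum:     p_l = m_t v_l,   p_l* = p_l / (m_t L) = v_l / L
* angular momentum:    p_th = I v_th,   p_th* = p_th / (m_t L^2)

The torque expression is the exact product-rule expansion for a non-rigid
body rotating about a moving COM; ``w_i`` is the angular velocity of segment
``i`` about the COM (a configuration flag substitutes the whole-body snout
angular velocity for sensitivity analysis).  Angles are handled in degrees
throughout, matching the field's reporting convention, so torque carries
units of g cm^2 deg s^-2 and angular momentum g cm^2 deg s^-1.  All time
derivatives are central differences on interior frames with one-sided
differences at the series ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .body_model import MorphometricProfile, partition_masses, straight_body_moi
from .errors import (
    AlignmentError,
    DegenerateMassError,
    InvalidArgumentError,
    ShortSeriesError,
)
from .kinematics import AngleSeries, MidlineTrack

__all__ = [
    "DynamicsSeries",
    "ConceptualTailModel",
    "segment_centroids",
    "center_of_mass",
    "moment_of_inertia",
    "normalize_moi",
    "whole_body_torque",
    "linear_momentum",
    "angular_momentum",
    "tail_torque_alpha",
    "compute_dynamics",
]


@dataclass(frozen=True)
class ConceptualTailModel:
    """Rigid conceptual model of tail-driven turning.

    ``r_tail`` is the distance from the center of rotation to the center of
    pressure on the caudal fin (cm), ``f_perp`` the tail force perpendicular
    to that moment arm, and ``moi`` the body's moment of inertia (g cm^2).
    """

    r_tail: float
    f_perp: float
    moi: float

    def __post_init__(self) -> None:
        if self.r_tail < 0:
            raise InvalidArgumentError("r_tail must be non-negative")
        if self.moi <= 0:
            raise InvalidArgumentError("moment of inertia must be positive")


def tail_torque_alpha(model: ConceptualTailModel) -> float:
    """Angular acceleration alpha = tau_tail / I with tau_tail = r_tail * f_perp.

    Bending the body shrinks the moment arm linearly but the moment of
    inertia quadratically, which is the tradeoff this model illustrates.
    """
    return model.r_tail * model.f_perp / model.moi


def segment_centroids(track: MidlineTrack) -> NDArray[np.float64]:
    """Midpoints of consecutive midline points, shape (frames, n_points-1, 2)."""
    return 0.5 * (track.landmarks[:, :-1, :] + track.landmarks[:, 1:, :])


def center_of_mass(centroids: NDArray[np.float64], masses: NDArray[np.float64]) -> NDArray[np.float64]:
    """Mass-weighted mean of segment centroids per frame, shape (frames, 2)."""
    masses = np.asarray(masses, dtype=float)
    if centroids.shape[-2] != masses.size:
        raise AlignmentError("centroid and mass counts differ")
    m_t = masses.sum()
    if m_t <= 0:
        raise DegenerateMassError("total segment mass is zero")
    return np.einsum("fij,i->fj", centroids, masses) / m_t


def moment_of_inertia(
    centroids: NDArray[np.float64],
    masses: NDArray[np.float64],
    com: NDArray[np.float64],
) -> NDArray[np.float64]:
    """I = sum(m_i r_i^2) per frame about the given COM, g cm^2."""
    rel = centroids - com[:, None, :]
    r2 = np.einsum("fij,fij->fi", rel, rel)
    return r2 @ np.asarray(masses, dtype=float)


def normalize_moi(
    moi: NDArray[np.float64],
    profile: MorphometricProfile,
    bounds: NDArray[np.float64] | None = None,
    rescale_to_total: bool = True,
) -> NDArray[np.float64]:
    """Divide the instantaneous I by the individual's straight-body I.

    The straight-body reference uses the same segment partition as the
    pipeline (landmark span at the dynamics granularity) so a perfectly
    straight frame normalizes to 1.
    """
    ref = straight_body_moi(profile, bounds=bounds, rescale_to_total=rescale_to_total)
    if ref <= 0:
        raise DegenerateMassError("straight-body reference moment of inertia is zero")
    return np.asarray(moi, dtype=float) / ref


def _gradient(series: NDArray[np.float64], dt: float) -> NDArray[np.float64]:
    return np.gradient(series, dt, axis=0)


def whole_body_torque(
    centroids: NDArray[np.float64],
    masses: NDArray[np.float64],
    com: NDArray[np.float64],
    dt: float,
    snout_omega: NDArray[np.float64] | None = None,
    omega_convention: str = "per_segment",
) -> NDArray[np.float64]:
    """Non-rigid whole-body torque tau = sum(m_i (2 r_i w_i rdot_i + r_i^2 wdot_i)).

    Per segment, the bearing angle about the instantaneous COM is unwrapped
    and differentiated centrally to give ``w_i`` (deg/s) and ``wdot_i``
    (deg/s^2); ``rdot_i`` is the central difference of the COM distance.  With
    ``omega_convention="snout"`` the first term uses the whole-body snout
    angular velocity instead of ``w_i`` (the literal reading of the printed
    formula); the default per-segment convention follows the defining
    product-rule derivation.
    """
    if centroids.shape[0] < 5:
        raise ShortSeriesError("need at least 5 frames for torque estimation")
    if omega_convention not in ("per_segment", "snout"):
        raise InvalidArgumentError("omega_convention must be 'per_segment' or 'snout'")
    masses = np.asarray(masses, dtype=float)
    rel = centroids - com[:, None, :]
    r = np.sqrt(np.einsum("fij,fij->fi", rel, rel))
    theta = np.degrees(np.unwrap(np.arctan2(rel[..., 1], rel[..., 0]), axis=0))
    omega_i = _gradient(theta, dt)
    omega_dot = _gradient(omega_i, dt)
    r_dot = _gradient(r, dt)
    if omega_convention == "snout":
        if snout_omega is None:
            raise InvalidArgumentError("snout omega series required for omega_convention='snout'")
        first = 2.0 * r * snout_omega[:, None] * r_dot
    else:
        first = 2.0 * r * omega_i * r_dot
    tau_i = masses[None, :] * (first + r**2 * omega_dot)
    return tau_i.sum(axis=1)


def linear_momentum(
    com: NDArray[np.float64],
    total_mass: float,
    dt: float,
    body_length: float,
    signed_axis: NDArray[np.float64] | None = None,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """(p_l, p_l*) from the COM trajectory.

    ``v_l`` is the central difference of COM position; by default its
    magnitude (speed) is used.  Passing ``signed_axis`` (a unit vector)
    projects the velocity onto that axis instead, for momentum-exchange plots
    that need a sign.  ``p_l* = v_l / L`` is in body lengths per second.
    """
    if com.shape[0] < 3:
        raise ShortSeriesError("need at least 3 frames for linear momentum")
    vel = _gradient(com, dt)
    if signed_axis is not None:
        axis = np.asarray(signed_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        v = vel @ axis
    else:
        v = np.linalg.norm(vel, axis=1)
    return total_mass * v, v / body_length


def angular_momentum(
    moi: NDArray[np.float64],
    snout_omega: NDArray[np.float64],
    total_mass: float,
    body_length: float,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """(p_theta, p_theta*) = (I * v_theta, I * v_theta / (m_t L^2)).

    ``v_theta`` is the snout angular velocity (deg/s); the normalized form has
    deg/s scale and removes size differences across individuals.
    """
    moi = np.asarray(moi, dtype=float)
    snout_omega = np.asarray(snout_omega, dtype=float)
    if moi.shape != snout_omega.shape:
        raise AlignmentError("moment of inertia and omega series lengths differ")
    p = moi * snout_omega
    return p, p / (total_mass * body_length**2)


@dataclass(frozen=True)
class DynamicsSeries:
    """Per-frame dynamics of one trial, all series frame-aligned.

    Angles/angular rates in degrees; masses g; lengths cm.  ``tau`` is in
    g cm^2 deg s^-2; ``p_l_norm`` in body lengths per second; ``p_theta_norm``
    in deg/s.
    """

    times: NDArray[np.float64]
    frame_rate: float
    com: NDArray[np.float64]
    moi: NDArray[np.float64]
    moi_norm: NDArray[np.float64]
    tau: NDArray[np.float64]
    p_l: NDArray[np.float64]
    p_l_norm: NDArray[np.float64]
    p_theta: NDArray[np.float64]
    p_theta_norm: NDArray[np.float64]
    omega_snout: NDArray[np.float64]
    theta_snout: NDArray[np.float64]
    omega_tail: NDArray[np.float64]
    theta_tail: NDArray[np.float64]
    turn_direction: int
    total_mass: float
    body_length: float

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time_s": self.times,
                "com_x": self.com[:, 0],
                "com_y": self.com[:, 1],
                "I": self.moi,
                "I_norm": self.moi_norm,
                "tau": self.tau,
                "p_l": self.p_l,
                "p_l_norm": self.p_l_norm,
                "p_theta": self.p_theta,
                "p_theta_norm": self.p_theta_norm,
                "omega_snout": self.omega_snout,
                "omega_tail": self.omega_tail,
                "theta_snout": self.theta_snout,
                "theta_tail": self.theta_tail,
            }
        )


def compute_dynamics(
    resampled: MidlineTrack,
    profile: MorphometricProfile,
    snout: AngleSeries,
    tail: AngleSeries,
    rescale_to_total: bool = True,
    omega_convention: str = "per_segment",
) -> DynamicsSeries:
    """Assemble the full per-frame dynamics from a resampled track.

    ``resampled`` must carry arclengths (as produced by
    :func:`turnkin.kinematics.resample_midline` on a track read with landmark
    arclength metadata) so segment masses can be integrated from the
    morphometric profile.  ``snout``/``tail`` are angle series with angular
    velocity already attached (see :func:`turnkin.kinematics.angular_velocity`).
    """
    if resampled.arclengths is None:
        raise InvalidArgumentError("resampled track must carry arclengths")
    if snout.omega is None or tail.omega is None:
        raise InvalidArgumentError("snout and tail series must carry angular velocity")
    if snout.times.size != resampled.n_frames or tail.times.size != resampled.n_frames:
        raise AlignmentError("angle series and track must share the frame base")
    masses = partition_masses(profile, resampled.arclengths, rescale_to_total=rescale_to_total)
    cents = segment_centroids(resampled)
    com = center_of_mass(cents, masses)
    moi = moment_of_inertia(cents, masses, com)
    moi_norm = normalize_moi(
        moi, profile, bounds=resampled.arclengths, rescale_to_total=rescale_to_total
    )
    tau = whole_body_torque(
        cents,
        masses,
        com,
        resampled.dt,
        snout_omega=snout.omega,
        omega_convention=omega_convention,
    )
    m_t = float(masses.sum())
    p_l, p_l_norm = linear_momentum(com, m_t, resampled.dt, profile.body_length)
    p_theta, p_theta_norm = angular_momentum(moi, snout.omega, m_t, profile.body_length)
    return DynamicsSeries(
        times=resampled.times,
        frame_rate=resampled.frame_rate,
        com=com,
        moi=moi,
        moi_norm=moi_norm,
        tau=tau,
        p_l=p_l,
        p_l_norm=p_l_norm,
        p_theta=p_theta,
        p_theta_norm=p_theta_norm,
        omega_snout=snout.omega,
        theta_snout=snout.angle,
        omega_tail=tail.omega,
        theta_tail=tail.angle,
        turn_direction=snout.turn_direction if snout.turn_direction is not None else 1,
        total_mass=m_t,
        body_length=profile.body_length,
    )
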