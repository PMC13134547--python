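"""Midline track filtering, resampling, and angle/angular-velocity series.

Coordinates are planar centimeters in the chamber frame: +x forward along the
chamber, +y to the fish's left.  Tracks hold one row of 7 midline landmarks
per video frame (snout, gill, pelvic, mid pelvic-anal, anal insertion, mid
anal-peduncle, peduncle) at a uniform frame rate.

Position series are smoothed coordinate-wise with a zero-phase (forward-
backward) low-pass Butterworth filter; zero phase is essential because any
phase lag would shift the torque-versus-inertia timing comparison downstream.
Angles are computed with atan2, unwrapped, low-pass filtered, and
differentiated with central differences; the endpoints use one-sided
differences and are flagged so extremum searches can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import signal
from scipy.interpolate import CubicSpline

from .errors import (
    DegenerateGeometryError,
    InvalidArgumentError,
    ShortSeriesError,
)

__all__ = [
    "LANDMARK_NAMES",
    "TAIL_ANGLE_PAIRS",
    "MidlineTrack",
    "AngleSeries",
    "smooth_positions",
    "resample_midline",
    "segment_angle",
    "landmark_angle_series",
    "angular_velocity",
]

LANDMARK_NAMES = (
    "snout",
    "gill",
    "pelvic",
    "mid_pelvic_anal",
    "anal",
    "mid_anal_peduncle",
    "peduncle",
)

#: Named (front, back) landmark pairs for the tail angle.  The default pairs
#: the peduncle with the mid anal-peduncle point; the alternative uses the
#: anal-fin insertion as the rear reference.
TAIL_ANGLE_PAIRS = {
    "peduncle": ("peduncle", "mid_anal_peduncle"),
    "anal": ("peduncle", "anal"),
}


@dataclass(frozen=True)
class MidlineTrack:
    """Per-frame planar landmark coordinates at a uniform frame rate.

    ``landmarks`` has shape (frames, points, 2) in cm.  ``arclengths``
    optionally records the nominal body arclength of each point (cm), which a
    resampled track carries so the dynamics stage can assign segment masses.
    """

    times: NDArray[np.float64]
    landmarks: NDArray[np.float64]
    frame_rate: float
    arclengths: NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "landmarks", np.asarray(self.landmarks, dtype=float))
        if self.landmarks.ndim != 3 or self.landmarks.shape[2] != 2:
            raise InvalidArgumentError("landmarks must have shape (frames, points, 2)")
        if self.times.shape != (self.landmarks.shape[0],):
            raise InvalidArgumentError("times length must match frame count")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise InvalidArgumentError("times must be strictly increasing")
            if np.ptp(dt) > 1e-6:
                raise InvalidArgumentError("frame spacing must be uniform to 1e-6 s")
        if self.frame_rate <= 0:
            raise InvalidArgumentError("frame rate must be positive")
        if not np.all(np.isfinite(self.landmarks)):
            raise InvalidArgumentError("landmark coordinates contain NaN/inf; interpolate gaps upstream")
        if self.arclengths is not None:
            arc = np.asarray(self.arclengths, dtype=float)
            if arc.shape != (self.landmarks.shape[1],):
                raise InvalidArgumentError("arclengths must have one entry per midline point")
            object.__setattr__(self, "arclengths", arc)

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def n_points(self) -> int:
        return int(self.landmarks.shape[1])

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    def point(self, name: str) -> NDArray[np.float64]:
        """Coordinate series (frames, 2) of a named landmark (7-point tracks)."""
        if self.n_points != len(LANDMARK_NAMES):
            raise InvalidArgumentError("named landmark access requires a 7-point track")
        return self.landmarks[:, LANDMARK_NAMES.index(name), :]


@dataclass(frozen=True)
class AngleSeries:
    """Unwrapped angle (deg vs +x axis) and optional angular velocity.

    ``omega`` is oriented so positive values are motion in the direction of
    the turn; ``endpoint_flags`` marks frames whose derivative came from a
    one-sided difference (series ends) and should be excluded from extremum
    searches.
    """

    times: NDArray[np.float64]
    angle: NDArray[np.float64]
    frame_rate: float
    omega: NDArray[np.float64] | None = None
    turn_direction: int | None = None
    endpoint_flags: NDArray[np.bool_] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "angle", np.asarray(self.angle, dtype=float))
        if self.angle.shape != self.times.shape:
            raise InvalidArgumentError("angle and times must have the same length")
        if self.angle.size >= 2 and np.any(np.abs(np.diff(self.angle)) >= 180.0):
            raise InvalidArgumentError("angle series must be unwrapped (<180 deg between frames)")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate


def _butter_lowpass(cutoff: float, order: int, frame_rate: float):
    nyquist = frame_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise InvalidArgumentError(
            f"cutoff must lie in (0, Nyquist={nyquist:g} Hz), got {cutoff:g} Hz"
        )
    if order < 1:
        raise InvalidArgumentError("filter order must be >= 1")
    return signal.butter(order, cutoff, btype="low", fs=frame_rate, output="sos")


def _filtfilt(series: NDArray[np.float64], sos, order: int) -> NDArray[np.float64]:
    # sosfiltfilt pads by default; require comfortably more frames than taps
    if series.shape[0] <= 3 * (order + 1):
        raise ShortSeriesError(
            f"series of {series.shape[0]} frames too short for order-{order} zero-phase filtering"
        )
    return signal.sosfiltfilt(sos, series, axis=0)


def smooth_positions(track: MidlineTrack, cutoff: float, order: int = 9) -> MidlineTrack:
    """Zero-phase Butterworth low-pass of every landmark coordinate.

    The study protocol uses a 9th-order filter at 8 Hz for fast turns and
    4 Hz for slow turns at 60 fps.  Filtering is applied forward and backward
    (``sosfiltfilt``) so the output has no phase lag; the effective attenuation
    order doubles.  Timestamps are unchanged.
    """
    sos = _butter_lowpass(cutoff, order, track.frame_rate)
    flat = track.landmarks.reshape(track.n_frames, -1)
    smoothed = _filtfilt(flat, sos, order)
    return replace(track, landmarks=smoothed.reshape(track.landmarks.shape))


def _resample_frame(points: NDArray[np.float64], n_points: int, n_dense: int = 2000) -> NDArray[np.float64]:
    """Equal-arclength resampling of one frame's midline through a cubic spline.

    The spline (chord-length parameterized) is sampled densely, its arclength
    measured by chord accumulation, and the parameter values hitting equal
    arclength targets found by inverse interpolation; at ``n_dense`` samples
    the residual spacing non-uniformity is far below the 0.5% contract.
    """
    chord = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(chord <= 1e-12):
        raise DegenerateGeometryError("coincident consecutive landmarks; midline is degenerate")
    u = np.concatenate(([0.0], np.cumsum(chord)))
    spline = CubicSpline(u, points, axis=0)
    uu = np.linspace(0.0, u[-1], n_dense)
    dense = spline(uu)
    arc = np.concatenate(([0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))))
    targets = np.linspace(0.0, arc[-1], n_points)
    return spline(np.interp(targets, arc, uu))


def resample_midline(track: MidlineTrack, n_points: int = 20) -> MidlineTrack:
    """Spline each frame's midline and return points evenly spaced in arclength.

    A cubic spline is fit per frame through the landmarks parameterized by
    cumulative chord length, then iteratively re-parameterized so the returned
    ``n_points`` samples are uniform in arclength to better than 0.5%.  The
    returned track carries nominal arclengths (uniform over the landmark span)
    so segment masses can be assigned downstream.
    """
    if n_points < 7:
        raise InvalidArgumentError("n_points must be >= 7")
    out = np.empty((track.n_frames, n_points, 2))
    for f in range(track.n_frames):
        out[f] = _resample_frame(track.landmarks[f], n_points)
    if track.arclengths is not None:
        arc = np.linspace(track.arclengths[0], track.arclengths[-1], n_points)
    else:
        arc = np.linspace(0.0, 1.0, n_points)
    return MidlineTrack(times=track.times, landmarks=out, frame_rate=track.frame_rate, arclengths=arc)


def segment_angle(front: ArrayLike, back: ArrayLike) -> float:
    """Four-quadrant angle (deg, in (-180, 180]) of the back->front vector vs +x."""
    front = np.asarray(front, dtype=float)
    back = np.asarray(back, dtype=float)
    d = front - back
    if np.hypot(d[0], d[1]) <= 1e-12:
        raise DegenerateGeometryError("front and back points coincide")
    theta = float(np.degrees(np.arctan2(d[1], d[0])))
    return 180.0 if theta == -180.0 else theta


def landmark_angle_series(
    track: MidlineTrack,
    which: str = "snout",
    tail_landmarks: str = "peduncle",
) -> AngleSeries:
    """Unwrapped snout or tail angle series from a 7-landmark track.

    Snout angle uses the pelvic-point -> snout vector.  Tail angle pairs the
    peduncle with either the mid anal-peduncle point (default) or the anal-fin
    insertion (``tail_landmarks="anal"``); the protocol descriptions are
    ambiguous between the two, so both are supported.
    """
    if which == "snout":
        front, back = track.point("snout"), track.point("pelvic")
    elif which == "tail":
        try:
            fname, bname = TAIL_ANGLE_PAIRS[tail_landmarks]
        except KeyError:
            raise InvalidArgumentError(
                f"tail_landmarks must be one of {sorted(TAIL_ANGLE_PAIRS)}"
            ) from None
        front, back = track.point(fname), track.point(bname)
    else:
        raise InvalidArgumentError("which must be 'snout' or 'tail'")
    d = front - back
    if np.any(np.hypot(d[:, 0], d[:, 1]) <= 1e-12):
        raise DegenerateGeometryError("coincident angle landmarks in at least one frame")
    theta = np.degrees(np.unwrap(np.arctan2(d[:, 1], d[:, 0])))
    return AngleSeries(times=track.times, angle=theta, frame_rate=track.frame_rate)


def angular_velocity(
    angles: AngleSeries,
    smooth_cutoff: float | None = 4.0,
    turn_direction: int | None = None,
    filter_order: int = 4,
) -> AngleSeries:
    """Angular velocity by central differences of the (smoothed) angle.

    The unwrapped angle is low-pass filtered (zero-phase Butterworth, default
    4 Hz) and differentiated with a central difference; the first and last
    frames use one-sided differences and are flagged.  ``omega`` is multiplied
    by the turn direction (inferred from the sign of the net angle change when
    not given) so positive values always mean motion in the turn direction.
    """
    if angles.angle.size < 3:
        raise ShortSeriesError("need at least 3 frames to differentiate")
    theta = angles.angle
    if smooth_cutoff is not None:
        sos = _butter_lowpass(smooth_cutoff, filter_order, angles.frame_rate)
        theta = _filtfilt(theta, sos, filter_order)
    if turn_direction is None:
        net = theta[-1] - theta[0]
        turn_direction = 1 if net >= 0 else -1
    elif turn_direction not in (-1, 1):
        raise InvalidArgumentError("turn_direction must be +1 or -1")
    omega = np.gradient(theta, angles.dt) * turn_direction
    flags = np.zeros(theta.size, dtype=bool)
    flags[[0, -1]] = True
    return AngleSeries(
        times=angles.times,
        angle=theta,
        frame_rate=angles.frame_rate,
        omega=omega,
        turn_direction=int(turn_direction),
        endpoint_flags=flags,
    )
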