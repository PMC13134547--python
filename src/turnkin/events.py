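"""Turn detection, phase partitioning, and per-trial summary statistics.

A turn starts at the first observable snout movement in the direction of the
turn and ends when the snout points the opposite way (an approximately 180
degree reversal).  "First observable movement" is operationalized as the
first frame where the direction-oriented snout angular velocity exceeds a
threshold for a sustained run of frames; the end is the first frame where the
unwrapped snout angle has moved at least ``180 - end_tolerance`` degrees from
its value at the start.

Trial summaries collect the quantities the turning-tradeoff analysis rests
on: mean and maximum snout angular velocity, minimum and mean normalized
moment of inertia, the times of maximum angular velocity, minimum moment of
inertia and maximum |torque| relative to the turn start, their ordering
(``dt_tau_minus_I = t_max_tau - t_min_I``; positive means the moment of
inertia was minimized first), and pre-turn and per-third means of the
normalized linear and angular momenta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy import signal

from .dynamics import DynamicsSeries
from .errors import (
    InsufficientHistoryError,
    InvalidArgumentError,
    NoTurnDetectedError,
)
from .kinematics import AngleSeries

__all__ = [
    "TurnEvent",
    "TrialSummary",
    "detect_turn",
    "detect_turns",
    "turn_phases",
    "pre_turn_momentum",
    "summarize_trial",
]


@dataclass(frozen=True)
class TurnEvent:
    """A detected turning maneuver on a frame-indexed series."""

    start_frame: int
    end_frame: int
    direction: int
    total_angle: float
    frame_rate: float
    speed_label: str = ""

    def __post_init__(self) -> None:
        if self.start_frame >= self.end_frame:
            raise InvalidArgumentError("turn must span at least one frame")
        if self.direction not in (-1, 1):
            raise InvalidArgumentError("direction must be +1 or -1")

    @property
    def n_frames(self) -> int:
        """Number of frames in the turn window (inclusive of both ends)."""
        return self.end_frame - self.start_frame + 1

    @property
    def duration(self) -> float:
        return (self.end_frame - self.start_frame) / self.frame_rate


def _sustained_runs(mask: NDArray[np.bool_], sustain: int) -> NDArray[np.int64]:
    """Start indices of runs of True of length >= sustain."""
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return starts[(ends - starts) >= sustain]


def detect_turns(
    snout: AngleSeries,
    omega_threshold: float = 15.0,
    sustain_frames: int = 3,
    end_tolerance: float = 5.0,
    speed_label: str = "",
) -> list[TurnEvent]:
    """All complete reversals in a snout angle series, in time order.

    Scans the series for sustained angular velocity above ``omega_threshold``
    (deg/s, in either direction), takes the local direction from the sign of
    the smoothed velocity, and closes the event at the first frame whose angle
    has moved ``>= 180 - end_tolerance`` degrees from the start frame's angle.
    Candidate starts whose reversal never completes are discarded.
    """
    if snout.omega is None:
        raise InvalidArgumentError("attach angular velocity before turn detection")
    theta = snout.angle
    # undo the direction orientation: recover the signed velocity
    signed_omega = snout.omega * (snout.turn_direction or 1)
    events: list[TurnEvent] = []
    cursor = 0
    n = theta.size
    while cursor < n:
        found = None
        for direction in (1, -1):
            mask = np.zeros(n, dtype=bool)
            mask[cursor:] = direction * signed_omega[cursor:] > omega_threshold
            starts = _sustained_runs(mask, sustain_frames)
            # a "first observable movement" needs observed stillness before it;
            # runs touching the series boundary (filter settling region) are
            # not valid starts
            starts = starts[starts > 0]
            if starts.size == 0:
                continue
            s = int(starts[0])
            moved = direction * (theta[s:] - theta[s])
            past = np.flatnonzero(moved >= 180.0 - end_tolerance)
            if past.size == 0:
                continue
            e = s + int(past[0])
            if found is None or s < found[0]:
                found = (s, e, direction)
        if found is None:
            break
        s, e, direction = found
        events.append(
            TurnEvent(
                start_frame=s,
                end_frame=e,
                direction=direction,
                total_angle=float(theta[e] - theta[s]),
                frame_rate=snout.frame_rate,
                speed_label=speed_label,
            )
        )
        cursor = e + 1
    return events


def detect_turn(
    snout: AngleSeries,
    omega_threshold: float = 15.0,
    sustain_frames: int = 3,
    end_tolerance: float = 5.0,
    speed_label: str = "",
) -> TurnEvent:
    """The first complete reversal; raises :class:`NoTurnDetectedError` if none."""
    events = detect_turns(
        snout,
        omega_threshold=omega_threshold,
        sustain_frames=sustain_frames,
        end_tolerance=end_tolerance,
        speed_label=speed_label,
    )
    if not events:
        raise NoTurnDetectedError("no sustained reversal found in the angle series")
    return events[0]


def turn_phases(event: TurnEvent) -> list[NDArray[np.int64]]:
    """Three contiguous near-equal thirds of the turn's frame indices.

    The frame count is split as evenly as possible; remainder frames go to
    the last third (e.g. 91 frames -> 30/30/31).
    """
    frames = np.arange(event.start_frame, event.end_frame + 1)
    base = frames.size // 3
    return [frames[:base], frames[base : 2 * base], frames[2 * base :]]


def pre_turn_momentum(series: NDArray[np.float64], event: TurnEvent) -> float:
    """Mean of a momentum series over the two frames before the turn start.

    At 60 fps two frames is about 30 ms of pre-turn history.
    """
    if event.start_frame < 2:
        raise InsufficientHistoryError("turn starts within 2 frames of the series start")
    return float(np.mean(series[event.start_frame - 2 : event.start_frame]))


@dataclass(frozen=True)
class TrialSummary:
    """Scalar summary of one turning trial.

    Times are seconds from the turn start.  ``dt_tau_minus_I`` positive means
    the moment of inertia was minimized before torque peaked ("MoI first");
    ``omega_before_min_moi`` is True when angular velocity peaked before the
    moment of inertia reached its minimum.
    """

    speed_label: str
    direction: int
    duration: float
    total_angle: float
    mean_omega: float
    max_omega: float
    t_max_omega: float
    min_moi_norm: float
    mean_moi_norm: float
    t_min_moi: float
    max_abs_tau: float
    t_max_tau: float
    dt_tau_minus_moi: float
    omega_before_min_moi: bool
    pre_turn_p_l_norm: float
    pre_turn_p_theta_norm: float
    thirds_p_l_norm: tuple[float, float, float]
    thirds_p_theta_norm: tuple[float, float, float]
    has_nan: bool = False
    fin_summary: "object | None" = None

    def to_dict(self) -> dict:
        d = {
            "speed_label": self.speed_label,
            "direction": self.direction,
            "duration_s": self.duration,
            "total_angle_deg": self.total_angle,
            "mean_omega_deg_s": self.mean_omega,
            "max_omega_deg_s": self.max_omega,
            "t_max_omega_s": self.t_max_omega,
            "min_I_norm": self.min_moi_norm,
            "mean_I_norm": self.mean_moi_norm,
            "t_min_I_s": self.t_min_moi,
            "max_abs_tau": self.max_abs_tau,
            "t_max_tau_s": self.t_max_tau,
            "dt_tau_minus_I_s": self.dt_tau_minus_moi,
            "omega_before_min_I": self.omega_before_min_moi,
            "pre_p_l_norm": self.pre_turn_p_l_norm,
            "pre_p_theta_norm": self.pre_turn_p_theta_norm,
        }
        for k in range(3):
            d[f"third{k + 1}_p_l_norm"] = self.thirds_p_l_norm[k]
            d[f"third{k + 1}_p_theta_norm"] = self.thirds_p_theta_norm[k]
        d["has_nan"] = self.has_nan
        if self.fin_summary is not None:
            d.update(self.fin_summary.to_dict())
        return d


def _extremum_time(
    values: NDArray[np.float64], frames: NDArray[np.int64], event: TurnEvent, mode: str
) -> tuple[float, float]:
    window = values[frames]
    idx = int(np.argmin(window) if mode == "min" else np.argmax(window))
    t = (frames[idx] - event.start_frame) / event.frame_rate
    return float(window[idx]), float(t)


def summarize_trial(
    dynamics: DynamicsSeries,
    event: TurnEvent,
    fin_summary: "object | None" = None,
    tau_signed: bool = False,
    timing_cutoff_hz: float | None = None,
) -> TrialSummary:
    """Extract the trial-level statistics for one turn.

    Extrema and their times are restricted to the turn window; ties are broken
    to the earliest frame.  Torque timing uses ``|tau|`` by default
    (``tau_signed=True`` restricts the maximum to torque in the turn
    direction).  ``timing_cutoff_hz`` optionally low-pass filters the
    moment-of-inertia series (zero phase) *only* for locating its extremum
    time: the inertia minimum of a turning fish is quadratically flat, so
    residual digitizing noise otherwise jitters its argmin; the reported
    extremum *values* always come from the unfiltered series.  NaN anywhere
    in the turn window sets ``has_nan`` and propagates into the affected
    statistics.
    """
    if event.end_frame >= dynamics.n_frames:
        raise InvalidArgumentError("event extends past the dynamics series")
    frames = np.arange(event.start_frame, event.end_frame + 1)
    omega = dynamics.omega_snout
    tau = dynamics.tau * event.direction if tau_signed else np.abs(dynamics.tau)

    max_omega, t_max_omega = _extremum_time(omega, frames, event, "max")
    min_moi, _ = _extremum_time(dynamics.moi_norm, frames, event, "min")
    moi_for_timing = dynamics.moi_norm
    if timing_cutoff_hz is not None and frames.size > 15:
        sos = signal.butter(4, timing_cutoff_hz, btype="low", fs=event.frame_rate, output="sos")
        moi_for_timing = signal.sosfiltfilt(sos, dynamics.moi_norm)
    _, t_min_moi = _extremum_time(moi_for_timing, frames, event, "min")
    max_tau, t_max_tau = _extremum_time(tau, frames, event, "max")

    thirds = turn_phases(event)
    thirds_pl = tuple(float(np.mean(dynamics.p_l_norm[f])) for f in thirds)
    thirds_pt = tuple(float(np.mean(dynamics.p_theta_norm[f])) for f in thirds)

    window_stack = np.concatenate(
        [omega[frames], dynamics.moi_norm[frames], tau[frames], dynamics.p_l_norm[frames]]
    )
    return TrialSummary(
        speed_label=event.speed_label,
        direction=event.direction,
        duration=event.duration,
        total_angle=event.total_angle,
        mean_omega=float(np.mean(omega[frames])),
        max_omega=max_omega,
        t_max_omega=t_max_omega,
        min_moi_norm=min_moi,
        mean_moi_norm=float(np.mean(dynamics.moi_norm[frames])),
        t_min_moi=t_min_moi,
        max_abs_tau=max_tau,
        t_max_tau=t_max_tau,
        dt_tau_minus_moi=t_max_tau - t_min_moi,
        omega_before_min_moi=bool(t_max_omega < t_min_moi),
        pre_turn_p_l_norm=pre_turn_momentum(dynamics.p_l_norm, event),
        pre_turn_p_theta_norm=pre_turn_momentum(dynamics.p_theta_norm, event),
        thirds_p_l_norm=thirds_pl,
        thirds_p_theta_norm=thirds_pt,
        has_nan=bool(np.any(~np.isfinite(window_stack))),
        fin_summary=fin_summary,
    )
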