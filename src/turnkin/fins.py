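"""Pectoral-fin stroke amplitude, backing classification, and turn summaries.

Stroke amplitude is the angle between the fin's base-to-tip vector at maximal
extension and the posterior-pointing local body axis at the pectoral girdle:
0 deg means the fin lies flat against the body pointing backward, 90 deg
perpendicular, and anything greater than 90 deg is angled toward the snout.
A *backing stroke* — a stroke that pushes water forward and so brakes or
reverses that side of the body — is any stroke with amplitude strictly
greater than 90 deg at maximal extension.

Fins are labeled inside/outside relative to the turn: in a turn to the
fish's left (direction +1) the left fin is the inside fin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike

from .errors import DegenerateGeometryError, InvalidArgumentError
from .events import TurnEvent

__all__ = [
    "FinStrokeEvent",
    "FinSummary",
    "stroke_amplitude",
    "classify_backing",
    "inside_fin_side",
    "fin_summary",
]


def stroke_amplitude(base: ArrayLike, tip: ArrayLike, body_axis_posterior: ArrayLike) -> float:
    """Angle (deg, [0, 180]) between the base->tip fin vector and the posterior body axis."""
    base = np.asarray(base, dtype=float)
    tip = np.asarray(tip, dtype=float)
    axis = np.asarray(body_axis_posterior, dtype=float)
    fin = tip - base
    nf = np.linalg.norm(fin)
    na = np.linalg.norm(axis)
    if nf <= 1e-12 or na <= 1e-12:
        raise DegenerateGeometryError("zero-length fin vector or body axis")
    cosang = np.clip(np.dot(fin, axis) / (nf * na), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def classify_backing(amplitude: float) -> bool:
    """True iff the stroke amplitude strictly exceeds 90 deg."""
    return amplitude > 90.0


@dataclass(frozen=True)
class FinStrokeEvent:
    """One digitized pectoral fin stroke at maximal extension."""

    frame: int
    side: str  # 'L' or 'R' in the fish's body frame
    base: np.ndarray
    tip: np.ndarray
    amplitude: float
    backing: bool
    inside: bool | None = None

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise InvalidArgumentError("fin side must be 'L' or 'R'")
        if not 0.0 <= self.amplitude <= 180.0:
            raise InvalidArgumentError("amplitude must lie in [0, 180] deg")

    @classmethod
    def from_points(
        cls,
        frame: int,
        side: str,
        base: ArrayLike,
        tip: ArrayLike,
        body_axis_posterior: ArrayLike,
        turn_direction: int | None = None,
    ) -> "FinStrokeEvent":
        amp = stroke_amplitude(base, tip, body_axis_posterior)
        inside = None
        if turn_direction is not None:
            inside = side == inside_fin_side(turn_direction)
        return cls(
            frame=int(frame),
            side=side,
            base=np.asarray(base, dtype=float),
            tip=np.asarray(tip, dtype=float),
            amplitude=amp,
            backing=classify_backing(amp),
            inside=inside,
        )


def inside_fin_side(turn_direction: int) -> str:
    """Body-frame side ('L'/'R') of the inside fin for a given turn direction.

    Direction +1 is a turn to the fish's left (+y), so the left fin is inside.
    """
    if turn_direction not in (-1, 1):
        raise InvalidArgumentError("turn_direction must be +1 or -1")
    return "L" if turn_direction == 1 else "R"


@dataclass(frozen=True)
class FinSummary:
    """Stroke counts, backing count, per-side mean amplitudes, and frequency."""

    n_strokes: int
    n_inside: int
    n_outside: int
    n_backing: int
    mean_amp_inside: float
    mean_amp_outside: float
    frequency: float  # strokes per second over the turn
    empty: bool = False

    def to_dict(self) -> dict:
        return {
            "fin_n_strokes": self.n_strokes,
            "fin_n_inside": self.n_inside,
            "fin_n_outside": self.n_outside,
            "fin_n_backing": self.n_backing,
            "fin_mean_amp_inside": self.mean_amp_inside,
            "fin_mean_amp_outside": self.mean_amp_outside,
            "fin_frequency_hz": self.frequency,
            "fin_empty": self.empty,
        }


def fin_summary(strokes: list[FinStrokeEvent], event: TurnEvent) -> FinSummary:
    """Summarize the strokes falling within a turn window.

    Frequency is the stroke count divided by the turn duration (Hz); an empty
    stroke list yields zero counts and frequency with the ``empty`` flag set.
    """
    inside_side = inside_fin_side(event.direction)
    in_turn = [s for s in strokes if event.start_frame <= s.frame <= event.end_frame]
    if not in_turn:
        return FinSummary(0, 0, 0, 0, float("nan"), float("nan"), 0.0, empty=True)
    inside = [s for s in in_turn if s.side == inside_side]
    outside = [s for s in in_turn if s.side != inside_side]
    mean_in = float(np.mean([s.amplitude for s in inside])) if inside else float("nan")
    mean_out = float(np.mean([s.amplitude for s in outside])) if outside else float("nan")
    return FinSummary(
        n_strokes=len(in_turn),
        n_inside=len(inside),
        n_outside=len(outside),
        n_backing=sum(s.backing for s in in_turn),
        mean_amp_inside=mean_in,
        mean_amp_outside=mean_out,
        frequency=len(in_turn) / event.duration,
    )
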