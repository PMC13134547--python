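"""Run configuration: filter settings, detection thresholds, conventions.

Defaults encode the study protocol: 9th-order zero-phase Butterworth position
filtering at 8 Hz for fast turns and 4 Hz for slow turns, 4 Hz angle
smoothing, 60 fps video, 20-point midline resampling, and a sustained
15 deg/s threshold operationalizing "first observable snout movement".
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidArgumentError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Analysis parameters for one run.

    ``speed_label`` selects the position-filter cutoff from ``cutoff_hz``;
    ``tail_landmarks`` chooses the rear landmark of the tail angle
    ("peduncle" pairs peduncle with the mid anal-peduncle point, "anal" with
    the anal-fin insertion); ``torque_omega`` selects the per-segment or
    whole-body snout angular velocity in the torque product-rule term.
    """

    speed_label: str = "slow"
    cutoff_hz: dict = field(default_factory=lambda: {"slow": 4.0, "fast": 8.0})
    filter_order: int = 9
    angle_cutoff_hz: float = 4.0
    angle_filter_order: int = 4
    n_points: int = 20
    omega_threshold_deg_s: float = 15.0
    sustain_frames: int = 3
    end_tolerance_deg: float = 5.0
    tail_landmarks: str = "peduncle"
    torque_omega: str = "per_segment"
    rescale_mass: bool = True
    tau_signed: bool = False
    timing_cutoff_hz: float | None = 4.0
    turn_direction: int | None = None
    exclude: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_label not in self.cutoff_hz:
            raise InvalidArgumentError(
                f"speed_label {self.speed_label!r} not in cutoff table {sorted(self.cutoff_hz)}"
            )
        if self.tail_landmarks not in ("peduncle", "anal"):
            raise InvalidArgumentError("tail_landmarks must be 'peduncle' or 'anal'")
        if self.torque_omega not in ("per_segment", "snout"):
            raise InvalidArgumentError("torque_omega must be 'per_segment' or 'snout'")
        if self.turn_direction not in (None, -1, 1):
            raise InvalidArgumentError("turn_direction must be None, +1 or -1")

    @property
    def position_cutoff(self) -> float:
        return float(self.cutoff_hz[self.speed_label])

    def validate_for_frame_rate(self, frame_rate: float) -> None:
        nyquist = frame_rate / 2.0
        if not 0 < self.position_cutoff < nyquist:
            raise InvalidArgumentError(
                f"position cutoff {self.position_cutoff} Hz not below Nyquist {nyquist} Hz"
            )
        if not 0 < self.angle_cutoff_hz < nyquist:
            raise InvalidArgumentError(
                f"angle cutoff {self.angle_cutoff_hz} Hz not below Nyquist {nyquist} Hz"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance headers."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
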