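"""Readers and writers for landmark tracks, morphometry, and stroke tables.

Formats
-------
Landmark CSV
    Columns ``frame, time_s, pt0_x, pt0_y, ..., pt6_x, pt6_y`` (cm), header
    required.  Optional leading comment lines ``# key: value`` carry metadata
    (``frame_rate``, ``landmarks_cm`` as a comma list of arclengths).
Landmark HDF5
    Datasets ``/times`` (s) and ``/landmarks`` (frames x points x 2, cm) with
    attributes ``frame_rate`` and ``units``; optional ``/arclengths``.
Morphometry CSV
    Comment header ``# mass_g: ...``, ``# length_cm: ...``, ``# density: ...``,
    ``# landmarks_cm: s0,...,s6`` followed by columns
    ``line_index, arclength_cm, width_cm, height_cm``.
Stroke CSV
    Columns ``frame, side, base_x, base_y, tip_x, tip_y`` with side L/R.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .body_model import MorphometricProfile
from .errors import SchemaError
from .kinematics import LANDMARK_NAMES, MidlineTrack

__all__ = [
    "read_landmark_track",
    "write_landmark_track",
    "read_morphometry",
    "write_morphometry",
    "read_strokes",
    "write_strokes",
]

_TRACK_COLUMNS = ["frame", "time_s"] + [
    f"pt{i}_{ax}" for i in range(len(LANDMARK_NAMES)) for ax in ("x", "y")
]


def _read_comment_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_landmark_track(path: str | Path, fmt: str | None = None, sort_frames: bool = True) -> MidlineTrack:
    """Read a 7-landmark track from CSV or HDF5 (inferred from the suffix).

    Shuffled frame order is sorted by time when ``sort_frames`` is true and
    rejected otherwise.  Missing columns and NaN coordinates raise
    :class:`~turnkin.errors.SchemaError` naming the offender; interpolate
    tracking gaps upstream.
    """
    path = Path(path)
    fmt = fmt or ("hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv")
    if fmt == "hdf5":
        with h5py.File(path, "r") as fh:
            times = np.asarray(fh["times"], dtype=float)
            landmarks = np.asarray(fh["landmarks"], dtype=float)
            frame_rate = float(fh.attrs["frame_rate"])
            arclengths = np.asarray(fh["arclengths"], dtype=float) if "arclengths" in fh else None
    else:
        meta = _read_comment_metadata(path)
        df = pd.read_csv(path, comment="#")
        missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"landmark CSV missing columns: {', '.join(missing)}")
        if df[_TRACK_COLUMNS].isna().any().any():
            bad = df.columns[df[_TRACK_COLUMNS].isna().any()].tolist()
            raise SchemaError(f"NaN values in columns: {', '.join(map(str, bad))}")
        times = df["time_s"].to_numpy(dtype=float)
        coords = df[_TRACK_COLUMNS[2:]].to_numpy(dtype=float)
        landmarks = coords.reshape(len(df), len(LANDMARK_NAMES), 2)
        if "frame_rate" in meta:
            frame_rate = float(meta["frame_rate"])
        elif times.size >= 2:
            frame_rate = 1.0 / float(np.median(np.diff(np.sort(times))))
        else:
            raise SchemaError("cannot infer frame rate from a single-frame CSV")
        arclengths = None
        if "landmarks_cm" in meta:
            arclengths = np.array([float(v) for v in meta["landmarks_cm"].split(",")])
    if times.size >= 2 and np.any(np.diff(times) <= 0):
        if not sort_frames:
            raise SchemaError("frames are out of order and sort_frames is disabled")
        order = np.argsort(times)
        times, landmarks = times[order], landmarks[order]
    return MidlineTrack(times=times, landmarks=landmarks, frame_rate=frame_rate, arclengths=arclengths)


def write_landmark_track(track: MidlineTrack, path: str | Path, fmt: str | None = None) -> None:
    """Write a track as CSV (with metadata comments) or HDF5."""
    path = Path(path)
    fmt = fmt or ("hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv")
    if fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=track.times)
            fh.create_dataset("landmarks", data=track.landmarks)
            if track.arclengths is not None:
                fh.create_dataset("arclengths", data=track.arclengths)
            fh.attrs["frame_rate"] = track.frame_rate
            fh.attrs["units"] = "cm"
        return
    buf = _io.StringIO()
    buf.write(f"# frame_rate: {float(track.frame_rate)!r}\n# units: cm\n")
    if track.arclengths is not None:
        buf.write("# landmarks_cm: " + ",".join(repr(float(v)) for v in track.arclengths) + "\n")
    df = pd.DataFrame(
        track.landmarks.reshape(track.n_frames, -1), columns=_TRACK_COLUMNS[2:]
    )
    df.insert(0, "time_s", track.times)
    df.insert(0, "frame", np.arange(track.n_frames))
    df.to_csv(buf, index=False, float_format="%.12g")
    path.write_text(buf.getvalue())


def read_morphometry(path: str | Path) -> MorphometricProfile:
    """Read a morphometry table with its comment-line metadata block."""
    path = Path(path)
    meta = _read_comment_metadata(path)
    for key in ("mass_g", "length_cm", "landmarks_cm"):
        if key not in meta:
            raise SchemaError(f"morphometry CSV missing '# {key}:' metadata line")
    df = pd.read_csv(path, comment="#")
    for col in ("arclength_cm", "width_cm", "height_cm"):
        if col not in df.columns:
            raise SchemaError(f"morphometry CSV missing column {col}")
    return MorphometricProfile(
        arclengths=df["arclength_cm"].to_numpy(dtype=float),
        widths=df["width_cm"].to_numpy(dtype=float),
        heights=df["height_cm"].to_numpy(dtype=float),
        landmark_arclengths=np.array([float(v) for v in meta["landmarks_cm"].split(",")]),
        density=float(meta.get("density", 1.0)),
        total_mass=float(meta["mass_g"]),
        body_length=float(meta["length_cm"]),
    )


def write_morphometry(profile: MorphometricProfile, path: str | Path) -> None:
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"# mass_g: {float(profile.total_mass)!r}\n")
    buf.write(f"# length_cm: {float(profile.body_length)!r}\n")
    buf.write(f"# density: {float(profile.density)!r}\n")
    buf.write("# landmarks_cm: " + ",".join(repr(float(v)) for v in profile.landmark_arclengths) + "\n")
    df = pd.DataFrame(
        {
            "line_index": np.arange(profile.n_lines),
            "arclength_cm": profile.arclengths,
            "width_cm": profile.widths,
            "height_cm": profile.heights,
        }
    )
    df.to_csv(buf, index=False, float_format="%.12g")
    path.write_text(buf.getvalue())


def read_strokes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = ["frame", "side", "base_x", "base_y", "tip_x", "tip_y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"stroke CSV missing columns: {', '.join(missing)}")
    bad = set(df["side"].unique()) - {"L", "R"}
    if bad:
        raise SchemaError(f"stroke CSV has invalid side labels: {sorted(bad)}")
    return df


def write_strokes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")
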