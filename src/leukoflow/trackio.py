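"""Track data model, Tracker-dialect I/O, and finite-difference kinematics.

A flow-chamber recording is a set of per-leukocyte trajectories: ordered
``(t, x, y)`` samples in seconds and micrometres, with ``x`` the flow axis
of the 600 x 480 um observation window.  Velocity and acceleration series
are forward differences of ``x``::

    v[i] = (x[i+1] - x[i]) / (t[i+1] - t[i])
    a[i] = (v[i+1] - v[i]) / (t[i+1] - t[i])

so a track of ``n`` points has ``n-1`` velocity and ``n-2`` acceleration
samples.  Only the flow axis enters the descriptors; transverse motion in
a laminar chamber is negligible.

The "Tracker dialect" read and written here is a plain UTF-8 table with a
header naming time and position columns (``t``/``time``, ``x``, ``y``,
unit suffixes tolerated), either one file per cell or a single file with a
``track_id`` column.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = ("Healthy", "T1D", "T2D")


class TrackFormatError(ValueError):
    """Raised when an export file cannot be interpreted as tracks."""


class EmptyRecordingError(ValueError):
    """Raised when a file yields no usable track at all."""


class KinematicsError(ValueError):
    """Raised when a track is too short for the requested derivative."""


@dataclass(frozen=True)
class TrackPoint:
    """One video-frame sample of a leukocyte: time (s), position (um)."""

    t: float
    x: float
    y: float


@dataclass(frozen=True)
class CalibrationSpec:
    """Spatial/temporal calibration of the recording.

    ``scale_reference_um`` is the length of the calibration reference in
    the field of view (327 um for this chamber); the visible window is
    600 x 480 um.
    """

    scale_reference_um: float = 327.0
    window_x_um: float = 600.0
    window_y_um: float = 480.0
    frame_interval_s: float = 0.033

    def __post_init__(self) -> None:
        for name in ("scale_reference_um", "window_x_um", "window_y_um", "frame_interval_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def field_area_mm2(self) -> float:
        return self.window_x_um * self.window_y_um / 1e6


@dataclass
class Track:
    """One leukocyte's trajectory with derived kinematic series."""

    track_id: str
    points: list[TrackPoint]
    velocity_series: np.ndarray | None = None
    acceleration_series: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.points)

    @property
    def times(self) -> np.ndarray:
        return np.array([p.t for p in self.points], dtype=float)

    @property
    def xs(self) -> np.ndarray:
        return np.array([p.x for p in self.points], dtype=float)

    @property
    def ys(self) -> np.ndarray:
        return np.array([p.y for p in self.points], dtype=float)

    def is_monotone(self) -> bool:
        ts = self.times
        return bool(np.all(np.diff(ts) > 0))


@dataclass
class FieldRecording:
    """All tracks of one recorded field plus acquisition metadata."""

    individual_id: str
    group: str
    tnf: bool
    duration_s: float
    calibration: CalibrationSpec
    tracks: list[Track] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"group must be one of {VALID_GROUPS}, got {self.group!r}")

    def usable_tracks(self, min_points: int = 3) -> list[Track]:
        return [tr for tr in self.tracks if len(tr) >= min_points]


# ---------------------------------------------------------------------------
# kinematics


def compute_kinematics(track: Track) -> Track:
    """Attach forward-difference velocity and acceleration series to a track.

    Irregular sampling is allowed: each difference uses its own dt.  The
    acceleration series is the forward difference of the velocity series,
    indexed to the earlier interval.

    Raises
    ------
    KinematicsError
        If the track has fewer than 2 points.
    """
    if len(track) < 2:
        raise KinematicsError(f"track {track.track_id!r} has {len(track)} point(s); need >= 2")
    t = track.times
    x = track.xs
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise KinematicsError(f"track {track.track_id!r} has non-increasing timestamps")
    v = np.diff(x) / dt
    track.velocity_series = v
    if len(track) >= 3:
        track.acceleration_series = np.diff(v) / dt[:-1]
    else:
        track.acceleration_series = np.empty(0)
    return track


# ---------------------------------------------------------------------------
# Tracker-dialect parsing

_TIME_NAMES = ("t", "time")
_X_NAMES = ("x",)
_Y_NAMES = ("y",)
_ID_NAMES = ("track_id", "track", "cell", "cell_id")


def _canonical(col: str) -> str:
    """Normalize a header name: lowercase, strip unit suffixes like '(um)'."""
    c = col.strip().lower()
    c = re.sub(r"[\(\[].*?[\)\]]", "", c)  # drop "(µm)" / "[s]"
    return c.strip().rstrip("_ ")


def _find_column(columns: Sequence[str], names: Iterable[str]) -> str | None:
    canon = {_canonical(c): c for c in columns}
    for n in names:
        if n in canon:
            return canon[n]
    return None


def _read_table(path: Path) -> pd.DataFrame:
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise EmptyRecordingError(f"{path} is empty")
    first_line = text.lstrip().splitlines()[0]
    sep = "\t" if "\t" in first_line else ","
    return pd.read_csv(path, sep=sep, skipinitialspace=True)


def _df_to_tracks(df: pd.DataFrame, source: str) -> tuple[list[Track], int]:
    """Build tracks from a parsed table; returns (tracks, skipped_row_count)."""
    tcol = _find_column(df.columns, _TIME_NAMES)
    if tcol is None:
        raise TrackFormatError(f"{source}: no time column among {list(df.columns)}")
    xcol = _find_column(df.columns, _X_NAMES)
    if xcol is None:
        raise TrackFormatError(f"{source}: no x column among {list(df.columns)}")
    ycol = _find_column(df.columns, _Y_NAMES)
    idcol = _find_column(df.columns, _ID_NAMES)

    keep = [tcol, xcol] + ([ycol] if ycol else [])
    numeric = df[keep].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    n_skipped = int(bad.sum())
    if n_skipped:
        logger.warning("%s: skipped %d malformed row(s)", source, n_skipped)
    df = df.loc[~bad]
    numeric = numeric.loc[~bad]

    tracks: list[Track] = []
    if idcol is not None:
        groups = [(str(k), idx) for k, idx in df.groupby(idcol, sort=False).groups.items()]
    else:
        groups = [(Path(source).stem, df.index)]
    for tid, idx in groups:
        sub = numeric.loc[idx]
        pts = [
            TrackPoint(t=float(r[tcol]), x=float(r[xcol]), y=float(r[ycol]) if ycol else 0.0)
            for _, r in sub.iterrows()
        ]
        tr = Track(track_id=tid, points=pts)
        if not tr.is_monotone():
            logger.warning("%s: track %s rejected (non-monotone time)", source, tid)
            continue
        tracks.append(tr)
    return tracks, n_skipped


def parse_tracker_export(path: str | Path, calibration: CalibrationSpec | None = None,
                         individual_id: str | None = None, group: str = "Healthy",
                         tnf: bool = False) -> FieldRecording:
    """Read a Tracker-dialect export (file or directory of files).

    A directory holds one file per tracked leukocyte; a single file holds
    either one track or several distinguished by a ``track_id`` column.
    Positions are taken to be already calibrated to micrometres.  Tracks
    with non-monotone timestamps are rejected (not re-sorted) with a
    warning; malformed rows are skipped with a logged count.
    """
    path = Path(path)
    calibration = calibration or CalibrationSpec()
    tracks: list[Track] = []
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix in {".txt", ".tsv", ".csv"})
        if not files:
            raise EmptyRecordingError(f"{path}: no track files found")
        for f in files:
            trs, _ = _df_to_tracks(_read_table(f), str(f))
            tracks.extend(trs)
    else:
        trs, _ = _df_to_tracks(_read_table(path), str(path))
        tracks.extend(trs)
    if not tracks:
        raise EmptyRecordingError(f"{path}: no usable tracks")

    t_max = max(tr.times[-1] for tr in tracks)
    rec = FieldRecording(
        individual_id=individual_id or path.stem,
        group=group,
        tnf=tnf,
        duration_s=float(t_max),
        calibration=calibration,
        tracks=tracks,
    )
    for tr in rec.tracks:
        if len(tr) >= 2:
            compute_kinematics(tr)
    return rec


def write_tracker_export(rec: FieldRecording, path: str | Path) -> Path:
    """Write a recording in the Tracker dialect (single tab-separated file).

    Column layout ``track_id\\tt\\tx\\ty`` with positions printed to 6
    decimals, so a write/parse round trip reproduces point values exactly
    at that precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["track_id\tt\tx\ty"]
    for tr in rec.tracks:
        for p in tr.points:
            lines.append(f"{tr.track_id}\t{p.t:.6f}\t{p.x:.6f}\t{p.y:.6f}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    """Invariant audit of one recording (reporting only, never raises)."""

    n_tracks: int
    short_tracks: list[str]
    non_monotone_tracks: list[str]
    out_of_window_fraction: float
    out_of_range_time_tracks: list[str]
    safe_for_descriptors: bool

    @property
    def violations(self) -> int:
        return len(self.short_tracks) + len(self.non_monotone_tracks) + len(
            self.out_of_range_time_tracks
        )


def validate_recording(rec: FieldRecording) -> ValidationReport:
    """Audit a recording against the track/recording invariants.

    Checks per-track monotone time, the >= 3 point minimum needed for
    descriptor extraction, window bounds on positions, and that all
    timestamps fall within ``[0, duration_s]``.
    """
    short: list[str] = []
    nonmono: list[str] = []
    bad_time: list[str] = []
    n_points = 0
    n_out = 0
    cal = rec.calibration
    for tr in rec.tracks:
        if len(tr) < 3:
            short.append(tr.track_id)
        if not tr.is_monotone():
            nonmono.append(tr.track_id)
        ts = tr.times
        if len(ts) and (ts[0] < 0 or ts[-1] > rec.duration_s + 1e-9):
            bad_time.append(tr.track_id)
        xs, ys = tr.xs, tr.ys
        n_points += len(tr)
        n_out += int(np.sum((xs < 0) | (xs > cal.window_x_um) | (ys < 0) | (ys > cal.window_y_um)))
    frac_out = n_out / n_points if n_points else 0.0
    usable = [tr for tr in rec.tracks if len(tr) >= 3 and tr.is_monotone()]
    return ValidationReport(
        n_tracks=len(rec.tracks),
        short_tracks=short,
        non_monotone_tracks=nonmono,
        out_of_window_fraction=float(frac_out),
        out_of_range_time_tracks=bad_time,
        safe_for_descriptors=len(usable) >= 1,
    )
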