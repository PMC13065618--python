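"""Classical rolling/adhesion parameters and the novel hydrodynamic descriptors.

One recording is condensed into 3 classical parameters (rolling velocity,
rolling flux, adhesion) and 45 descriptors organised in six families:
velocity, acceleration, rolling-event, standard-deviation, interaction-
product, and count variables.

Aggregation is per-leukocyte first: each usable track (>= 3 points)
contributes its mean absolute velocity, mean signed and mean absolute
acceleration, and its positive/negative rolling-event counts; population
statistics are then taken over those per-cell summaries.  Each cell is
assigned to exactly one velocity bin (by mean |v_x|) and one acceleration
bin (by mean signed a_x); a value exactly on a bin edge belongs to the
upper bin.  A pooled per-frame-sample mode is available as a sensitivity
switch.

Velocity bins: 0-500, 500-1000, 1000-1500, 1500-inf um/s.
Acceleration bins: -inf..-5000, -5000..0, 0..5000, 5000..inf um/s^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trackio import FieldRecording, Track

logger = logging.getLogger(__name__)


class FeatureError(ValueError):
    """Raised when a recording has no usable track for descriptor extraction."""


@dataclass(frozen=True)
class BinScheme:
    """Velocity/acceleration bin edges (half-open, upper bin on ties)."""

    velocity_edges: tuple[float, ...] = (0.0, 500.0, 1000.0, 1500.0, math.inf)
    acceleration_edges: tuple[float, ...] = (-math.inf, -5000.0, 0.0, 5000.0, math.inf)

    def __post_init__(self) -> None:
        for edges in (self.velocity_edges, self.acceleration_edges):
            if len(edges) != 5 or any(b <= a for a, b in zip(edges, edges[1:])):
                raise ValueError("bin edges must be 5 strictly increasing values (4 bins)")

    @staticmethod
    def _assign(values: np.ndarray, edges: tuple[float, ...]) -> np.ndarray:
        inner = np.asarray(edges[1:-1], dtype=float)
        idx = np.searchsorted(inner, values, side="right")
        return idx

    def velocity_bin(self, values: np.ndarray) -> np.ndarray:
        return self._assign(np.asarray(values, dtype=float), self.velocity_edges)

    def acceleration_bin(self, values: np.ndarray) -> np.ndarray:
        return self._assign(np.asarray(values, dtype=float), self.acceleration_edges)


VELOCITY_BIN_TAGS = ("0_500", "500_1000", "1000_1500", "1500_inf")
ACCEL_BIN_TAGS = ("minf_m5000", "m5000_0", "0_5000", "5000_inf")

_V_PAIRS = [(i, j) for i in range(4) for j in range(i + 1, 4)]

#: canonical descriptor column order (45 novel variables)
FEATURE_COLUMNS: tuple[str, ...] = (
    "v_ave", "v_med",
    *(f"v_{t}" for t in VELOCITY_BIN_TAGS),
    "a_ave", "a_med",
    *(f"a_{t}" for t in ACCEL_BIN_TAGS),
    "ratio_v_a_ave", "ratio_v_a_med", "prod_v_a_ave", "prod_v_a_med",
    "R_pos", "R_neg", "R_ratio",
    "s_vx", "s_ax", "ratio_s_vx_s_ax", "prod_s_vx_s_ax",
    "ratio_v_ave_s_vx", "ratio_a_ave_s_ax",
    *(f"prod_v_{VELOCITY_BIN_TAGS[i]}_x_{VELOCITY_BIN_TAGS[j]}" for i, j in _V_PAIRS),
    *(f"prod_a_{ACCEL_BIN_TAGS[i]}_x_{ACCEL_BIN_TAGS[j]}" for i, j in _V_PAIRS),
    *(f"N_v_{t}" for t in VELOCITY_BIN_TAGS),
    *(f"N_a_{t}" for t in ACCEL_BIN_TAGS),
)

CLASSICAL_COLUMNS: tuple[str, ...] = ("rolling_velocity", "rolling_flux", "adhesion")

#: machine-readable column dictionary: name -> (family, units, description)
FEATURE_DICTIONARY: dict[str, tuple[str, str, str]] = {
    "v_ave": ("velocity", "um/s", "population mean of per-cell mean |v_x|"),
    "v_med": ("velocity", "um/s", "population median of per-cell mean |v_x|"),
    "a_ave": ("acceleration", "um/s^2", "population mean of per-cell mean |a_x|"),
    "a_med": ("acceleration", "um/s^2", "population median of per-cell mean signed a_x"),
    "ratio_v_a_ave": ("acceleration", "s", "v_ave / a_ave"),
    "ratio_v_a_med": ("acceleration", "s", "v_med / a_med"),
    "prod_v_a_ave": ("acceleration", "um^2/s^3", "v_ave * a_ave"),
    "prod_v_a_med": ("acceleration", "um^2/s^3", "v_med * a_med"),
    "R_pos": ("rolling", "events/cell", "mean number of positive rolling events (accelerations)"),
    "R_neg": ("rolling", "events/cell", "mean number of negative rolling events (decelerations)"),
    "R_ratio": ("rolling", "-", "R_pos / R_neg"),
    "s_vx": ("sd", "um/s", "SD (ddof 1) of per-cell mean |v_x|"),
    "s_ax": ("sd", "um/s^2", "SD (ddof 1) of per-cell mean signed a_x"),
    "ratio_s_vx_s_ax": ("sd", "s", "s_vx / s_ax"),
    "prod_s_vx_s_ax": ("sd", "um^2/s^3", "s_vx * s_ax"),
    "ratio_v_ave_s_vx": ("sd", "-", "v_ave / s_vx"),
    "ratio_a_ave_s_ax": ("sd", "-", "a_ave / s_ax"),
    "rolling_velocity": ("classical", "um/s", "mean 100-um segment crossing speed, first <=53 cells"),
    "rolling_flux": ("classical", "cells", "cells dwelling in the reference ROI beyond the minimum time"),
    "adhesion": ("classical", "cells", "stationary >=30 s cell count extrapolated to 8.77 mm^2"),
}
for _i, _tag in enumerate(VELOCITY_BIN_TAGS):
    FEATURE_DICTIONARY[f"v_{_tag}"] = (
        "velocity", "um/s", f"mean per-cell |v_x| within velocity bin {_tag} (0 if empty)")
    FEATURE_DICTIONARY[f"N_v_{_tag}"] = ("count", "cells", f"cells in velocity bin {_tag}")
for _i, _tag in enumerate(ACCEL_BIN_TAGS):
    FEATURE_DICTIONARY[f"a_{_tag}"] = (
        "acceleration", "um/s^2", f"mean per-cell signed a_x within acceleration bin {_tag} (0 if empty)")
    FEATURE_DICTIONARY[f"N_a_{_tag}"] = ("count", "cells", f"cells in acceleration bin {_tag}")
for _i, _j in _V_PAIRS:
    FEATURE_DICTIONARY[f"prod_v_{VELOCITY_BIN_TAGS[_i]}_x_{VELOCITY_BIN_TAGS[_j]}"] = (
        "interaction", "um^2/s^2",
        f"v_{VELOCITY_BIN_TAGS[_i]} * v_{VELOCITY_BIN_TAGS[_j]}")
    FEATURE_DICTIONARY[f"prod_a_{ACCEL_BIN_TAGS[_i]}_x_{ACCEL_BIN_TAGS[_j]}"] = (
        "interaction", "um^2/s^4",
        f"a_{ACCEL_BIN_TAGS[_i]} * a_{ACCEL_BIN_TAGS[_j]}")


def feature_dictionary_frame() -> pd.DataFrame:
    """Column dictionary as a tidy DataFrame (name, family, units, description)."""
    rows = [
        {"name": n, "family": f, "units": u, "description": d}
        for n, (f, u, d) in FEATURE_DICTIONARY.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rolling events


def rolling_event_counts(track: Track, epsilon_um_s: float = 0.0) -> tuple[int, int]:
    """Count positive/negative rolling events of one cell.

    A positive rolling event is a frame-to-frame velocity increase
    ``dv > epsilon`` (detachment-like acceleration); a negative event is
    ``dv < -epsilon`` (adhesion-like deceleration).  Tracks with fewer
    than 3 points have no velocity pair and return ``(0, 0)``.
    """
    if len(track) < 3:
        logger.debug("track %s too short for rolling events", track.track_id)
        return (0, 0)
    if track.velocity_series is None:
        raise FeatureError(f"track {track.track_id!r} has no kinematics; "
                           "call compute_kinematics first")
    dv = np.diff(track.velocity_series)
    n_pos = int(np.sum(dv > epsilon_um_s))
    n_neg = int(np.sum(dv < -epsilon_um_s))
    return n_pos, n_neg


# ---------------------------------------------------------------------------
# novel features


def _safe_ratio(num: float, den: float) -> float:
    if den == 0 or not np.isfinite(den):
        return float("nan")
    return num / den


def _per_cell_summaries(rec: FieldRecording, epsilon_um_s: float) -> pd.DataFrame:
    rows = []
    for tr in rec.usable_tracks(min_points=3):
        if tr.velocity_series is None or tr.acceleration_series is None:
            raise FeatureError(f"track {tr.track_id!r} lacks kinematics")
        v = tr.velocity_series
        a = tr.acceleration_series
        n_pos, n_neg = rolling_event_counts(tr, epsilon_um_s)
        rows.append({
            "track_id": tr.track_id,
            "mean_abs_v": float(np.mean(np.abs(v))),
            "mean_abs_a": float(np.mean(np.abs(a))) if len(a) else 0.0,
            "mean_signed_a": float(np.mean(a)) if len(a) else 0.0,
            "n_pos": n_pos,
            "n_neg": n_neg,
        })
    return pd.DataFrame(rows)


def novel_features(rec: FieldRecording, bins: BinScheme | None = None,
                   epsilon_um_s: float = 0.0, per_leukocyte: bool = True) -> pd.Series:
    """Compute the 45 hydrodynamic descriptors of one recording.

    Returns a Series indexed by :data:`FEATURE_COLUMNS`.  Undefined values
    (``R_ratio`` with no decelerations, SDs with a single cell, ratios
    with zero denominators) are NaN; empty bins contribute feature value 0
    while their count distinguishes emptiness.

    With ``per_leukocyte=False`` the velocity/acceleration families are
    computed on pooled per-frame samples instead of per-cell means
    (sensitivity mode; count conservation no longer refers to cells).
    """
    bins = bins or BinScheme()
    cells = _per_cell_summaries(rec, epsilon_um_s)
    if cells.empty:
        raise FeatureError(f"recording {rec.individual_id!r}: no usable track (>= 3 points)")

    if per_leukocyte:
        v_samples = cells["mean_abs_v"].to_numpy()
        a_abs_samples = cells["mean_abs_a"].to_numpy()
        a_signed_samples = cells["mean_signed_a"].to_numpy()
    else:
        v_samples = np.concatenate(
            [np.abs(tr.velocity_series) for tr in rec.usable_tracks()])
        a_all = [tr.acceleration_series for tr in rec.usable_tracks()
                 if len(tr.acceleration_series)]
        a_pool = np.concatenate(a_all) if a_all else np.empty(0)
        a_abs_samples = np.abs(a_pool)
        a_signed_samples = a_pool

    out: dict[str, float] = {}
    out["v_ave"] = float(np.mean(v_samples))
    out["v_med"] = float(np.median(v_samples))
    out["a_ave"] = float(np.mean(a_abs_samples)) if len(a_abs_samples) else 0.0
    out["a_med"] = float(np.median(a_signed_samples)) if len(a_signed_samples) else 0.0

    vbin = bins.velocity_bin(v_samples)
    abin = bins.acceleration_bin(a_signed_samples)
    for b, tag in enumerate(VELOCITY_BIN_TAGS):
        sel = v_samples[vbin == b]
        out[f"v_{tag}"] = float(np.mean(sel)) if len(sel) else 0.0
        out[f"N_v_{tag}"] = float(len(sel))
    for b, tag in enumerate(ACCEL_BIN_TAGS):
        sel = a_signed_samples[abin == b]
        out[f"a_{tag}"] = float(np.mean(sel)) if len(sel) else 0.0
        out[f"N_a_{tag}"] = float(len(sel))

    out["ratio_v_a_ave"] = _safe_ratio(out["v_ave"], out["a_ave"])
    out["ratio_v_a_med"] = _safe_ratio(out["v_med"], out["a_med"])
    out["prod_v_a_ave"] = out["v_ave"] * out["a_ave"]
    out["prod_v_a_med"] = out["v_med"] * out["a_med"]

    out["R_pos"] = float(cells["n_pos"].mean())
    out["R_neg"] = float(cells["n_neg"].mean())
    if out["R_neg"] == 0:
        logger.debug("recording %s: R_neg = 0, R_ratio undefined", rec.individual_id)
        out["R_ratio"] = float("nan")
    else:
        out["R_ratio"] = out["R_pos"] / out["R_neg"]

    out["s_vx"] = float(np.std(v_samples, ddof=1)) if len(v_samples) > 1 else float("nan")
    out["s_ax"] = (float(np.std(a_signed_samples, ddof=1))
                   if len(a_signed_samples) > 1 else float("nan"))
    out["ratio_s_vx_s_ax"] = _safe_ratio(out["s_vx"], out["s_ax"])
    out["prod_s_vx_s_ax"] = out["s_vx"] * out["s_ax"]
    out["ratio_v_ave_s_vx"] = _safe_ratio(out["v_ave"], out["s_vx"])
    out["ratio_a_ave_s_ax"] = _safe_ratio(out["a_ave"], out["s_ax"])

    for i, j in _V_PAIRS:
        out[f"prod_v_{VELOCITY_BIN_TAGS[i]}_x_{VELOCITY_BIN_TAGS[j]}"] = (
            out[f"v_{VELOCITY_BIN_TAGS[i]}"] * out[f"v_{VELOCITY_BIN_TAGS[j]}"])
        out[f"prod_a_{ACCEL_BIN_TAGS[i]}_x_{ACCEL_BIN_TAGS[j]}"] = (
            out[f"a_{ACCEL_BIN_TAGS[i]}"] * out[f"a_{ACCEL_BIN_TAGS[j]}"])

    return pd.Series(out, dtype=float).reindex(list(FEATURE_COLUMNS))


# ---------------------------------------------------------------------------
# classical parameters


@dataclass(frozen=True)
class ClassicalParams:
    """Rolling velocity (um/s), rolling flux (cells), adhesion (cells/8.77 mm^2)."""

    rolling_velocity: float
    rolling_flux: float
    adhesion: float

    def as_series(self) -> pd.Series:
        return pd.Series({
            "rolling_velocity": self.rolling_velocity,
            "rolling_flux": self.rolling_flux,
            "adhesion": self.adhesion,
        })


def _segment_crossing_time(tr: Track, x0: float, x1: float) -> tuple[float, float] | None:
    """(entry time, crossing duration) of the first upward pass over [x0, x1]."""
    t, x = tr.times, tr.xs

    def first_upcross(level: float, start_idx: int = 0) -> tuple[int, float] | None:
        for i in range(start_idx, len(x) - 1):
            if x[i] <= level < x[i + 1]:
                frac = (level - x[i]) / (x[i + 1] - x[i])
                return i, t[i] + frac * (t[i + 1] - t[i])
        return None

    a = first_upcross(x0)
    if a is None:
        return None
    b = first_upcross(x1, a[0])
    if b is None:
        return None
    return a[1], b[1] - a[1]


def _is_stationary(tr: Track, radius_um: float, min_s: float) -> tuple[float, float] | None:
    """First (x, y) anchor around which the cell stays within ``radius_um``
    for at least ``min_s``; None if the cell never does."""
    t, x, y = tr.times, tr.xs, tr.ys
    n = len(t)
    for i in range(n):
        j = i
        while j + 1 < n and math.hypot(x[j + 1] - x[i], y[j + 1] - y[i]) < radius_um:
            j += 1
        if t[j] - t[i] >= min_s:
            return float(x[i]), float(y[i])
    return None


def classical_parameters(rec: FieldRecording, segment_um: float = 100.0,
                         roi_um2: float = 100.0, min_roll_s: float = 60.0,
                         min_adhere_s: float = 30.0, n_fields: int = 10,
                         max_cells: int = 53, seed: int | None = None,
                         stationary_radius_um: float = 5.0,
                         dish_area_mm2: float = 8.77,
                         subfield_area_mm2: float | None = None) -> ClassicalParams:
    """Classical flow-chamber parameters of one recording.

    rolling velocity
        Mean of (segment length / crossing time) over the first up to
        ``max_cells`` (53) tracks that traverse a fixed 100-um segment
        centred on the flow axis; NaN (flagged) if no track crosses.
    rolling flux
        Number of distinct tracks whose cumulative dwell inside a fixed
        ``roi_um2`` region of the monolayer exceeds ``min_roll_s``
        (dwell-overlap reading of the ROI criterion).
    adhesion
        Mean count, over ``n_fields`` randomly placed sub-fields, of
        cells staying within ``stationary_radius_um`` of a point for at
        least ``min_adhere_s``, extrapolated to the dish area
        (8.77 mm^2).  Sub-fields default to the full observation window,
        in which case the placements coincide and the mean equals the
        window count.
    """
    cal = rec.calibration
    if cal.window_x_um <= 0 or cal.window_y_um <= 0:
        raise ValueError("zero-area field")
    rng = np.random.default_rng(seed)

    # --- rolling velocity over a fixed 100 um segment
    x0 = (cal.window_x_um - segment_um) / 2.0
    x1 = x0 + segment_um
    crossings = []
    for tr in rec.tracks:
        if len(tr) < 2:
            continue
        res = _segment_crossing_time(tr, x0, x1)
        if res is not None and res[1] > 0:
            crossings.append(res)
    crossings.sort(key=lambda r: r[0])
    if crossings:
        speeds = [segment_um / dur for _, dur in crossings[:max_cells]]
        rolling_velocity = float(np.mean(speeds))
    else:
        logger.warning("recording %s: no track crosses the %g um segment; "
                       "rolling velocity undefined", rec.individual_id, segment_um)
        rolling_velocity = float("nan")

    # --- rolling flux: dwell inside a fixed ROI square at the window centre
    side = math.sqrt(roi_um2)
    rx0 = cal.window_x_um / 2 - side / 2
    ry0 = cal.window_y_um / 2 - side / 2
    flux = 0
    for tr in rec.tracks:
        if len(tr) < 2:
            continue
        t, x, y = tr.times, tr.xs, tr.ys
        inside = (x >= rx0) & (x <= rx0 + side) & (y >= ry0) & (y <= ry0 + side)
        dt = np.diff(t)
        dwell = float(np.sum(dt[inside[:-1]]))
        if dwell > min_roll_s:
            flux += 1

    # --- adhesion: stationary cells per random sub-field, scaled to the dish
    anchors = []
    for tr in rec.tracks:
        if len(tr) < 2:
            continue
        anchor = _is_stationary(tr, stationary_radius_um, min_adhere_s)
        if anchor is not None:
            anchors.append(anchor)
    sub_area = subfield_area_mm2 if subfield_area_mm2 is not None else cal.field_area_mm2
    frac = min(1.0, sub_area / cal.field_area_mm2)
    sw = cal.window_x_um * math.sqrt(frac)
    sh = cal.window_y_um * math.sqrt(frac)
    counts = []
    for _ in range(n_fields):
        ox = rng.uniform(0, cal.window_x_um - sw) if sw < cal.window_x_um else 0.0
        oy = rng.uniform(0, cal.window_y_um - sh) if sh < cal.window_y_um else 0.0
        c = sum(1 for ax, ay in anchors if ox <= ax <= ox + sw and oy <= ay <= oy + sh)
        counts.append(c)
    adhesion = float(np.mean(counts)) * dish_area_mm2 / sub_area if counts else 0.0

    return ClassicalParams(rolling_velocity=rolling_velocity,
                           rolling_flux=float(flux), adhesion=adhesion)


def extract_all(rec: FieldRecording, bins: BinScheme | None = None,
                epsilon_um_s: float = 0.0, per_leukocyte: bool = True,
                seed: int | None = None, **classical_kwargs) -> pd.Series:
    """45 novel descriptors + 3 classical parameters of one recording."""
    feats = novel_features(rec, bins=bins, epsilon_um_s=epsilon_um_s,
                           per_leukocyte=per_leukocyte)
    classical = classical_parameters(rec, seed=seed, **classical_kwargs).as_series()
    return pd.concat([feats, classical])
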