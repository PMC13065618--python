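"""Seeded synthetic flow-chamber cohorts with the structure the analysis assumes.

Leukocytes enter the 600 x 480 um observation window at Poisson times and
evolve through a three-state Markov chain::

    free flow --capture--> rolling  --arrest-->  arrested
                           rolling <--release--  arrested

Per frame, the x increment is drawn from the current state's speed
distribution (free flow ~10^3 um/s, rolling 10-10^2 um/s, arrest 0); while
rolling, "jerk" events inject sign-alternating velocity steps emulating
the transient accelerations/decelerations of adhesion-molecule engagement.
A track ends when the cell leaves the window or the 5-min recording ends.

Group presets encode the qualitative contrasts the descriptors are
designed to detect (healthy = fast rolling / low arrest, T1D = slow jerky
rolling, T2D = moderate rolling / frequent arrest); TNF-alpha activation
slows rolling and doubles arrest.  All values are scenario parameters, not
estimates of any clinical dataset.

Biomarker columns are generated per individual by a Gaussian-copula
construction with a controllable target correlation to a named descriptor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .descriptors import BinScheme, extract_all
from .trackio import CalibrationSpec, FieldRecording, Track, TrackPoint, compute_kinematics

logger = logging.getLogger(__name__)

FREE, ROLLING, ARRESTED = 0, 1, 2

CONDITIONS: tuple[tuple[str, bool], ...] = (
    ("Healthy", False), ("Healthy", True),
    ("T1D", False), ("T1D", True),
    ("T2D", False), ("T2D", True),
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class GroupKinetics:
    """State kinetics of one study condition.

    Rates are per second and converted by the frame interval; speeds in
    um/s.  ``capture_rate`` governs the free-flow -> rolling transition,
    ``arrest_rate`` rolling -> arrest, ``release_rate`` arrest -> rolling.
    ``jerk_rate`` is the expected number of jerk events per second while
    rolling, each adding a velocity step of ``jerk_amplitude_um_s`` with
    alternating sign.
    """

    free_flow_speed_mean: float = 1000.0
    free_flow_speed_sd: float = 150.0
    rolling_speed_mean: float = 400.0
    rolling_speed_sd: float = 80.0
    jerk_rate: float = 1.0
    jerk_amplitude_um_s: float = 150.0
    capture_rate: float = 2.0
    arrest_rate: float = 0.05
    release_rate: float = 0.1
    entry_rate: float = 0.3

    def __post_init__(self) -> None:
        rates = ("jerk_rate", "capture_rate", "arrest_rate", "release_rate", "entry_rate")
        if any(getattr(self, r) < 0 for r in rates):
            raise ConfigError("rates must be >= 0")
        if self.free_flow_speed_mean <= 0 or self.rolling_speed_mean <= 0:
            raise ConfigError("speed means must be > 0")
        if self.rolling_speed_mean >= self.free_flow_speed_mean:
            raise ConfigError("rolling speed mean must be below free-flow speed mean")


#: default per-condition kinetics mirroring the qualitative group contrasts
GROUP_PRESETS: dict[tuple[str, bool], GroupKinetics] = {
    ("Healthy", False): GroupKinetics(rolling_speed_mean=600.0, rolling_speed_sd=80.0,
                                      jerk_rate=1.0, arrest_rate=0.02, release_rate=0.10),
    ("Healthy", True): GroupKinetics(rolling_speed_mean=380.0, rolling_speed_sd=80.0,
                                     jerk_rate=1.8, arrest_rate=0.06, release_rate=0.08),
    ("T1D", False): GroupKinetics(rolling_speed_mean=200.0, rolling_speed_sd=60.0,
                                  jerk_rate=4.0, arrest_rate=0.05, release_rate=0.05),
    ("T1D", True): GroupKinetics(rolling_speed_mean=150.0, rolling_speed_sd=50.0,
                                 jerk_rate=5.0, arrest_rate=0.10, release_rate=0.04),
    ("T2D", False): GroupKinetics(rolling_speed_mean=400.0, rolling_speed_sd=70.0,
                                  jerk_rate=2.0, arrest_rate=0.15, release_rate=0.02),
    ("T2D", True): GroupKinetics(rolling_speed_mean=300.0, rolling_speed_sd=70.0,
                                 jerk_rate=2.5, arrest_rate=0.30, release_rate=0.015),
}


@dataclass(frozen=True)
class BiomarkerSpec:
    """One circulating-biomarker column: Gaussian copula against a descriptor."""

    name: str
    mean: float | dict[str, float]
    sd: float
    rho: float
    descriptor: str

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ConfigError("|target correlation| must be < 1")
        if self.sd <= 0:
            raise ConfigError("biomarker sd must be > 0")


@dataclass
class SimulationConfig:
    """Cohort design: six conditions x ``n_per_group`` individuals, 5-min fields."""

    group_kinetics: dict[tuple[str, bool], GroupKinetics] = field(
        default_factory=lambda: dict(GROUP_PRESETS))
    conditions: tuple[tuple[str, bool], ...] = CONDITIONS
    n_per_group: int = 10
    duration_s: float = 300.0
    frame_interval_s: float = 0.033
    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)
    biomarker_spec: list[BiomarkerSpec] = field(default_factory=list)
    bins: BinScheme = field(default_factory=BinScheme)
    epsilon_um_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        if self.duration_s <= 0 or self.frame_interval_s <= 0:
            raise ConfigError("duration and frame interval must be > 0")
        for cond in self.conditions:
            if cond not in self.group_kinetics:
                raise ConfigError(f"no kinetics for condition {cond}")


# ---------------------------------------------------------------------------
# single-recording simulation


def _geometric_frames(rng: np.random.Generator, p: float, cap: int) -> int:
    """Frames spent in a state before the next transition (>= 1), capped."""
    if p <= 0:
        return cap
    if p >= 1:
        return 1
    return min(int(rng.geometric(p)), cap)


def _simulate_cell(rng: np.random.Generator, kin: GroupKinetics, entry_frame: int,
                   n_frames: int, dt: float, window_x: float, window_y: float,
                   track_id: str) -> tuple[Track, np.ndarray] | None:
    """One cell's trajectory from entry until window exit or recording end."""
    y0 = rng.uniform(0.05 * window_y, 0.95 * window_y)
    state = FREE
    jerk_sign = 1.0
    vs: list[np.ndarray] = []
    states: list[np.ndarray] = []
    remaining = n_frames - entry_frame
    trans_p = {FREE: kin.capture_rate * dt, ROLLING: kin.arrest_rate * dt,
               ARRESTED: kin.release_rate * dt}
    while remaining > 0:
        m = _geometric_frames(rng, trans_p[state], remaining)
        if state == FREE:
            seg = rng.normal(kin.free_flow_speed_mean, kin.free_flow_speed_sd, m)
        elif state == ROLLING:
            seg = rng.normal(kin.rolling_speed_mean, kin.rolling_speed_sd, m)
            if kin.jerk_rate > 0:
                hits = np.nonzero(rng.random(m) < kin.jerk_rate * dt)[0]
                for h in hits:
                    seg[h] += jerk_sign * kin.jerk_amplitude_um_s
                    jerk_sign = -jerk_sign
        else:
            seg = np.zeros(m)
        vs.append(seg)
        states.append(np.full(m, state))
        remaining -= m
        if remaining <= 0:
            break
        state = {FREE: ROLLING, ROLLING: ARRESTED, ARRESTED: ROLLING}[state]

    v = np.concatenate(vs) if vs else np.empty(0)
    st = np.concatenate(states) if states else np.empty(0, dtype=int)
    x = np.concatenate([[0.0], np.cumsum(v * dt)])
    # truncate at window exit: keep points with x <= window_x
    exit_idx = np.argmax(x > window_x) if np.any(x > window_x) else len(x)
    x = x[:exit_idx]
    if len(x) < 2:
        return None
    st = st[:len(x) - 1]
    t = (entry_frame + np.arange(len(x))) * dt
    pts = [TrackPoint(t=float(ti), x=float(xi), y=float(y0)) for ti, xi in zip(t, x)]
    return Track(track_id=track_id, points=pts), st


def simulate_recording(kinetics: GroupKinetics, duration_s: float = 300.0,
                       frame_interval_s: float = 0.033, seed: int | None = 0,
                       calibration: CalibrationSpec | None = None,
                       individual_id: str = "sim", group: str = "Healthy",
                       tnf: bool = False,
                       return_states: bool = False):
    """Simulate one 5-min field recording under the given state kinetics.

    Identical ``seed`` gives an identical recording.  With
    ``return_states=True`` also returns ``{track_id: per-interval state
    codes}`` (0 free flow, 1 rolling, 2 arrested) for occupancy checks.
    """
    if duration_s <= 0 or frame_interval_s <= 0:
        raise ConfigError("duration and frame interval must be > 0")
    calibration = calibration or CalibrationSpec(frame_interval_s=frame_interval_s)
    rng = np.random.default_rng(seed)
    dt = frame_interval_s
    n_frames = int(round(duration_s / dt))
    n_cells = rng.poisson(kinetics.entry_rate * duration_s)
    entry_frames = np.sort(rng.integers(0, max(1, n_frames - 2), size=n_cells))

    tracks: list[Track] = []
    states: dict[str, np.ndarray] = {}
    for k, ef in enumerate(entry_frames):
        res = _simulate_cell(rng, kinetics, int(ef), n_frames, dt,
                             calibration.window_x_um, calibration.window_y_um,
                             track_id=f"{individual_id}_c{k:04d}")
        if res is None:
            continue
        tr, st = res
        compute_kinematics(tr)
        tracks.append(tr)
        states[tr.track_id] = st
    rec = FieldRecording(individual_id=individual_id, group=group, tnf=tnf,
                         duration_s=duration_s, calibration=calibration, tracks=tracks)
    if return_states:
        return rec, states
    return rec


# ---------------------------------------------------------------------------
# cohort simulation


def _condition_tag(group: str, tnf: bool) -> str:
    return f"{group}{'+TNF' if tnf else ''}"


def simulate_cohort(config: SimulationConfig,
                    return_recordings: bool = False):
    """Simulate a full cohort and assemble the individuals x features table.

    One recording per individual per condition; descriptors extracted per
    recording; biomarkers added at the individual level by the Gaussian-
    copula construction ``b = rho * z(descriptor) + sqrt(1 - rho^2) * eps``
    rescaled to the stated mean/sd.  Returns the cohort DataFrame (and the
    recordings when ``return_recordings=True``).
    """
    from .descriptors import CLASSICAL_COLUMNS, FEATURE_COLUMNS

    known = set(FEATURE_COLUMNS) | set(CLASSICAL_COLUMNS)
    for spec in config.biomarker_spec:
        if spec.descriptor not in known:
            raise ConfigError(f"unknown descriptor {spec.descriptor!r} in biomarker_spec")

    ss = np.random.SeedSequence(config.seed)
    rows = []
    recordings: dict[tuple[str, bool, int], FieldRecording] = {}
    for group, tnf in config.conditions:
        kin = config.group_kinetics[(group, tnf)]
        for i in range(config.n_per_group):
            child = ss.spawn(1)[0]
            rec_seed = int(child.generate_state(1)[0] % (2**31))
            iid = f"{group[:2]}{i:02d}"
            rec = simulate_recording(
                kin, duration_s=config.duration_s,
                frame_interval_s=config.frame_interval_s, seed=rec_seed,
                calibration=config.calibration, individual_id=iid,
                group=group, tnf=tnf)
            feats = extract_all(rec, bins=config.bins,
                                epsilon_um_s=config.epsilon_um_s, seed=rec_seed)
            row = {"individual_id": iid, "group": group, "tnf": tnf}
            row.update(feats.to_dict())
            rows.append(row)
            if return_recordings:
                recordings[(group, tnf, i)] = rec
    table = pd.DataFrame(rows)
    meta = ["individual_id", "group", "tnf"]
    table = table[meta + list(FEATURE_COLUMNS) + list(CLASSICAL_COLUMNS)]

    if config.biomarker_spec:
        rng = np.random.default_rng(ss.spawn(1)[0])
        for spec in config.biomarker_spec:
            if spec.descriptor not in table.columns:
                raise ConfigError(f"unknown descriptor {spec.descriptor!r} in biomarker_spec")
            col = table[spec.descriptor].to_numpy(dtype=float)
            col = np.where(np.isfinite(col), col, np.nanmean(col))
            sd = np.std(col, ddof=1)
            z = (col - np.mean(col)) / sd if sd > 0 else np.zeros_like(col)
            eps = rng.standard_normal(len(table))
            raw = spec.rho * z + math.sqrt(1 - spec.rho**2) * eps
            if isinstance(spec.mean, dict):
                mean = table["group"].map(spec.mean).to_numpy(dtype=float)
            else:
                mean = spec.mean
            table[spec.name] = mean + spec.sd * raw

    if return_recordings:
        return table, recordings
    return table


# ---------------------------------------------------------------------------
# optional video-loop closure: render frames and re-track


def render_and_track(rec: FieldRecording, noise_sd: float = 0.0,
                     psf_sigma_um: float = 3.0, seed: int | None = 0,
                     um_per_px: float = 2.0, gate_um: float | None = None,
                     amplitude: float = 1.0) -> FieldRecording:
    """Render a recording as Gaussian blobs on noisy frames and re-track it.

    Cells are painted as point-spread Gaussians, local maxima re-detected
    per frame and linked by nearest neighbour within a gate distance.
    With zero noise and well-separated cells the re-tracked positions
    match the input to better than one pixel.  Linking ambiguities (two
    candidates within the gate) are logged.
    """
    from scipy.ndimage import gaussian_filter
    from skimage.feature import peak_local_max

    cal = rec.calibration
    dt = cal.frame_interval_s
    rng = np.random.default_rng(seed)
    w = int(round(cal.window_x_um / um_per_px))
    h = int(round(cal.window_y_um / um_per_px))
    sigma_px = psf_sigma_um / um_per_px
    n_frames = int(round(rec.duration_s / dt)) + 1
    if gate_um is None:
        gate_um = 60.0

    # index input positions by frame
    frame_pos: dict[int, list[tuple[float, float]]] = {}
    max_disp = 0.0
    for tr in rec.tracks:
        t, x, y = tr.times, tr.xs, tr.ys
        if len(t) > 1:
            max_disp = max(max_disp, float(np.max(np.hypot(np.diff(x), np.diff(y)))))
        for ti, xi, yi in zip(t, x, y):
            f = int(round(ti / dt))
            frame_pos.setdefault(f, []).append((xi, yi))
    if max_disp > gate_um:
        logger.warning("gate %.1f um below max per-frame displacement %.1f um; "
                       "tracks will break", gate_um, max_disp)

    norm = 2 * math.pi * sigma_px**2  # impulse -> unit-peak blob after blur

    tracklets: list[dict] = []  # {"points": [(f,x,y)], "open": bool}
    n_ambiguous = 0
    for f in range(n_frames):
        img = np.zeros((h, w))
        for xi, yi in frame_pos.get(f, []):
            px = int(round(xi / um_per_px))
            py = int(round(yi / um_per_px))
            if 0 <= px < w and 0 <= py < h:
                img[py, px] += norm * amplitude
        img = gaussian_filter(img, sigma_px)
        if noise_sd > 0:
            img = img + rng.normal(0, noise_sd, size=img.shape)
        peaks = peak_local_max(img, min_distance=max(1, int(sigma_px)),
                               threshold_abs=0.3 * amplitude)
        dets = [(float(c * um_per_px), float(r * um_per_px)) for r, c in peaks]

        heads = [tl for tl in tracklets if tl["open"] and tl["points"][-1][0] == f - 1]
        used = set()
        for tl in heads:
            _, hx, hy = tl["points"][-1]
            cands = [(math.hypot(dx - hx, dy - hy), k) for k, (dx, dy) in enumerate(dets)
                     if k not in used and math.hypot(dx - hx, dy - hy) <= gate_um]
            if not cands:
                tl["open"] = False
                continue
            cands.sort()
            if len(cands) > 1 and cands[1][0] <= gate_um:
                n_ambiguous += 1
            d, k = cands[0]
            used.add(k)
            tl["points"].append((f, *dets[k]))
        for k, (dx, dy) in enumerate(dets):
            if k not in used:
                tracklets.append({"points": [(f, dx, dy)], "open": True})

    if n_ambiguous:
        logger.warning("%d linking ambiguities encountered", n_ambiguous)

    tracks = []
    for k, tl in enumerate(tracklets):
        pts = [TrackPoint(t=f * dt, x=x, y=y) for f, x, y in tl["points"]]
        if len(pts) < 2:
            continue
        tr = Track(track_id=f"retrack_{k:04d}", points=pts)
        compute_kinematics(tr)
        tracks.append(tr)
    return FieldRecording(individual_id=rec.individual_id + "_retracked",
                          group=rec.group, tnf=rec.tnf, duration_s=rec.duration_s,
                          calibration=cal, tracks=tracks)
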