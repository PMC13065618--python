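import numpy as np
import pytest

from leukoflow.trackio import CalibrationSpec, FieldRecording, Track, TrackPoint, \
    compute_kinematics


def make_track(track_id, ts, xs, ys=None, kinematics=True):
    ys = ys if ys is not None else [240.0] * len(ts)
    tr = Track(track_id=track_id,
               points=[TrackPoint(t=float(t), x=float(x), y=float(y))
                       for t, x, y in zip(ts, xs, ys)])
    if kinematics and len(tr) >= 2:
        compute_kinematics(tr)
    return tr


def track_from_velocities(track_id, velocities, dt=0.125, x0=0.0):
    # dt is binary-exact so constructed velocity series are reproduced exactly
    """Track whose forward-difference velocity series equals `velocities`."""
    xs = [x0]
    for v in velocities:
        xs.append(xs[-1] + v * dt)
    ts = [i * dt for i in range(len(xs))]
    return make_track(track_id, ts, xs)


def make_recording(tracks, duration_s=None, group="Healthy", tnf=False,
                   individual_id="rec"):
    duration = duration_s or max(tr.times[-1] for tr in tracks)
    return FieldRecording(individual_id=individual_id, group=group, tnf=tnf,
                          duration_s=float(duration),
                          calibration=CalibrationSpec(), tracks=list(tracks))


@pytest.fixture
def simulated_recording():
    """Moderate-size simulated recording with all three motion regimes."""
    from leukoflow.synthetic import GroupKinetics, simulate_recording

    kin = GroupKinetics(rolling_speed_mean=300.0, rolling_speed_sd=80.0,
                        jerk_rate=3.0, arrest_rate=0.08, release_rate=0.05,
                        entry_rate=1.5)
    return simulate_recording(kin, duration_s=120.0, seed=7,
                              individual_id="fix", group="T1D")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
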