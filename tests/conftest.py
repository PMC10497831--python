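import numpy as np
import pandas as pd
import pytest

from dgspace import (
    PositionTrack,
    Session,
    SessionMeta,
    TraceSet,
    generate_cell_traces,
    generate_track,
    young_defaults,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


def make_track(position, time=None, belt_length=180.0):
    position = np.asarray(position, dtype=float)
    if time is None:
        time = np.arange(position.size, dtype=float)
    return PositionTrack.from_position(position, time, belt_length)


def constant_speed_track(
    speed_cm_s=20.0, n_frames=900, frame_rate=10.0, belt_length=180.0
):
    dt = 1.0 / frame_rate
    time = np.arange(n_frames) * dt
    position = np.mod(speed_cm_s * time, belt_length)
    return PositionTrack.from_position(position, time, belt_length)


@pytest.fixture
def small_session():
    """Deterministic 60 s, 6-cell synthetic session with events."""
    params = young_defaults(session_length=60.0, cells_per_mouse=6, pause_prob=0.2)
    gen = np.random.default_rng(7)
    track = generate_track(params, gen)
    truth = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(6)],
            "preferred_cm": [15.0, 60.0, 100.0, 140.0, 170.0, 30.0],
            "kappa": [4.0, 4.0, 0.0, 8.0, 2.0, 0.0],
        }
    )
    traces = generate_cell_traces(track, truth, params, gen)
    meta = SessionMeta(
        mouse_id="m1",
        group="young",
        day=1,
        frame_rate=params.frame_rate,
        belt_length=params.belt_length,
        n_frames=track.n_frames,
        n_cells=6,
    )
    session = Session(meta=meta, track=track, traces=traces)
    session.validate()
    return session
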