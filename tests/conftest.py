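import numpy as np
import pytest

from swgaze.scene import build_default_scene, enumerate_conditions
from swgaze.simulate import (
    GazeEventParams,
    simulate_gaze,
    simulate_trial,
    simulate_walkers,
)


@pytest.fixture(scope="session")
def layout():
    return build_default_scene()


@pytest.fixture(scope="session")
def condition():
    # Left gate, row 1 entering from the left, sitters on both sides.
    return enumerate_conditions(1)[0]


@pytest.fixture(scope="session")
def trial_log(layout, condition):
    """One fully simulated walking trial (seed-fixed, shared read-only)."""
    return simulate_trial(layout, condition, seed=3, trial_id="trial_fixture")


@pytest.fixture(scope="session")
def fixed_head_stream(layout, condition):
    """A 30 s head-fixed gaze stream with ground truth at default noise."""
    fs = 80.0
    n = int(30 * fs)
    t = np.arange(n) / fs
    head = np.tile([0.0, 1.6, 0.0], (n, 1))
    tracks = simulate_walkers(layout, condition, 30.0)
    gaze = simulate_gaze(
        t, head, layout, tracks, condition, seed=11, params=GazeEventParams()
    )
    return {"t": t, "head": head, "tracks": tracks, "gaze": gaze, "fs": fs}
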