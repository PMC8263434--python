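import numpy as np
import pytest

from lapmotion import SGConfig, sg_smooth
from lapmotion.io import InstrumentTrack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(pos, fs=100.0, **kw):
    """Build a minimal InstrumentTrack from an (n, 3) position array."""
    pos = np.asarray(pos, float)
    t = np.arange(pos.shape[0]) / fs
    return InstrumentTrack(
        instrument_id=kw.pop("instrument_id", "scissors"),
        hand=kw.pop("hand", "right"),
        t=t,
        pos=pos,
        **kw,
    )


def smooth_random_walk(rng, n=1500, fs=100.0, step=0.05):
    """Random walk smoothed enough to be a plausible tip trajectory."""
    steps = rng.normal(0.0, step, size=(n, 3))
    pos = np.cumsum(steps, axis=0)
    # mild low-pass so SG smoothing does not erase the path
    kernel = np.ones(9) / 9.0
    pos = np.column_stack([np.convolve(pos[:, k], kernel, mode="same") for k in range(3)])
    return make_track(pos, fs=fs)


@pytest.fixture
def straight_series():
    """10 cm straight line at constant 2 cm/s, 100 Hz (5 s + margins)."""
    t = np.arange(0, 6.0, 0.01)
    pos = np.column_stack([2.0 * t, np.zeros_like(t), np.zeros_like(t)])
    return sg_smooth(pos, SGConfig(), t=t)
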