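import numpy as np
import pytest

from burstkit.detection import Burst, SpikeRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(spikes: dict, duration: float | None = None, **kw) -> SpikeRecording:
    """Small helper: build a recording, inferring duration from the data."""
    arrays = {k: np.asarray(v, dtype=float) for k, v in spikes.items()}
    if duration is None:
        duration = max((float(t[-1]) for t in arrays.values() if t.size), default=1.0) + 1.0
    return SpikeRecording(spikes=arrays, duration=duration, **kw)


def make_burst(start: float, end: float, counts: dict | None = None) -> Burst:
    return Burst(start, end, counts or {"ch0": 1})
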