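import numpy as np
import pytest

from todsense import ReporterTrace


@pytest.fixture
def make_trace():
    """Factory for uniform traces from an arbitrary value function of time."""

    def _make(fn, duration=120.0, dt=1.0 / 6.0, sample_id="t", channel="Bmal1"):
        n = int(round(duration / dt)) + 1
        t = np.arange(n) * dt
        return ReporterTrace(
            sample_id=sample_id, cell_model="m", channel=channel,
            times=t, values=np.asarray(fn(t), dtype=float) + np.zeros(n), dt=dt,
        )

    return _make


@pytest.fixture
def cosine_trace(make_trace):
    """Unit-amplitude 24-h cosine, 120 h at 10-min sampling."""
    return make_trace(lambda t: np.cos(2 * np.pi * t / 24.0))
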