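import numpy as np
import pytest

from swbold.types import CalciumTrace


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trace(values, fs_hz=1000.0, units="dff"):
    return CalciumTrace(values=np.asarray(values, dtype=float), fs_hz=fs_hz,
                        units=units)


def rectangular_pulse_trace(fs=1000.0, duration_s=10.0,
                            pulses=((1.0, 1.0), (4.0, 1.0), (7.0, 1.0)),
                            amplitude=1.0):
    """Noiseless trace of rectangular pulses (onset_s, width_s)."""
    n = int(duration_s * fs)
    v = np.zeros(n)
    for onset, width in pulses:
        v[int(onset * fs): int((onset + width) * fs)] = amplitude
    return make_trace(v, fs)
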