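import numpy as np
import pytest

from masksignal import BreathingModel, ScenarioScript, Segment, simulate_session


@pytest.fixture
def street_script():
    """A 2-minute flat street segment at 10 Hz."""
    return ScenarioScript(
        segments=[Segment("street", 120.0, ambient_temp=0.0, ambient_aqi=60.0)]
    )


@pytest.fixture
def short_session(street_script):
    """Default-breathing 2-minute session, fixed seed."""
    return simulate_session(street_script, BreathingModel(rate=12.0), seed=1)


def make_sine(rate_bpm: float, duration_s: float, fs: float = 10.0, amp: float = 1.0):
    """Clean breath-like sinusoid starting at a trough, so mean-crossings in
    the rising direction occur exactly rate*duration/60 times."""
    t = np.arange(0.0, duration_s, 1.0 / fs)
    return t, -amp * np.cos(2.0 * np.pi * rate_bpm / 60.0 * t)
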