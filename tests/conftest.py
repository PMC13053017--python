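import numpy as np
import pytest

from promkin.io_formats import SyllableInterval, UtteranceRecording
from promkin.synth import default_items


@pytest.fixture(scope="session")
def items():
    return default_items()


@pytest.fixture(scope="session")
def mismatch_item(items):
    # a profesor-like item: 3 syllables, competitor (idx 1) precedes target (idx 2)
    for it in items:
        if it.n_syll == 3 and it.competitor_idx == 1 and it.target_idx == 2:
            return it
    raise AssertionError("default item table lacks a (3, 2, 1) item")


def make_recording(waveform, sr=16000.0, bounds=(0.0, 0.2, 0.5, 0.9), **kw):
    """Wrap a waveform with evenly specified syllable boundaries."""
    syls = [
        SyllableInterval(a, b, f"syl{i}")
        for i, (a, b) in enumerate(zip(bounds, bounds[1:]))
    ]
    return UtteranceRecording(np.asarray(waveform, float), sr, syls, **kw)


@pytest.fixture
def tone_recording():
    """1 s of a 200 Hz sinusoid at amplitude 0.5, three syllables."""
    sr = 16000.0
    t = np.arange(int(sr)) / sr
    return make_recording(0.5 * np.sin(2 * np.pi * 200.0 * t), sr)
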