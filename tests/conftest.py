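import numpy as np
import pytest

from bulbulvox import AudioSignal, StftConfig, MelConfig
from bulbulvox.synthetic_fixtures import default_repertoire


@pytest.fixture(scope="session")
def repertoire():
    """Seeded default repertoire: 22 syllable templates, 13 word templates."""
    return default_repertoire(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tone(freq: float, duration: float = 0.5, rate: float = 44100.0,
         amplitude: float = 1.0, phase: float = 0.0) -> AudioSignal:
    t = np.arange(int(duration * rate)) / rate
    return AudioSignal(amplitude * np.sin(2 * np.pi * freq * t + phase), rate, f"tone{freq}")


def chirp(f0: float, f1: float, duration: float = 0.5, rate: float = 11025.0) -> AudioSignal:
    """Linear chirp; instantaneous frequency runs f0 -> f1."""
    t = np.arange(int(duration * rate)) / rate
    phase = 2 * np.pi * (f0 * t + (f1 - f0) / (2 * duration) * t ** 2)
    return AudioSignal(np.sin(phase), rate, "chirp")
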