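import numpy as np
import pytest

from robustmark.audio import Waveform


def harmonic(duration: float, f0: float = 140.0, amp: float = 0.1,
             rate: int = 16000, n_harmonics: int = 8) -> np.ndarray:
    """Pulse-train-like harmonic signal with 1/k roll-off."""
    t = np.arange(int(rate * duration)) / rate
    return amp * sum(
        np.sin(2 * np.pi * f0 * k * t) / k for k in range(1, n_harmonics + 1)
    )


@pytest.fixture
def speech_pause_speech() -> Waveform:
    """Known layout: speech [0,2), pause [2,3), speech [3,5)."""
    rate = 16000
    y = np.concatenate([harmonic(2.0), np.zeros(rate), harmonic(2.0)])
    return Waveform(y, rate)


@pytest.fixture
def constant_tone() -> Waveform:
    return Waveform(harmonic(1.0, f0=150.0), 16000)
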