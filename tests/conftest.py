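import numpy as np
import pytest

import spikecoch as sc


@pytest.fixture(scope="session")
def tone():
    """Factory for pure tones: tone(freq_hz, fs=16000, duration=1.0, amp=0.1)."""

    def _tone(freq, fs=16000.0, duration=1.0, amp=0.1):
        t = np.arange(int(round(duration * fs))) / fs
        return sc.AudioSignal(amp * np.sin(2 * np.pi * freq * t), fs)

    return _tone


@pytest.fixture(scope="session")
def vowel_token():
    """A fixed formant token used across tests (0.5 s, 16 kHz)."""
    spec = sc.TokenSpec(
        "a",
        120.0,
        (
            sc.FormantTrack(500.0, 520.0, 80.0),
            sc.FormantTrack(1500.0, 1450.0, 110.0),
            sc.FormantTrack(2600.0, 2600.0, 180.0),
        ),
        duration=0.5,
        seed=3,
    )
    return sc.synth_token(spec)


@pytest.fixture(scope="session")
def small_class_set():
    """4 classes x 4 exemplars of synthetic digit-like tokens."""
    return sc.make_class_set(4, 4, seed=7)


@pytest.fixture(scope="session")
def babble():
    return sc.babble_noise(2.0, n_talkers=8, seed=17)
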