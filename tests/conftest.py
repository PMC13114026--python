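import numpy as np
import pytest

from sevoeeg import ConcentrationProtocol, EEGRecording, default_mouse_montage


@pytest.fixture
def montage():
    return default_mouse_montage()


@pytest.fixture
def short_protocol():
    """5 steps of 60 s each, 2.0 -> 2.8 vol%."""
    return ConcentrationProtocol.stepped(step_duration_s=60.0)


@pytest.fixture
def full_protocol():
    """The study protocol: 5 steps of 300 s."""
    return ConcentrationProtocol.stepped()


def make_recording(samples, fs=500.0, labels=None, unit="mV"):
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if labels is None:
        labels = ["F1", "F2", "C1", "C2", "P1", "P2"][: samples.shape[0]]
    return EEGRecording(samples=samples, fs=fs, channel_labels=labels, unit=unit)


@pytest.fixture
def six_channel_recording():
    """60 s of structured six-channel signal at fs=500."""
    rng = np.random.default_rng(7)
    t = np.arange(30000) / 500.0
    samples = np.stack(
        [
            (3 + i) * np.sin(2 * np.pi * (5 + i) * t) + 0.3 * rng.standard_normal(t.size)
            for i in range(6)
        ]
    )
    return make_recording(samples)
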