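import numpy as np
import pytest

from neoburst import (
    DEFAULT_CHANNELS,
    EEGRecording,
    SimulationConfig,
    generate_recording,
)


@pytest.fixture(scope="session")
def short_sim():
    """5-minute synthetic recording with default burst structure."""
    cfg = SimulationConfig(duration=300.0, seed=42)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def quiet_recording():
    """60 s of plain filtered Gaussian background (no bursts)."""
    cfg = SimulationConfig(duration=60.0, burst_amplitude=0.0, seed=7)
    return generate_recording(cfg).recording


def make_recording(signal, fs=250.0, labels=None):
    signal = np.atleast_2d(np.asarray(signal, float))
    labels = labels or [DEFAULT_CHANNELS[i] for i in range(signal.shape[0])]
    return EEGRecording(signal, labels, fs)
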