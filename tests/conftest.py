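import numpy as np
import pytest

from eegnda.synthdata import EEGRecording, EventTimeline, SynthConfig, generate_eeg


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A short but fully featured synthetic recording configuration."""
    return SynthConfig(
        n_channels=8,
        duration=40.0,
        n_trials_per_class=4,
        lead_time=0.1,
        lag_time=0.1,
        snr=1.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate_eeg(small_config)


@pytest.fixture()
def toy_recording():
    """Deterministic 4-channel recording with a hand-built timeline."""
    rng = np.random.default_rng(7)
    n = 5000
    data = rng.standard_normal((4, n))
    triggers = np.zeros((6, n), dtype=np.int8)
    # one run per class, 150 samples each, spread over the recording
    for c in range(6):
        start = 400 + c * 700
        triggers[c, start : start + 150] = 1
    return EEGRecording(data, 500.0), EventTimeline(triggers)
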