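import numpy as np
import pytest

from preictal import Annotation, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(n_channels=3, fs=256.0, duration_s=10.0, seed=0,
                   annotations=(), subject_id="fixture"):
    """Small random recording with realistic microvolt amplitudes."""
    r = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    data = 30.0 * r.standard_normal((n_channels, n))
    return Recording(
        data=data,
        fs=fs,
        channel_labels=[f"EEG{i}" for i in range(n_channels)],
        annotations=list(annotations),
        subject_id=subject_id,
    )


@pytest.fixture
def recording():
    return make_recording()


def seizure(onset, duration=0.0):
    return Annotation(onset, duration, "seizure")
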