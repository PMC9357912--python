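import numpy as np
import pytest

from hrvstress.synth import SynthConfig, simulate_record


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free 5-minute synthetic ECG with ground-truth annotations."""
    return simulate_record(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def short_clean_record():
    """Noise-free 60 s synthetic ECG for fast unit tests."""
    return simulate_record(SynthConfig(seed=3, duration=60.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
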