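import numpy as np
import pytest

from fosemg.core import GridSpec, ProtocolSpec


@pytest.fixture
def grid():
    return GridSpec()


@pytest.fixture
def protocol():
    return ProtocolSpec()


@pytest.fixture
def short_protocol():
    """A 1.5 s trial: long enough for the envelope filter, fast for tests."""
    return ProtocolSpec(trial_duration=1.5, ramp_duration=0.75)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def smooth_positive_signal(rng: np.random.Generator, n: int) -> np.ndarray:
    """A smooth nonnegative signal in [0, 1] for pool/fit tests."""
    from fosemg.preprocess import lowpass_envelope, normalize_to_max

    x = np.abs(lowpass_envelope(rng.standard_normal(n), 1000.0, cutoff=3.0))
    return normalize_to_max(x + 1e-3)
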