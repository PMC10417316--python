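import numpy as np
import pytest

from ppgbp import SyntheticConfig, record_to_segments, synth_record


@pytest.fixture(scope="session")
def clean_record():
    """Noise-, drift-, and corruption-free record with ground-truth beats."""
    return synth_record(
        SyntheticConfig(
            duration=60.0,
            noise_sd=0.0,
            abp_noise_sd=0.0,
            drift_amplitude=0.0,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def noisy_record():
    """Record under the default study conditions (noise + drift)."""
    return synth_record(SyntheticConfig(duration=60.0, seed=7))


@pytest.fixture(scope="session")
def small_segments(noisy_record):
    return record_to_segments(noisy_record)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
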