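import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from jurysense.synthetic import SyntheticSessionSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """Reduced session (4 sounds, short segments) for fast pipeline tests."""
    return SyntheticSessionSpec(
        n_sounds=4, segment_duration=5.0, gap=0.5, seed=42
    )


@pytest.fixture
def clean_spec():
    """Noise-free, fully attentive, perfectly consistent conditions."""
    return SyntheticSessionSpec(
        n_sounds=4,
        segment_duration=5.0,
        gap=0.5,
        emotion_noise_sd=0.0,
        inattentive_noise_sd=0.0,
        p_consistent=1.0,
        attention_rates=(1.0, 1.0, 1.0),
        blink_rate=0.0,
        seed=42,
    )
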