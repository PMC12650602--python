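import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Balanced 5-class beat dataset, 40 per class, fixed seed."""
    from hctgnet import generate_dataset

    return generate_dataset(40, rng_seed=123)


@pytest.fixture(scope="session")
def synth_record():
    """A mixed-class annotated 360 Hz record with realistic noise."""
    from hctgnet import NoiseModel, generate_record

    return generate_record(
        n_beats=80, class_probs=(0.4, 0.15, 0.2, 0.15, 0.1), fs=360,
        noise=NoiseModel(baseline_wander_amplitude=0.1,
                         baseline_wander_freq=0.25,
                         hf_noise_sd=0.02, seed=11),
        rng_seed=42, record_id="synthfix")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
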