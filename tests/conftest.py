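import numpy as np
import pytest

from sasbls.synth import SynthConfig, generate_cohort, generate_subject


@pytest.fixture(scope="session")
def clean_subject():
    """One artifact-free overnight recording with a moderate event load."""
    return generate_subject(
        SynthConfig(duration_min=360, event_rate_per_hour=20, seed=1)
    )


@pytest.fixture(scope="session")
def noisy_subject():
    """Recording with sensor artifacts, exercising the delta filter."""
    return generate_subject(
        SynthConfig(duration_min=360, event_rate_per_hour=20,
                    artifact_rate_per_hour=6, seed=2)
    )


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects across the AHI range; shared by the slower pipeline tests."""
    return generate_cohort(12, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
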