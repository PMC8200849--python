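import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pdvoice as pv
from pdvoice.synthetic import CohortConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def effect_cohort():
    """Posterior-only cohort with default ON/OFF effects (10 patients)."""
    return pv.generate_cohort(CohortConfig(n_patients=10, seed=4), audio=False)


@pytest.fixture(scope="session")
def null_cohort():
    """Posterior-only cohort with every state effect zeroed."""
    return pv.generate_cohort(CohortConfig.null(n_patients=8, seed=1), audio=False)


@pytest.fixture(scope="session")
def tiny_audio_cohort():
    """Small cohort with audio, for network integration tests."""
    return pv.generate_cohort(
        CohortConfig(n_patients=4, protocols=("pataka", "vowels", "read"), seed=0),
        audio=True,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
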