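import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_config():
    """A quick longitudinal design: 6 patients, 13 scans, small phantom."""
    from msqmri import CohortConfig

    return CohortConfig(
        scans_per_patient={2: 5, 3: 1},
        trait_means={"total_brain_volume": 8.0, "lesion_volume": 0.2},
        seed=7,
    )
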