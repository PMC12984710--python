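import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oct_its import PhantomSpec, generate_cohort, patient_wise_split

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """~450 B-scans from 12 patients; enough structure for split tests."""
    return generate_cohort(PhantomSpec(n_patients=12, noise_sd=0.05, seed=42))


@pytest.fixture(scope="session")
def medium_cohort():
    """~2200 B-scans from 60 patients; for fraction-accuracy checks."""
    return generate_cohort(PhantomSpec(n_patients=60, noise_sd=0.05, seed=7))


@pytest.fixture(scope="session")
def big_cohort():
    """Full-scale phantom cohort: 150 patients at the default noise level."""
    return generate_cohort(PhantomSpec(n_patients=150, noise_sd=0.05, seed=1234))


@pytest.fixture(scope="session")
def big_split(big_cohort):
    return patient_wise_split(big_cohort, (0.64, 0.17, 0.19), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
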