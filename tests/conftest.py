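import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bisffm import ColeParameters, SynthConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cole_params():
    """Cohort-typical Cole parameters used across the spectral tests."""
    return ColeParameters(r0=786.0, rinf=597.0, fc_khz=40.0, alpha=0.1)


@pytest.fixture(scope="session")
def small_cohort():
    """One 65-child cohort with spectra, shared across read-only tests."""
    return generate_cohort(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort_fast():
    """Spectra-free cohort for tests that only need records/references."""
    return generate_cohort(SynthConfig(seed=11, generate_spectra=False))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
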