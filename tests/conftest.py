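import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from allelochoice import ActivationModelParams, CountNoiseParams, make_locus

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_params() -> ActivationModelParams:
    """Per-allele activation probabilities and segment counts of the hybrid study."""
    return ActivationModelParams(p_b6=0.43, p_cast=0.25, n_potential=60, n_total=96)


@pytest.fixture(scope="session")
def default_noise() -> CountNoiseParams:
    return CountNoiseParams(mu_active=100.0, mu_leak=1.0, dispersion=0.1, n_replicates=2)


@pytest.fixture(scope="session")
def full_locus():
    return make_locus(96, 60, seed=1)


@pytest.fixture(scope="session")
def small_locus():
    return make_locus(8, 6, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
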