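import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ieakinetics.model_core import KineticParameters

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def n_gene_params() -> KineticParameters:
    """Kinetic parameters of the N-gene LAMP assay at 65 C, full enzyme."""
    return KineticParameters(T_theta=0.294, K_A=7.040, nu=1.579, c_p0=1.6, S_a=145)


@pytest.fixture(scope="session")
def simple_params() -> KineticParameters:
    """Round-number parameters used for closed-form pipeline checks."""
    return KineticParameters(T_theta=0.300, K_A=5.0, nu=1.5, c_p0=1.6, S_a=145)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
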