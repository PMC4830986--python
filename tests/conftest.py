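import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20100320)


@pytest.fixture
def lab_concentrations_m3():
    """NO2 number densities spanning the flow-reactor range (0.1-24 ppmv)."""
    from nitrodust import GasConditions

    return np.array(
        [GasConditions.from_ppmv(p).number_density for p in (0.1, 1, 3, 6, 12, 24)]
    )
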