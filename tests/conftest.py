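import pytest
from hypothesis import HealthCheck, settings

import neonet as nn

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_params():
    """A scaled-down state: 8 regions x 5 municipalities, full 2008-2019."""
    return nn.SynthParams(
        n_regions=8,
        munis_per_region=5,
        admissions_per_muni_year=6.0,
        births_per_muni_year=60.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_data(small_params):
    return nn.generate_dataset(small_params)


@pytest.fixture(scope="session")
def small_registry(small_data):
    return small_data["registry"]


@pytest.fixture(scope="session")
def default_data():
    """The full default study conditions (22 regions, ~190k admissions)."""
    return nn.generate_dataset(nn.SynthParams(seed=7))
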