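import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nfkbsim import (
    build_catalog,
    nominal_parameters,
    nominal_pools,
    simulate_scenario_run,
)
from nfkbsim.simulate import equilibrate

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return nominal_parameters()


@pytest.fixture(scope="session")
def pools():
    return nominal_pools()


@pytest.fixture(scope="session")
def catalog():
    return build_catalog()


@pytest.fixture(scope="session")
def nominal_eq(params, pools):
    return equilibrate(params, pools)


@pytest.fixture(scope="session")
def nominal_traj(params, pools):
    return simulate_scenario_run(params, pools, None)


@pytest.fixture(scope="session")
def scenario_run(params, pools, catalog):
    """Session-cached scenario simulations keyed by catalog name."""
    cache = {}

    def _run(name):
        if name not in cache:
            scenario = None if name == "nominal" else catalog[name]
            cache[name] = simulate_scenario_run(params, pools, scenario)
        return cache[name]

    return _run


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231)
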