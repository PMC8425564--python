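import pytest
from hypothesis import HealthCheck, settings

import ckdflow as ck

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def registry():
    """Packaged default parameter registry (params, costs)."""
    return ck.load_parameters()


@pytest.fixture(scope="session")
def params(registry):
    return registry[0]


@pytest.fixture(scope="session")
def costs(registry):
    return registry[1]


@pytest.fixture(scope="session")
def baseline_run(registry):
    params, costs = registry
    return ck.run_projection(params, costs)


@pytest.fixture(scope="session")
def intervention_run(registry):
    params, costs = registry
    return ck.run_projection(params, costs, ck.intervention_scenario(params, costs))
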