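import pytest

from ckdflow.ckd import build_ckd_model, default_parameters
from ckdflow.engine import SimulationConfig, simulate


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(t_start=2010.0, t_end=2022.0, dt=0.0625)


@pytest.fixture(scope="session")
def base_run(params, config):
    """The base 2010–2022 trajectory, shared read-only across tests."""
    return simulate(build_ckd_model(params), config)
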