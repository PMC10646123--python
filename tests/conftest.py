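import numpy as np
import pytest

from fairyring import ModelParams, SimConfig, run


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def default_run():
    """One reference simulation shared across tests: combined hypothesis at
    published defaults, 1D transect, 2000 days."""
    return run(SimConfig())


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20231114)
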