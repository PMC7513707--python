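import numpy as np
import pytest

from detoxevo import ModelParams, SCENARIOS


@pytest.fixture(scope="session")
def fig1_params() -> ModelParams:
    """Base parameter set of the dynamics examples (panels b-d)."""
    return SCENARIOS["fig1b"].params


@pytest.fixture(scope="session")
def fig1e_params() -> ModelParams:
    return SCENARIOS["fig1e"].params


@pytest.fixture(scope="session")
def fig2_params() -> ModelParams:
    return SCENARIOS["fig2"].params


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20231001)
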