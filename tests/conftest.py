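import numpy as np
import pytest

from torquegait import build_default_model
from torquegait.dynamics import DynamicsEngine
from torquegait.mtg import build_mtg_set, default_strength_table

#: reference anthropometry used throughout the suite (7-year-old child)
CHILD_MASS = 24.7
CHILD_HEIGHT = 1.25


@pytest.fixture(scope="session")
def child_model():
    return build_default_model(CHILD_MASS, CHILD_HEIGHT)


@pytest.fixture(scope="session")
def engine(child_model):
    return DynamicsEngine(child_model)


@pytest.fixture(scope="session")
def pathological_mtgs():
    return build_mtg_set(default_strength_table("pathological"))


@pytest.fixture(scope="session")
def healthy_mtgs():
    return build_mtg_set(default_strength_table("healthy"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
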