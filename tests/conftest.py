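import numpy as np
import pytest

from vestiflow import (WATER_LIKE_ENDOLYMPH, build_fixture, elasticity_for_T1)


@pytest.fixture(scope="session")
def props():
    return WATER_LIKE_ENDOLYMPH


@pytest.fixture(scope="session")
def two_duct_net():
    """Right-isosceles two-duct labyrinth (gamma = 1, lambda = 1/(1+sqrt 2))."""
    return build_fixture("two_duct_fig4")


@pytest.fixture(scope="session")
def three_duct_net():
    """Folded-out flat three-duct labyrinth with realistic proportions."""
    return build_fixture("flat_three_duct")


@pytest.fixture(scope="session")
def human_net():
    """Single-duct circuit with human-like dimensions (T2 = 5 ms)."""
    return build_fixture("human_like")


@pytest.fixture(scope="session")
def three_duct_S(three_duct_net):
    """Cupular stiffness giving duct a a slow constant T1 = 20 s."""
    return elasticity_for_T1(three_duct_net["a"], three_duct_net.props, 20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
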