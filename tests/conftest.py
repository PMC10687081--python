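import numpy as np
import pytest

from trilokit import base_shape, builtin_template
from trilokit.shapeio import CEPHALON, PYGIDIUM


@pytest.fixture(scope="session")
def cephalon_template():
    return builtin_template(CEPHALON)


@pytest.fixture(scope="session")
def pygidium_template():
    return builtin_template(PYGIDIUM)


@pytest.fixture
def base_cephalon():
    return base_shape(CEPHALON)


@pytest.fixture
def base_pygidium():
    return base_shape(PYGIDIUM)


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


def random_configuration(rng, p=6, scale=1.0):
    """An asymmetric p-point configuration with generic position."""
    return rng.normal(0.0, 1.0, size=(p, 2)) * scale


@pytest.fixture
def random_config_factory(rng):
    def factory(p=6, scale=1.0):
        return random_configuration(rng, p=p, scale=scale)

    return factory
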