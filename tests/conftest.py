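import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from axomech.composition import default_registry, get_preset
from axomech.builder import build_bilayer


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def myelin():
    return get_preset("myelin")


@pytest.fixture(scope="session")
def node():
    return get_preset("node")


@pytest.fixture(scope="session")
def small_frame(myelin):
    """A 200-lipid myelin patch used by many geometric tests."""
    return build_bilayer(myelin, 200, thickness=4.5, box_lz=12.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
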