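import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

from msiconcord import SimulationConfig, build_panels, default_registry, marker_index


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def panels(registry):
    return build_panels(registry)


@pytest.fixture(scope="session")
def midx(registry):
    return marker_index(registry)


@pytest.fixture(scope="session")
def seq_markers(registry):
    return [m for m in registry if any(t in ("seq24", "seq54") for t in m.panel_tags)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture
def fast_config():
    """Reduced depth for unit tests that only need the noise structure."""
    return SimulationConfig(seed=7, depth=400)
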