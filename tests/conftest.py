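import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sedstoich import BufferState, CellGeometry, Component
from sedstoich.synthetic_data import reference_compositions, reference_registry


@pytest.fixture(scope="session")
def buffer():
    return BufferState()


@pytest.fixture(scope="session")
def registry():
    return reference_registry()


@pytest.fixture(scope="session")
def compositions(registry):
    return reference_compositions(registry)


@pytest.fixture(scope="session")
def sv_geometry():
    return CellGeometry(meniscus=6.0, bottom=7.2)


@pytest.fixture
def simple_components():
    """Minimal two-component registry for arithmetic-level tests."""
    return {
        "prot": Component("prot", 27_000.0, 0.734, {280.0: 2.44e4}, "protein"),
        "dna": Component("dna", 5_100.0, 0.56, {260.0: 1.2e5}, "ssDNA"),
    }
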