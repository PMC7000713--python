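import numpy as np
import pytest

from megabiota import (
    GridDomain,
    SimConfig,
    pleistocene_community,
)


@pytest.fixture(scope="session")
def reference_community():
    return pleistocene_community()


@pytest.fixture(scope="session")
def small_domain():
    """Small all-land basin with a western-edge source, cheap to solve."""
    ny, nx = 10, 15
    land = np.ones((ny, nx), dtype=bool)
    source = np.zeros((ny, nx), dtype=bool)
    source[:, 0] = True
    return GridDomain(nx=nx, ny=ny, dx=50.0, land_mask=land, source_mask=source)


@pytest.fixture(scope="session")
def default_sim_config():
    return SimConfig(phi=4.4, loss_rate=4.4e-6)
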