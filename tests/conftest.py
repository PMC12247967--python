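import numpy as np
import pytest

from multibud import build_actin_fields, build_grid, place_buds

PAPER_DOMAIN = (10.5, 6.6, 6.6)


@pytest.fixture(scope="session")
def coarse_grid():
    """Desk-scale grid used by most solver tests."""
    return build_grid(10.0, 6.0, PAPER_DOMAIN, (32, 20, 20))


@pytest.fixture(scope="session")
def medium_grid():
    return build_grid(10.0, 6.0, PAPER_DOMAIN, (64, 40, 40))


@pytest.fixture(scope="session")
def asym_buds(coarse_grid):
    return place_buds(coarse_grid, "adjacent2_distant1")


@pytest.fixture(scope="session")
def asym_fields(coarse_grid, asym_buds):
    return build_actin_fields(coarse_grid, asym_buds, beta=3.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
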