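import numpy as np
import pytest

from rosecal import WavenumberWindow, default_grid, default_library


@pytest.fixture(scope="session")
def grid():
    """Default 4000 -> 600 cm^-1 grid, 2 cm^-1 step (1701 points)."""
    return default_grid()


@pytest.fixture(scope="session")
def library():
    """Default component library with brand jitter enabled."""
    return default_library()


@pytest.fixture(scope="session")
def library_nojitter():
    return default_library(brand_jitter_cv=0.0)


@pytest.fixture(scope="session")
def hca_windows():
    """The two survey windows used for classification."""
    return [WavenumberWindow(high=3541, low=3153), WavenumberWindow(high=1771, low=663)]


@pytest.fixture()
def rng():
    return np.random.default_rng(20210811)
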