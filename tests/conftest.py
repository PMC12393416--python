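import warnings

import numpy as np
import pytest

from msbptomo import Grid2D, OpticalConfig

# high-contrast phantoms intentionally exceed the thin-screen comfort zone
warnings.filterwarnings("ignore", message=r"peak \|delta_n\|")


@pytest.fixture
def grid16():
    return Grid2D(16, 16, 0.2)


@pytest.fixture
def grid64():
    return Grid2D(64, 64, 0.125)


@pytest.fixture
def optics():
    """Oil/water-ish high-NA configuration used throughout the suite."""
    return OpticalConfig(wavelength=0.635, n0=1.33, na_detect=1.2, na_illum=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
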