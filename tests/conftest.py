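import numpy as np
import pytest

from colorform import stimuli as st
from colorform.activations import extract_activations
from colorform.synth import toy_network_adapter


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def calibration():
    return st.CalibrationTarget("cieluv", 60.0, 40.0)


@pytest.fixture(scope="session")
def bar_set(calibration):
    """The default 144-stimulus oriented-bar grid (400 px canvas)."""
    return st.make_bars(calibration)


@pytest.fixture(scope="session")
def small_bar_set(calibration):
    """A reduced bar grid (cheap to push through networks repeatedly)."""
    return st.make_bars(
        calibration,
        n_orientations=6,
        n_hues=12,
        template=st.BarSpec(0.0, 96, 20, 128),
    )


@pytest.fixture(scope="session")
def toy_adapter():
    return toy_network_adapter(seed=7, n_stages=3, input_size=32)


@pytest.fixture(scope="session")
def small_activations(toy_adapter, small_bar_set):
    return extract_activations(toy_adapter, small_bar_set)


@pytest.fixture
def disc_source():
    """A mid-gray disc on a white canvas with a known mask."""
    n = 64
    yy, xx = np.mgrid[0:n, 0:n]
    mask = (xx - n / 2 + 0.5) ** 2 + (yy - n / 2 + 0.5) ** 2 <= (n / 4) ** 2
    raster = np.full((n, n, 3), 255, dtype=np.uint8)
    raster[mask] = 128
    return st.SourceObjectImage("disc", raster, mask)
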