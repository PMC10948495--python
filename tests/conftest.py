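import numpy as np
import pytest

from chemograd import ChannelGeometry, ImagingParams, NoiseModel
from chemograd.rendering import BackgroundInhomogeneity


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_geometry():
    """A narrow channel that keeps explicit PDE solves cheap."""
    return ChannelGeometry(width_um=100.0, length_um=50.0, pixel_size_um=5.0)


@pytest.fixture
def noise_free_imaging():
    """Continuum rendering with every stochastic term switched off."""
    return ImagingParams(
        gain=80.0,
        background_level=200.0,
        background_inhomogeneity=BackgroundInhomogeneity(amplitude=0.0),
        noise_model=NoiseModel(shot=False, read_sigma=0.0),
        mode="continuum",
        duration_h=0.5,
    )
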