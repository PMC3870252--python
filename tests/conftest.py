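import numpy as np
import pytest

from oligospot import CameraModel, build_cell_model


@pytest.fixture
def camera():
    """Default sCMOS camera model."""
    return CameraModel()


@pytest.fixture
def quiet_camera():
    """Noise-free camera (zero read noise) for deterministic rendering."""
    return CameraModel(offset=100.0, gain=2.0, read_noise_sd=0.0)


@pytest.fixture
def cell():
    """A typical unconstricted cell placed inside a positive-coordinate field."""
    return build_cell_model(3.0, 1.0, "unconstricted", center_um=(2.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
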