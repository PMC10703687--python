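import numpy as np
import pytest

import epigrad as eg


@pytest.fixture(scope="session")
def impulse():
    return eg.load_coil_preset("impulse")


@pytest.fixture(scope="session")
def ac84():
    return eg.load_coil_preset("ac84")


@pytest.fixture(scope="session")
def xr_body():
    return eg.load_coil_preset("xr_body")


@pytest.fixture(scope="session")
def protocol_06():
    """0.6 mm / FOV 192 / matrix 320 / GRAPPA 3 / PF 6/8 protocol."""
    return eg.EPIProtocol.from_resolution(0.6, 192.0, grappa_r=3, partial_fourier=0.75)


@pytest.fixture(scope="session")
def protocol_05():
    """0.5 mm / FOV 192 / matrix 384 / GRAPPA 3 / PF 6/8 protocol."""
    return eg.EPIProtocol.from_resolution(0.5, 192.0, grappa_r=3, partial_fourier=0.75)


@pytest.fixture(scope="session")
def smooth_test_image():
    """Smooth nonnegative 2D image with zero borders (PE along axis 1)."""
    from scipy import ndimage

    rng = np.random.default_rng(0)
    img = ndimage.gaussian_filter((rng.random((48, 64)) > 0.6).astype(float), 3.0)
    img[:, :3] = 0.0
    img[:, -3:] = 0.0
    img[:3] = 0.0
    img[-3:] = 0.0
    return img
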