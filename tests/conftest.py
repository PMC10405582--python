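import numpy as np
import pytest

from xpcskit.geometry import DetectorGeometry, build_qmap


@pytest.fixture
def usaxs_geometry() -> DetectorGeometry:
    """ID-style USAXS geometry: 1 A beam, 31 m flight path."""
    return DetectorGeometry(
        wavelength=0.1,
        distance=31.0,
        pixel_pitch=75e-6,
        beam_center=(16.0, 16.0),
    )


@pytest.fixture
def small_qmap(usaxs_geometry):
    return build_qmap(usaxs_geometry, (32, 32))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
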