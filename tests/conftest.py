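import numpy as np
import pytest

from exuscan.detector import DetectionConfig
from exuscan.image_io import GrayImage
from exuscan.synthetic import SceneSpec, generate_scene


@pytest.fixture
def default_cfg():
    return DetectionConfig()


@pytest.fixture
def small_cfg():
    """A config small enough for exhaustive per-pixel oracles on tiny images."""
    return DetectionConfig(th1=0.05, th2=1, th3=2, r0=1.0, r1=5.0, n_semi=4, n_dirs=3)


@pytest.fixture
def constant_image():
    return GrayImage(np.full((24, 24), 0.0))


@pytest.fixture
def disc_image():
    """Bright disc (radius 12, contrast +0.3) on a flat background, 64x64."""
    yy, xx = np.mgrid[0:64, 0:64].astype(float)
    inside = np.hypot(yy - 32, xx - 32) <= 12
    return GrayImage(np.where(inside, 0.8, 0.5)), inside


@pytest.fixture
def clean_scene():
    """A deterministic noise-free scene with known ground truth."""
    spec = SceneSpec(
        seed=7,
        size=(160, 160),
        n_lesions=3,
        lesion_radius_range=(5.0, 10.0),
        noise_sigma=0.0,
        n_vessels=2,
    )
    return generate_scene(spec)
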