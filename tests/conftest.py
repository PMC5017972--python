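import numpy as np
import pytest

from glaucoscreen.config import RunConfig
from glaucoscreen.localize import RoiPatch, extract_roi
from glaucoscreen.synth import (VesselSpec, generate_fundus,
                                make_ground_truth)


@pytest.fixture(scope="session")
def cfg_small() -> RunConfig:
    return RunConfig.profile("small")


@pytest.fixture(scope="session")
def clean_truth():
    """Noise-free, vessel-free, gradient-free ground truth (CDR 0.3)."""
    return make_ground_truth(seed=7, cdr=0.3,
                             vessel_spec=VesselSpec(count=0),
                             illumination_gradient=0.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_image(clean_truth):
    return generate_fundus(clean_truth)


@pytest.fixture(scope="session")
def clean_roi(clean_truth, clean_image, cfg_small) -> RoiPatch:
    """ROI cropped at the true disc centre of the clean image."""
    center = (int(clean_truth.disc_ellipse.center[1]),
              int(clean_truth.disc_ellipse.center[0]))
    return extract_roi(clean_image, center, cfg_small.roi_size)


@pytest.fixture(scope="session")
def default_truth():
    """Ground truth with the default vessels/gradient/noise (CDR 0.3)."""
    return make_ground_truth(seed=11, cdr=0.3)


@pytest.fixture(scope="session")
def default_image(default_truth):
    return generate_fundus(default_truth)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
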