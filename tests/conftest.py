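import numpy as np
import pytest

import lvseg


@pytest.fixture(scope="session")
def clean_truth():
    """Noise-free phantom (speckle and artifacts disabled)."""
    spec = lvseg.random_spec(2, speckle_shape=None, artifact_count=0)
    return lvseg.render_phantom(spec)


@pytest.fixture(scope="session")
def speckled_truth():
    """Phantom at the default study conditions (speckle shape 10, 2 artifacts)."""
    return lvseg.render_phantom(lvseg.random_spec(3))


@pytest.fixture(scope="session")
def bimodal_frame():
    """Two-level image with Gaussian noise, 100x100."""
    rng = np.random.default_rng(7)
    levels = rng.integers(0, 2, size=(100, 100))
    img = np.where(levels == 1, 180.0, 40.0) + rng.normal(0, 10, (100, 100))
    return lvseg.UltrasoundFrame(np.clip(img, 0, 255)), levels
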