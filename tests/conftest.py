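import numpy as np
import pytest

from cherenkov_denoise import AcquisitionSpec, Image2D, NoiseModel, SceneSpec, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """A fast 96x96 scene with the same structure as the defaults."""
    return SceneSpec(height=96, width=96, phantom_margin=8, vignette_sigma=60.0)


@pytest.fixture(scope="session")
def small_dataset():
    """One quick truth/noisy pair for tests that need realistic noise."""
    spec = SceneSpec(height=96, width=96, phantom_margin=8, vignette_sigma=60.0)
    acq = AcquisitionSpec(frames_truth=300, frames_noisy=5, seed=11)
    truth, noisy = make_dataset(spec, acq, NoiseModel())
    return spec, acq, truth, noisy


@pytest.fixture
def random_image(rng):
    return Image2D(np.abs(rng.normal(100.0, 15.0, (24, 24))))
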