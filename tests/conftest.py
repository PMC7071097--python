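import numpy as np
import pytest

from retipatch import preprocess, synthetic


@pytest.fixture(scope="session")
def small_config():
    """A compact synthetic image: fast enough for per-module tests while
    still containing FOV, optic disc, vessels and both lesion classes."""
    return synthetic.SyntheticConfig(
        image_width=256,
        image_height=256,
        n_exudates=3,
        n_microaneurysms=2,
        n_hemorrhages=1,
        lesion_size_range=(6.0, 14.0),
        lesion_contrast=0.4,
        vessel_count=6,
        noise_sigma=0.01,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_sample(small_config):
    return synthetic.generate_sample(small_config)


@pytest.fixture(scope="session")
def conditioned(small_sample):
    return preprocess.condition(
        small_sample.image,
        fov_mask=small_sample.fov_mask,
        od_mask=small_sample.od_mask,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
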