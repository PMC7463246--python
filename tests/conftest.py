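import numpy as np
import pytest

from mammofusion import patch_sampling, phantom, preprocess
from mammofusion.mias_io import MammogramImage


@pytest.fixture(scope="session")
def small_phantom():
    """4 normal + 4 abnormal phantom images (side 256) with annotations."""
    config = phantom.PhantomConfig(n_normal=4, n_abnormal=4, image_side=256,
                                   seed=11)
    images, annotations = phantom.generate_dataset(config)
    return config, images, annotations


@pytest.fixture(scope="session")
def small_rois(small_phantom):
    _, images, annotations = small_phantom
    rois = preprocess.extract_rois(
        {im.image_id: im for im in images}, annotations, seed=11)
    assert len(rois) == 8
    return rois


@pytest.fixture(scope="session")
def small_split(small_rois):
    return patch_sampling.split_rois(small_rois, seed=11)


@pytest.fixture(scope="session")
def small_patchsets(small_rois, small_split):
    return patch_sampling.build_patch_dataset(
        small_rois, small_split, counts={"Normal": 20, "Tumor": 40}, seed=11)


@pytest.fixture()
def random_image():
    rng = np.random.default_rng(3)
    return MammogramImage(
        image_id="rand", pixels=rng.integers(0, 256, (64, 64), dtype=np.uint8))


@pytest.fixture()
def flat_roi():
    pixels = np.full((120, 120), 90, np.uint8)
    return preprocess.Roi(pixels=pixels, label="Normal", image_id="flat",
                          center_row=60, center_col=60)
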