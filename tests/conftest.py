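import numpy as np
import pytest

from pyrafex import (
    ImageFixtureSpec,
    PyramidConfig,
    TableFixtureSpec,
    make_feature_table,
    make_image_dataset,
    stub_backbone,
)

# small geometry used by most tests: 56-px working side, 14/28-px patches
# (16 + 4 + 1 = 21 views), so full pipelines run in well under a second
SMALL_PYRAMID = PyramidConfig(working_side=56, patch_sides=(14, 28))


@pytest.fixture(scope="session")
def small_pyramid() -> PyramidConfig:
    return SMALL_PYRAMID


@pytest.fixture(scope="session")
def small_backbone():
    return stub_backbone(seed=0, output_dim=20)


@pytest.fixture(scope="session")
def image_dataset_dir(tmp_path_factory):
    """2 classes x 6 images, 56 px, written once per session."""
    spec = ImageFixtureSpec(
        n_classes=2, images_per_class=6, side=56, texture_scales=(8, 28),
        noise_sd=0.05, seed=11,
    )
    root = tmp_path_factory.mktemp("imgset")
    make_image_dataset(spec, root)
    return root


@pytest.fixture(scope="session")
def planted_table():
    """200 x 50 table, columns 0-4 shifted by 2 sd between two classes."""
    return make_feature_table(TableFixtureSpec(seed=3))


def random_rgb(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    return rng.random((h, w, 3))
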