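import numpy as np
import pytest

from leaffusion.synthetic import (
    SyntheticDatasetSpec,
    generate_dataset,
    make_lookalike_specs,
    make_separable_specs,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_rgb(rng):
    return rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)


@pytest.fixture()
def random_gray(rng):
    return rng.integers(0, 256, size=(32, 32), dtype=np.uint8)


@pytest.fixture(scope="session")
def separable_dir(tmp_path_factory):
    """3 color-separable classes x 10 images at 64x64."""
    root = tmp_path_factory.mktemp("separable")
    spec = SyntheticDatasetSpec(
        class_specs=make_separable_specs(3), images_per_class=10, image_size=(64, 64), seed=11
    )
    generate_dataset(spec, root)
    return root


@pytest.fixture(scope="session")
def lookalike_dir(tmp_path_factory):
    """Color-matched texture-differing pair plus an outgroup, 12 images each."""
    root = tmp_path_factory.mktemp("lookalike")
    spec = SyntheticDatasetSpec(
        class_specs=make_lookalike_specs(), images_per_class=12, image_size=(64, 64), seed=23
    )
    generate_dataset(spec, root)
    return root


@pytest.fixture(scope="session")
def blob_matrix():
    """Well-separated 3-class Gaussian blobs in 2-D (seeded)."""
    from leaffusion.balancing import FeatureMatrix

    rng = np.random.default_rng(7)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    X = np.vstack([c + rng.normal(0, 0.5, size=(20, 2)) for c in centers])
    y = np.repeat([0, 1, 2], 20)
    return FeatureMatrix(X, y, class_names=["a", "b", "c"])
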