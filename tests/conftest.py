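import numpy as np
import pytest

from ltssl.data import SyntheticDatasetSpec, generate_dataset, split_labeled


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small, fast long-tailed dataset (3 classes, ~200 images, 16x16)."""
    spec = SyntheticDatasetSpec(n_classes=3, head_count=120, imbalance_ratio=0.5,
                                min_count=10, image_size=16, test_per_class=20,
                                seed=11)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def tiny_split(tiny_dataset):
    return split_labeled(tiny_dataset, 0.2, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
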