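import numpy as np
import pytest

from stagedistill import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_synth(tmp_path_factory):
    """The default desk-scale dataset: 300 images, reference imbalance."""
    root = tmp_path_factory.mktemp("synth_default")
    config = SyntheticConfig(seed=7)
    manifest = generate_dataset(config, root)
    return config, manifest


@pytest.fixture(scope="session")
def easy_synth(tmp_path_factory):
    """Difficulty-0 variant (maximally separable classes)."""
    root = tmp_path_factory.mktemp("synth_easy")
    config = SyntheticConfig(difficulty=0.0, seed=7)
    manifest = generate_dataset(config, root)
    return config, manifest


@pytest.fixture(scope="session")
def tiny_manifest(tmp_path_factory):
    """Small balanced 32x32 dataset for fast pipeline tests."""
    root = tmp_path_factory.mktemp("synth_tiny")
    config = SyntheticConfig(
        image_size=32,
        class_proportions=(1, 1, 1, 1, 1),
        total_images=50,
        difficulty=0.0,
        seed=3,
    )
    return generate_dataset(config, root)
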