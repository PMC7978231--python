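import numpy as np
import pytest

from jigsawssl.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """Small balanced-ish dataset: enough labelled videos per class for
    5-fold video-level splitting, cheap enough for trainer tests."""
    cfg = SyntheticConfig(n_videos=32, frames_per_video=5, seed=7,
                          class_imbalance=0.5, unlabeled_fraction=0.2,
                          domain_mix=0.5)
    manifest, images = generate_dataset(cfg)
    return cfg, manifest, images


@pytest.fixture(scope="session")
def default_dataset():
    """The default-scale synthetic dataset (60 videos x 15 frames)."""
    cfg = SyntheticConfig(seed=1)
    manifest, images = generate_dataset(cfg)
    return cfg, manifest, images
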