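import numpy as np
import pytest

from julite.datapipe import AugmentConfig, SyntheticConfig, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small synthetic image-folder corpus (64 px, 8 per class)."""
    root = tmp_path_factory.mktemp("tinydata")
    cfg = SyntheticConfig(image_size=64, n_per_class=8, seed=7)
    manifest = generate_dataset(cfg, root)
    return root, manifest, cfg


@pytest.fixture(scope="session")
def aug64():
    return AugmentConfig(output_size=64)
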