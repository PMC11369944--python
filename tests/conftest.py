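import numpy as np
import pytest

from weedssl import SceneConfig, generate_dataset
from weedssl.scene_forge import BoxCountLaw


@pytest.fixture(scope="session")
def tiny_scene():
    """Twelve small 3-class scenes shared by plumbing tests."""
    cfg = SceneConfig(
        num_classes=3,
        image_size=(96, 96),
        seed=5,
        box_count_law=BoxCountLaw(crowded_prob=0.0, typical_high=4),
    )
    return cfg, generate_dataset(cfg, 12)


@pytest.fixture(scope="session")
def separable_single_class():
    """Fifty single-class scenes for training smoke tests."""
    cfg = SceneConfig(
        num_classes=1,
        class_weights=(1.0,),
        seed=11,
        box_count_law=BoxCountLaw(crowded_prob=0.0),
    )
    return cfg, generate_dataset(cfg, 50)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
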