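import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def phantom_batch_64():
    """Small labeled phantom set at 64 px shared by slower tests."""
    from adstage.phantom import generate_dataset

    manifest, samples = generate_dataset(20, seed=7, image_size=64)
    images = np.stack([samples[r.id].image for r in manifest.records])
    gm = np.stack([samples[r.id].gm_mask for r in manifest.records])
    brain = np.stack([samples[r.id].brain_mask for r in manifest.records])
    labels = np.array([r.label for r in manifest.records])
    return images, brain, gm, labels
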