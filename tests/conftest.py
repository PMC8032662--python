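import numpy as np
import pytest

from mranomaly import (
    GanomalyPatchDetector,
    ModelConfig,
    MultiChannelVolume,
    PhantomConfig,
    generate_normal,
    normalize_intensity,
    sample_training_patches,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    return ModelConfig(latent_dim=8, channel_widths=(4, 6))


@pytest.fixture
def small_phantom_config():
    # small grid for fast unit tests; keeps the anisotropic spacing
    return PhantomConfig(
        shape=(8, 48, 48),
        ellipse_semiaxes=(3.8, 20.0, 18.0),
        rng_seed=7,
    )


@pytest.fixture
def small_volume(small_phantom_config):
    return normalize_intensity(generate_normal(small_phantom_config))


@pytest.fixture
def random_volume(rng):
    """Unstructured random volume with a blocky mask, for contract tests."""
    channels = rng.normal(50.0, 10.0, size=(2, 6, 40, 40)).astype(np.float32)
    mask = np.zeros((6, 40, 40), dtype=bool)
    mask[:, 5:35, 5:35] = True
    return MultiChannelVolume(
        channels=channels, spacing=(4.0, 0.9, 0.9), mask=mask, volume_id="rand"
    )


@pytest.fixture(scope="session")
def trained_tiny():
    """A quickly trained small detector on phantom-like normal patches.

    Shared across scoring/evaluation tests; 3 epochs on 1,500 patches is
    enough for the latent statistics to be well-defined.
    """
    cfgs = [
        PhantomConfig(shape=(8, 48, 48), ellipse_semiaxes=(3.8, 20.0, 18.0), rng_seed=s)
        for s in (100, 101)
    ]
    vols = [normalize_intensity(generate_normal(c)) for c in cfgs]
    tp = sample_training_patches(vols, 1500, rng_seed=1)
    vp = sample_training_patches(vols, 300, rng_seed=2)
    det = GanomalyPatchDetector(
        latent_dim=8,
        channel_widths=(4, 6),
        max_epochs=3,
        random_state=0,
    )
    det.fit(tp.patches, X_val=vp.patches)
    return det
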