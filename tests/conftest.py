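import numpy as np
import pytest

from glomseg import BackboneConfig, HeadSpec, PhantomSpec, synthetic_catalog


@pytest.fixture(scope="session")
def tiny_backbone_cfg() -> BackboneConfig:
    """Smallest legal backbone for unit tests."""
    return BackboneConfig(depth=2, base_width=4, decoder_out_channels=4)


@pytest.fixture(scope="session")
def tiny_head() -> HeadSpec:
    return HeadSpec((4, 4, 1))


@pytest.fixture(scope="session")
def catalog():
    return synthetic_catalog()


@pytest.fixture(scope="session")
def phantom_batch(catalog):
    """Eight 32x32 phantoms cycling through all ten classes."""
    from glomseg import generate_samples
    spec = PhantomSpec(image_size=32)
    return generate_samples(spec, 8, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def learnability_run():
    """The reference end-to-end training run on nested-structure phantoms.

    Session-scoped because training is the expensive step; the run is shared
    by the learnability, overlap and reproducibility checks.
    """
    from glomseg.protocols import learnability_experiment
    return learnability_experiment(seed=1234, epochs=30)
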