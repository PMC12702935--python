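import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_phantom_batch():
    """Four 64x64, 4-class phantoms with the generator defaults."""
    from iap_transunet.phantoms import PhantomSpec, generate_phantom
    spec = PhantomSpec()
    pairs = [generate_phantom(spec, [7, i]) for i in range(4)]
    images = np.stack([p[0] for p in pairs])
    labels = np.stack([p[1] for p in pairs])
    return spec, images, labels
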