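import numpy as np
import pytest

from imcodec.synthetic import PhantomSpec, default_prototypes, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ellipse_128():
    return generate(PhantomSpec("ellipse", 128, 128, seed=0))


@pytest.fixture(scope="session")
def mosaic_clean_128():
    protos = default_prototypes(4)
    img = generate(
        PhantomSpec("mosaic", 128, 128, prototypes=protos, noise_sigma=0.0, seed=0)
    )
    return img, protos


@pytest.fixture(scope="session")
def mosaic_noisy_128():
    protos = default_prototypes(4)
    img = generate(
        PhantomSpec("mosaic", 128, 128, prototypes=protos, noise_sigma=2.0, seed=1)
    )
    return img, protos
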