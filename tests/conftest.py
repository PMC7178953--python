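import numpy as np
import pytest

from tendonseg.network import NetworkSpec


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_spec():
    """Smallest valid architecture: fast enough for training smoke tests."""
    return NetworkSpec(input_hw=(16, 32), init_channels=4,
                       levels=((1, 2), (2, 4), (3, 8), (4, 16)),
                       td_channels=(4, 8, 16), tu_channels=(16, 8, 4),
                       penult_channels=4)


@pytest.fixture(scope="session")
def tiny_phantoms():
    """Eight small phantom image/tendon pairs matching tiny_spec's input."""
    from tendonseg.phantom import generate_dataset
    data = generate_dataset(8, clear_fraction=0.5, seed=7, image_hw=(16, 32))
    return [(img, tendon) for img, tendon, _, _ in data]
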