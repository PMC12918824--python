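import numpy as np
import pytest

from meiodel.fixtures import make_toy_dataset


@pytest.fixture(scope="session")
def toy():
    """Session-wide toy dataset: 50-kb reference, two hotspot pairs, one
    single hotspot tiled by four overlapping amplicons."""
    return make_toy_dataset(11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
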