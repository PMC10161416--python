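import numpy as np
import pytest
from hypothesis import settings

from evoaug import seqdata

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_seq(rng):
    """A strictly one-hot random 80-mer."""
    return seqdata.random_one_hot(rng, 1, 80)[0]


@pytest.fixture(scope="session")
def small_dataset():
    """Seed-fixed planted-motif dataset shared across read-only tests."""
    spec = seqdata.SyntheticSpec(n_records=400, length=100, seed=11)
    return seqdata.generate_synthetic_dataset(spec)
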