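import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small in-memory phantom dataset shared by training smoke tests."""
    from petuq import make_dataset

    return make_dataset(n_phantoms=6, drfs=[20], split_fracs=(0.5, 0.25, 0.25), seed=11)
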