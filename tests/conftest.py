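import numpy as np
import pytest

from simplerpm.dataset import DatasetConfig, build_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_dataset():
    """All 40 rules at 10/2/2 rows per rule (560 rows)."""
    return build_dataset(DatasetConfig(n_train=10, n_val=2, n_test=2, seed=7))
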