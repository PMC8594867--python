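import numpy as np
import pytest

from pcmbench.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but structured synthetic dataset shared across tests."""
    cfg = SyntheticConfig(n_proteins=30, n_series=12, seed=11)
    dataset, truth = generate_dataset(cfg)
    return dataset, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
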