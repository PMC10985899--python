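import numpy as np
import pytest

from drugsyn import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-signal dataset shared by model-level tests."""
    cfg = synthetic.SyntheticConfig(n_drugs=12, n_cells=8, n_genes=60,
                                    n_triplets=160, seed=7)
    return synthetic.generate_dataset(cfg)
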