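import numpy as np
import pytest

from swepool import SyntheticSpec, gen_property_dataset
from swepool.train import RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_binary_dataset():
    """Small, strongly separable binary dataset for fast end-to-end tests."""
    spec = SyntheticSpec(n_proteins=200, d=8, length_min=10, length_max=20,
                         k_signal=5, signal_strength=5.0, noise_sd=1.0,
                         task="binary", seed=11)
    return gen_property_dataset(spec)


@pytest.fixture
def fast_config():
    return RunConfig(task="ec", pooler="avg", epochs=5, seeds=(0,), batch_size=32)
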