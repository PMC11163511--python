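import numpy as np
import pytest

from polypseg.config import tiny_model_config
from polypseg.data import SyntheticConfig, generate_synthetic_dataset

# the fixed study conditions for smoke training: 8 synthetic 96x96 pairs
SMOKE_SYNTH = SyntheticConfig(n_images=8, image_size=(96, 96), seed=42)


@pytest.fixture(scope="session")
def fixture_pairs():
    """Eight deterministic 96x96 synthetic image/mask pairs."""
    return generate_synthetic_dataset(SMOKE_SYNTH)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_cfg():
    return tiny_model_config(ref_input_size=(96, 96))


def zero_module(module):
    """Set every parameter of a module tree to zero, in place."""
    for p in module.parameters():
        p.data = np.zeros_like(p.data)
    return module
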