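import numpy as np
import pytest

from msa_maxnet.nn import Module


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def zero_params(module: Module) -> Module:
    """Zero every parameter of a module in place (bias tables included)."""
    for p in module.parameters():
        p.data[...] = 0.0
    return module


@pytest.fixture
def zeroed():
    return zero_params
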