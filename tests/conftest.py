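import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_cfg():
    from dganet import NetConfig
    return NetConfig(stage_widths=(8, 8, 8, 8, 8), nominal_size=(32, 32),
                     token_budget=64, seed=7)


def zero_params(module):
    """Zero every parameter of a module in place."""
    for p in module.parameters():
        p.data[...] = 0.0
    return module
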