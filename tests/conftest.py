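import numpy as np
import pytest

from psma_cua.economics import compare
from psma_cua.models import build_pair, load_parameters


@pytest.fixture(scope="session")
def params():
    return load_parameters()


@pytest.fixture(scope="session")
def base_case(params):
    """Base-case outcomes and comparisons for both models, computed once."""
    out = {}
    for model in ("I", "II"):
        iv, cp = build_pair(model, params)
        o_iv, o_cp = iv.outcome(), cp.outcome()
        out[model] = {
            "intervention": o_iv, "comparator": o_cp,
            "incremental": compare(o_iv, o_cp),
            "arms": (iv, cp),
        }
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
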