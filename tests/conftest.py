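import numpy as np
import pytest

from sulfgrowth import REFERENCE_PARAMS, ModelParams


@pytest.fixture(scope="session")
def reference_params() -> ModelParams:
    """The measured/inferred parameter set for RM11 met17Δ."""
    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def fixed_measured() -> dict:
    """The directly measured parameters held fixed during (r, k_s) inference."""
    return {"g_max": 0.26, "c": 3.0, "K": 1.6e8, "delta": 0.0}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
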