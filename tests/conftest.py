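import numpy as np
import pytest

from accuscan.error_model import ErrorModel
from accuscan.fixtures import generate_reference
from accuscan.substitution import VARIANT_TYPES


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def reference():
    """A small shared synthetic reference chromosome."""
    return {"chrS": generate_reference(20_000, gc=0.41, seed=11)}


@pytest.fixture
def uniform_em():
    return ErrorModel.uniform(4.2e-7)


@pytest.fixture
def typed_em():
    """Heterogeneous per-type error rates (C-T dominant, as after consensus)."""
    rates = dict(zip(VARIANT_TYPES, [2e-6, 3e-7, 5e-7, 2e-7, 8e-7, 1e-7]))
    return ErrorModel.from_rates(rates)
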