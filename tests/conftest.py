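import numpy as np
import pytest

from hcvnet.cohort import build_default_schema, default_outcome_model, null_outcome_model


@pytest.fixture(scope="session")
def schema():
    return build_default_schema()


@pytest.fixture(scope="session")
def null_model(schema):
    return null_outcome_model(schema)


@pytest.fixture(scope="session")
def planted_model(schema):
    return default_outcome_model(schema, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
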