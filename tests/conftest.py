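import numpy as np
import pandas as pd
import pytest

from hdoe.design import FactorSpace, ModelSpec, candidate_set


@pytest.fixture(scope="session")
def space5() -> FactorSpace:
    return FactorSpace.regular(5)


@pytest.fixture(scope="session")
def grid5(space5) -> pd.DataFrame:
    return candidate_set(space5)


@pytest.fixture(scope="session")
def full_quad5() -> ModelSpec:
    return ModelSpec.full_quadratic(5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
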