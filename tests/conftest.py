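import numpy as np
import pytest

from lesionmap.synthetic_data import (
    default_atlas_spec,
    default_cohort_spec,
    make_toy_atlas,
)


@pytest.fixture(scope="session")
def toy_atlas():
    return make_toy_atlas(default_atlas_spec())


@pytest.fixture(scope="session")
def small_atlas():
    return make_toy_atlas(default_atlas_spec(shape=(32, 32, 32)))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_cohort():
    return default_cohort_spec()
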