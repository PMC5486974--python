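import numpy as np
import pytest

from stimcnv import EnvironmentCondition, LocusConfig, ModelParams


@pytest.fixture
def cup1_locus():
    return LocusConfig("CUP1", copies=13, promoter_kind="copper_inducible")


@pytest.fixture
def gal_locus():
    return LocusConfig("PGAL1_HA", copies=17, promoter_kind="galactose_inducible")


@pytest.fixture
def model():
    return ModelParams()


@pytest.fixture
def plain_env():
    return EnvironmentCondition()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
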