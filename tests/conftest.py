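import numpy as np
import pytest
from hypothesis import settings

from mapcalib import CoarseGridSpec, SensorModel, TopographicMapSpec
from mapcalib.experiments import TASK1_K, TASK1_SIGMA, TASK1_DISTORTION

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def map_spec():
    return TopographicMapSpec(n_g=100, extent=1.5, dim=2)


@pytest.fixture(scope="session")
def coarse():
    return CoarseGridSpec(k=8, gp_cov=0.0352, dim=2)


@pytest.fixture(scope="session")
def task1_sensor():
    return SensorModel(K=TASK1_K, sigma_rf=TASK1_SIGMA)


@pytest.fixture(scope="session")
def task1_distortion():
    return TASK1_DISTORTION


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
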