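import numpy as np
import pytest

from taskconn.experiments import default_atlas
from taskconn.synthetic import EffectSpec, make_design
from taskconn.volume import VolumeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def atlas():
    return default_atlas()


@pytest.fixture
def small_design():
    return make_design(4, seed=7)


@pytest.fixture
def null_effects():
    return EffectSpec(delta_3way=0.0, delta_task=0.0, subject_sd=0.0,
                      noise_sd=0.0)


def make_series(data, voxel_size=2.0, tr=0.555):
    return VolumeSeries(data=np.asarray(data, dtype=float),
                        voxel_size_mm=np.full(3, voxel_size),
                        repetition_time_s=tr)


@pytest.fixture
def series_factory():
    return make_series
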