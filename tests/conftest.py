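import numpy as np
import pytest

from dynent import VoltageSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(values, rate=4.1, **kwargs) -> VoltageSeries:
    return VoltageSeries(np.asarray(values, dtype=float), rate, **kwargs)


@pytest.fixture
def gaussian_series(rng):
    return make_series(rng.standard_normal(5000))
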