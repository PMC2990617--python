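import numpy as np
import pytest

from hyperflux import (
    CELL_SCHEME,
    TUMOUR_SCHEME,
    ExchangeParameters,
    simulate_acquisition,
)
from hyperflux.model import PeakSeries


@pytest.fixture
def cell_scheme():
    return CELL_SCHEME


@pytest.fixture
def tumour_scheme():
    return TUMOUR_SCHEME


@pytest.fixture
def rng():
    return np.random.default_rng(20251)


def noiseless_series(k_fwd, scheme, m0_sub=15.0, **kwargs) -> PeakSeries:
    params = ExchangeParameters(k_fwd=k_fwd, m0_sub=m0_sub, **kwargs)
    return PeakSeries.from_trajectory(simulate_acquisition(params, scheme))


@pytest.fixture
def make_series():
    return noiseless_series
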