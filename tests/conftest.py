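import warnings

import numpy as np
import pandas as pd
import pytest

from kelpflux.environment import EnvSeries
from kelpflux.simulate import SimulationConfig


@pytest.fixture(autouse=True)
def _quiet_salinity_warnings():
    # synthetic estuarine salinities near the low end of the scale can brush
    # the PSS-78 validity boundary; the warning itself is tested explicitly
    from kelpflux.environment import SalinityRangeWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SalinityRangeWarning)
        yield


@pytest.fixture
def config():
    return SimulationConfig(seed=1)


@pytest.fixture
def minute_env():
    """A deterministic one-day, 1-min environment series for aggregation tests."""
    idx = pd.date_range("2022-07-10", periods=24 * 60, freq="1min")
    minutes = np.arange(idx.size)
    return EnvSeries(
        pd.DataFrame(
            {
                "temperature": 9.0 + np.sin(2 * np.pi * minutes / (24 * 60)),
                "irradiance_par": np.abs(np.cos(2 * np.pi * minutes / (24 * 60))) * 100,
            },
            index=idx,
        )
    )
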