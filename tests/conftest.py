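import numpy as np
import pandas as pd
import pytest

from airtails.qc import SiteSeries


def hourly_series(values, *, site="t0001", pollutant="no2", lod=None, **meta):
    """Build a SiteSeries with consecutive hourly UTC timestamps."""
    values = np.asarray(values, dtype=float)
    ts = pd.date_range("2019-01-01", periods=len(values), freq="h", tz="UTC")
    return SiteSeries(site_code=site, pollutant=pollutant, timestamps=ts,
                      values=values, lod=lod, **meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
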