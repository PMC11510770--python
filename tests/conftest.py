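import numpy as np
import pandas as pd
import pytest

from portair import (
    MetSeries,
    SiteMeta,
    TimeSeries,
    generate_network,
)
from portair.synth import ScenarioConfig, single_site_scenario


def minute_series(values, start="2023-10-21", site="s1", pollutant="NO", tz="Asia/Shanghai"):
    idx = pd.date_range(pd.Timestamp(start, tz=tz), periods=len(values), freq="min")
    return TimeSeries(site, pollutant, pd.Series(np.asarray(values, float), index=idx))


def hour_series(values, start="2023-10-21", site="s1", pollutant="NO", tz="Asia/Shanghai"):
    idx = pd.date_range(pd.Timestamp(start, tz=tz), periods=len(values), freq="h")
    return TimeSeries(site, pollutant, pd.Series(np.asarray(values, float), index=idx), "hour")


def met_for(index, temp=20.0, rh=60.0, cadence="minute"):
    return MetSeries(
        pd.Series(np.broadcast_to(temp, len(index)).astype(float), index=index),
        pd.Series(np.broadcast_to(rh, len(index)).astype(float), index=index),
        cadence,
    )


@pytest.fixture(scope="session")
def tiny_bundle():
    """Four sites (one per zone, one colocated), four days — fast end-to-end."""
    cfg = ScenarioConfig(
        n_days=4,
        seed=1234,
        sites=[
            SiteMeta("a1", "OA", "PCT2", colocated=True),
            SiteMeta("a2", "SR", "PCT2"),
            SiteMeta("a3", "BA", "PCT4"),
            SiteMeta("a4", "OR", "PCT4"),
        ],
    )
    return generate_network(cfg)


@pytest.fixture(scope="session")
def single_site_bundle():
    """One berthing-area-rate site over six days, used for recovery checks."""
    return generate_network(single_site_scenario(seed=7, rate_per_hour=2.2, n_days=6))
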