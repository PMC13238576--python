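import numpy as np
import pandas as pd
import pytest

from ntheat import ehf, synthetic
from ntheat.climate import RegionDailySeries


@pytest.fixture(scope="session")
def tiny_frames():
    """In-memory 'tiny' fixture: 2 regions, 2 analysis years, seed 7."""
    return synthetic.build_fixture_frames("tiny", seed=7)


@pytest.fixture(scope="session")
def warm_series():
    """One region, four years of seasonal weather with injected heat runs."""
    cfg = synthetic.WeatherGenConfig(n_regions=1, start="1996-01-01", end="1999-12-31")
    weather, episodes = synthetic.simulate_weather(cfg, np.random.default_rng(11))
    series = synthetic.weather_to_series(weather)["R000"]
    return series, episodes


@pytest.fixture()
def ehf_params():
    return ehf.EHFParams(ref_start=1996, ref_end=1997)


@pytest.fixture()
def flat_series():
    """A constant-temperature region series (degenerate climate)."""
    dates = pd.date_range("1996-01-01", "1997-12-31", freq="D")
    return RegionDailySeries(
        region_id="FLAT",
        dates=dates,
        tmean_c=np.full(len(dates), 25.0),
        rh_pct=np.full(len(dates), 50.0),
    )
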