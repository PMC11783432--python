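import pandas as pd
import pytest

from clearwing.degree_days import DegreeDayConfig, accumulate_cdd, daily_series_dd
from clearwing.fitting import to_cumulative_proportions
from clearwing.reference import REFERENCE_PARAMS
from clearwing.synthetic import (
    TrapGenConfig,
    WeatherGenConfig,
    gen_trap_catches,
    gen_weather,
)


@pytest.fixture(scope="session")
def ref_params():
    """Published reference parameter set for S. bicingulata."""
    return REFERENCE_PARAMS


@pytest.fixture
def constant_weather():
    """Constant 14/14 °C weather, Oct 2013 through Dec 2014 (10 DD/day at LDT 4)."""
    dates = pd.date_range("2013-10-01", "2014-12-31", freq="D")
    return pd.DataFrame(
        {"location_id": "const", "date": dates, "tmin": 14.0, "tmax": 14.0}
    )


def make_site_year_points(n_sites=24, total=300, interval=7, seed=7000,
                          noise="poisson", params=REFERENCE_PARAMS):
    """Pooled (cdd, cum_prop) points from synthetic weather + trap catches."""
    cfg = DegreeDayConfig()
    frames = []
    for i in range(n_sites):
        weather = gen_weather(WeatherGenConfig(seed=seed + i, location_id=f"s{i}"))
        acc = accumulate_cdd(daily_series_dd(weather, cfg), 2014, cfg)
        traps = gen_trap_catches(
            TrapGenConfig(true_params=params, total=total, interval_days=interval,
                          noise=noise, seed=seed + 1000 + i, site=f"s{i}"),
            acc,
        )
        frames.append(to_cumulative_proportions(traps, acc))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def pooled_poisson_points():
    """24 Poisson site-years of 300 moths each, weekly sampling, fixed seed."""
    return make_site_year_points()
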