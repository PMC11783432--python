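"""Synthetic weather, trap-catch, and station-network generators.

The generators emulate the statistical structure of the pipeline's real
inputs — temperate-zone station weather (seasonal sinusoid plus Gaussian
noise) and pheromone-trap counts scattered around a two-peaked cumulative
emergence curve — so that every stage can be exercised end to end without
external downloads.  All generators are pure functions of (config, seed):
reruns are bit-identical.

Defaults describe a southern-Korea-like temperate climate (annual mean
13 °C, seasonal amplitude 12 °C, warmest day around July 29, diurnal range
9 °C, day-to-day noise SD 2.5 °C), which accumulates roughly 3400–3600
degree-days per year above a 4 °C threshold — enough for both flight peaks
of a bivoltine clearwing moth to fall within a season.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .degree_days import DegreeDaySeries
from .fitting import TrapCatchSeries
from .mapping import StationRecord
from .model import TwoPeakWeibullParams, evaluate

__all__ = [
    "WeatherGenConfig",
    "TrapGenConfig",
    "gen_weather",
    "gen_trap_catches",
    "gen_station_network",
]

DAYS_PER_YEAR = 365.25  # seasonal period; avoids phase drift over multi-year runs


@dataclass(frozen=True)
class WeatherGenConfig:
    """Sinusoid-plus-noise daily weather generator settings."""

    annual_mean: float = 13.0        # °C
    amplitude: float = 12.0          # °C, seasonal half-range
    warmest_doy: int = 210           # day-of-year of the warmest date
    diurnal_range: float = 9.0       # °C, tmax - tmin
    noise_sd: float = 2.5            # °C, day-to-day Gaussian noise on the mean
    start: dt.date = dt.date(2013, 10, 1)
    end: dt.date = dt.date(2014, 12, 31)
    seed: int = 0
    location_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.diurnal_range < 0:
            raise ValueError("diurnal_range must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.end < self.start:
            raise ValueError("end date before start date")


@dataclass(frozen=True)
class TrapGenConfig:
    """Trap-catch generator: counts around a true emergence curve."""

    true_params: TwoPeakWeibullParams
    total: int = 300                 # moths per site-year
    interval_days: int = 7           # sampling interval
    noise: str = "poisson"           # poisson | multinomial | none
    seed: int = 0
    site: str = "synthetic"

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total must be positive")
        if self.interval_days < 1:
            raise ValueError("interval_days must be >= 1")
        if self.noise not in ("poisson", "multinomial", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")


def gen_weather(cfg: WeatherGenConfig) -> pd.DataFrame:
    """Daily Tmin/Tmax with a seasonal sinusoidal mean and Gaussian noise.

    tmean(d) = mean + amplitude * cos(2*pi*(d - warmest)/365.25) + N(0, sd);
    tmax/tmin are tmean +/- diurnal_range/2 (so tmax >= tmin always holds).
    """
    rng = np.random.default_rng(cfg.seed)
    dates = pd.date_range(cfg.start, cfg.end, freq="D")
    warmest_ordinal = dt.date(cfg.start.year, 1, 1).toordinal() + cfg.warmest_doy - 1
    d = np.array([ts.toordinal() for ts in dates.date], dtype=float)
    tmean = (
        cfg.annual_mean
        + cfg.amplitude * np.cos(2 * np.pi * (d - warmest_ordinal) / DAYS_PER_YEAR)
        + rng.normal(0.0, cfg.noise_sd, size=len(dates))
    )
    half = cfg.diurnal_range / 2.0
    return pd.DataFrame(
        {
            "location_id": cfg.location_id,
            "date": dates,
            "tmin": tmean - half,
            "tmax": tmean + half,
        }
    )


def gen_trap_catches(cfg: TrapGenConfig, dd: DegreeDaySeries) -> TrapCatchSeries:
    """Trap counts at regular sampling dates along a degree-day series.

    The expected catch in each sampling interval is
    total * [P(cdd_end) - P(cdd_start)] under the true parameters, where
    P(cdd_start) of the first interval is P at zero accumulation.  Noise:

    * ``none`` — counts are differences of the rounded expected cumulative
      totals (so cumulative proportions match P within 1/total rounding);
    * ``poisson`` — independent Poisson counts per interval (open total);
    * ``multinomial`` — the season total is fixed at cfg.total and spread
      over intervals with probabilities proportional to the increments.
    """
    if dd.cdd is None:
        raise ValueError("degree-day series must be accumulated (have cdd)")
    rng = np.random.default_rng(cfg.seed)
    idx = np.arange(0, len(dd.dates), cfg.interval_days)
    if len(idx) < 2:
        raise ValueError("degree-day series too short for the sampling interval")
    dates = dd.dates[idx]
    p_cum = evaluate(cfg.true_params, dd.cdd[idx])
    year = int(dates[-1].year)

    if cfg.noise == "none":
        cum_counts = np.floor(cfg.total * p_cum + 0.5)
        counts = np.diff(cum_counts, prepend=0.0).astype(int)
    elif cfg.noise == "poisson":
        expected = cfg.total * np.diff(p_cum, prepend=0.0)
        counts = rng.poisson(np.maximum(expected, 0.0))
    else:  # multinomial: condition on the season total
        inc = np.maximum(np.diff(p_cum, prepend=0.0), 0.0)
        if inc.sum() <= 0:
            raise ValueError("emergence curve is flat over the sampled period")
        counts = rng.multinomial(cfg.total, inc / inc.sum())
    return TrapCatchSeries(cfg.site, year, dates, counts)


def gen_station_network(
    n: int,
    bbox: tuple[float, float, float, float],
    weather_cfg: WeatherGenConfig,
    lapse_per_deg_lat: float = 0.0,
    seed: int = 0,
) -> list[StationRecord]:
    """Random station network with a latitudinal temperature gradient.

    Stations are placed uniformly in `bbox` = (lat_min, lat_max, lon_min,
    lon_max); each station's weather comes from ``gen_weather`` with the
    annual mean offset by lapse_per_deg_lat * (lat - bbox centre latitude).
    """
    if n < 1:
        raise ValueError("need at least one station")
    lat_min, lat_max, lon_min, lon_max = bbox
    rng = np.random.default_rng(seed)
    lats = rng.uniform(lat_min, lat_max, size=n)
    lons = rng.uniform(lon_min, lon_max, size=n)
    lat_center = 0.5 * (lat_min + lat_max)
    stations = []
    for i in range(n):
        cfg_i = replace(
            weather_cfg,
            annual_mean=weather_cfg.annual_mean
            + lapse_per_deg_lat * (lats[i] - lat_center),
            seed=int(weather_cfg.seed + 1000 * i + 1),
            location_id=f"station{i:03d}",
        )
        stations.append(
            StationRecord(
                station_id=cfg_i.location_id,
                latitude=float(lats[i]),
                longitude=float(lons[i]),
                weather=gen_weather(cfg_i),
            )
        )
    return stations
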