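"""Degree-day accumulation from daily Tmin/Tmax.

Implements the single-sine method: each day's temperature course is modelled
as one full sine wave oscillating between Tmin and Tmax, and the area above a
lower developmental threshold (LDT) is integrated analytically.  Degree-days
are accumulated from a configurable biofix date (by default October 1 of the
year preceding the flight season, since overwintering larvae resume
development whenever autumn and winter temperatures exceed the threshold).

No upper developmental threshold is applied: accumulation is uncapped above
the LDT.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DailyWeather",
    "DegreeDayConfig",
    "DegreeDaySeries",
    "single_sine_dd",
    "daily_series_dd",
    "accumulate_cdd",
    "date_at_cdd",
    "weather_to_frame",
    "validate_weather_frame",
]


@dataclass(frozen=True)
class DailyWeather:
    """One day of station weather: Tmin/Tmax in degrees Celsius."""

    location_id: str
    date: dt.date
    tmin: float
    tmax: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tmin) and np.isfinite(self.tmax)):
            raise ValueError(f"non-finite temperature on {self.date}")
        if self.tmax < self.tmin:
            raise ValueError(
                f"tmax ({self.tmax}) < tmin ({self.tmin}) on {self.date}"
            )


@dataclass(frozen=True)
class DegreeDayConfig:
    """Accumulation settings: threshold and biofix.

    Parameters
    ----------
    ldt
        Lower developmental threshold in °C.  Default 4.0 °C, the threshold
        of the allied dogwood borer (*Synanthedon scitula*), adopted for
        *S. bicingulata* because both overwinter as larvae inside trunks
        without obligatory diapause.
    biofix_month, biofix_day
        Calendar day at which accumulation starts.  Default October 1.
    biofix_in_previous_year
        If true (default) the biofix falls in the year before the flight
        season, so winter warmth counts toward spring emergence.
    fill_gaps
        If true, missing days inside the window are filled by linear
        interpolation of tmin/tmax (logged).  Default false: gaps are a
        hard error.
    """

    ldt: float = 4.0
    biofix_month: int = 10
    biofix_day: int = 1
    biofix_in_previous_year: bool = True
    fill_gaps: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.ldt):
            raise ValueError("ldt must be finite")
        # validity check via a leap year (accepts Feb 29)
        dt.date(2000, self.biofix_month, self.biofix_day)

    def biofix_date(self, target_year: int) -> dt.date:
        year = target_year - 1 if self.biofix_in_previous_year else target_year
        return dt.date(year, self.biofix_month, self.biofix_day)


@dataclass
class DegreeDaySeries:
    """Dated daily degree-days, optionally with the running total (CDD)."""

    location_id: str
    dates: pd.DatetimeIndex
    daily_dd: np.ndarray
    cdd: np.ndarray | None = None
    biofix: dt.date | None = None

    def __post_init__(self) -> None:
        self.daily_dd = np.asarray(self.daily_dd, dtype=float)
        if len(self.dates) != len(self.daily_dd):
            raise ValueError("dates and daily_dd length mismatch")
        if self.cdd is not None:
            self.cdd = np.asarray(self.cdd, dtype=float)
            if len(self.cdd) != len(self.dates):
                raise ValueError("cdd length mismatch")

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        data = {"date": self.dates, "daily_dd": self.daily_dd}
        if self.cdd is not None:
            data["cdd"] = self.cdd
        return pd.DataFrame(data)

    def cdd_at(self, date: dt.date | pd.Timestamp) -> float:
        """End-of-day cumulative degree-days on `date`."""
        if self.cdd is None:
            raise ValueError("series has no cumulative degree-days; accumulate first")
        ts = pd.Timestamp(date)
        idx = self.dates.get_indexer([ts])
        if idx[0] < 0:
            raise KeyError(f"date {date} not in degree-day series")
        return float(self.cdd[idx[0]])


def single_sine_dd(tmin, tmax, ldt):
    """Degree-days for one day by the single-sine method.

    The day's temperature is T(t) = Tm + A·sin(t) over one full period,
    with Tm = (tmax+tmin)/2 and A = (tmax−tmin)/2; the result is the mean
    daily excess above `ldt`:

    * tmax ≤ ldt            → 0
    * tmin ≥ ldt            → Tm − ldt
    * threshold intercepted → (1/π)[(Tm−ldt)(π/2−θ) + A·cos θ],
      θ = arcsin((ldt−Tm)/A)

    Accepts scalars or broadcastable arrays; returns the same shape.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    ldt = np.asarray(ldt, dtype=float)
    if not (np.all(np.isfinite(tmin)) and np.all(np.isfinite(tmax)) and np.all(np.isfinite(ldt))):
        raise ValueError("non-finite input to single_sine_dd")
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin in single_sine_dd input")

    tm = (tmax + tmin) / 2.0
    amp = (tmax - tmin) / 2.0

    above = tmin >= ldt           # whole day above threshold
    below = tmax <= ldt           # whole day at or below threshold
    mid = ~(above | below)        # sine crosses the threshold

    out = np.where(above, tm - ldt, 0.0)
    if np.any(mid):
        # amp > 0 strictly on this branch (tmin < ldt < tmax)
        ratio = np.where(mid, (ldt - tm) / np.where(mid, amp, 1.0), 0.0)
        theta = np.arcsin(np.clip(ratio, -1.0, 1.0))
        dd_mid = (1.0 / np.pi) * ((tm - ldt) * (np.pi / 2.0 - theta) + amp * np.cos(theta))
        out = np.where(mid, dd_mid, out)
    out = np.maximum(out, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def weather_to_frame(weather: Iterable[DailyWeather]) -> pd.DataFrame:
    """Assemble DailyWeather records into the canonical weather frame."""
    rows = [(w.location_id, pd.Timestamp(w.date), w.tmin, w.tmax) for w in weather]
    return pd.DataFrame(rows, columns=["location_id", "date", "tmin", "tmax"])


def validate_weather_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Schema- and invariant-check a weather frame; returns it date-typed.

    Requires columns date, tmin, tmax (location_id optional); dates strictly
    increasing; tmax ≥ tmin everywhere; finite temperatures.
    """
    missing = {"date", "tmin", "tmax"} - set(frame.columns)
    if missing:
        raise ValueError(f"weather frame missing columns: {sorted(missing)}")
    frame = frame.copy()
    frame["date"] = pd.to_datetime(frame["date"])
    if len(frame) == 0:
        return frame
    if not frame["date"].is_monotonic_increasing or frame["date"].duplicated().any():
        raise ValueError("weather dates must be strictly increasing")
    bad = ~(np.isfinite(frame["tmin"]) & np.isfinite(frame["tmax"]))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-finite temperature at row {row} ({frame['date'].iloc[row].date()})")
    viol = frame["tmax"] < frame["tmin"]
    if viol.any():
        row = int(np.flatnonzero(viol)[0])
        raise ValueError(
            f"tmax < tmin at row {row} ({frame['date'].iloc[row].date()})"
        )
    return frame


def _check_contiguous(dates: pd.DatetimeIndex, cfg: DegreeDayConfig,
                      frame: pd.DataFrame) -> pd.DataFrame:
    """Detect calendar gaps; fill by interpolation if cfg allows, else raise."""
    if len(dates) < 2:
        return frame
    full = pd.date_range(dates[0], dates[-1], freq="D")
    if len(full) == len(dates):
        return frame
    missing = full.difference(dates)
    if not cfg.fill_gaps:
        raise ValueError(
            "weather series has missing days: "
            f"{missing[0].date()} .. {missing[-1].date()} "
            f"({len(missing)} day(s) absent)"
        )
    logger.info("gap-filling %d missing weather day(s) by linear interpolation", len(missing))
    filled = frame.set_index("date").reindex(full)
    filled[["tmin", "tmax"]] = filled[["tmin", "tmax"]].interpolate(method="time")
    if "location_id" in filled.columns:
        filled["location_id"] = filled["location_id"].ffill().bfill()
    return filled.rename_axis("date").reset_index()


def daily_series_dd(
    weather: pd.DataFrame | Sequence[DailyWeather],
    cfg: DegreeDayConfig = DegreeDayConfig(),
) -> DegreeDaySeries:
    """Daily degree-days (no accumulation) for a contiguous weather series."""
    if not isinstance(weather, pd.DataFrame):
        weather = weather_to_frame(weather)
    frame = validate_weather_frame(weather)
    loc = str(frame["location_id"].iloc[0]) if ("location_id" in frame.columns and len(frame)) else ""
    if len(frame) == 0:
        return DegreeDaySeries(loc, pd.DatetimeIndex([]), np.array([]))
    dates = pd.DatetimeIndex(frame["date"])
    frame = _check_contiguous(dates, cfg, frame)
    dates = pd.DatetimeIndex(frame["date"])
    dd = single_sine_dd(frame["tmin"].to_numpy(), frame["tmax"].to_numpy(), cfg.ldt)
    return DegreeDaySeries(loc, dates, np.atleast_1d(dd))


def accumulate_cdd(
    series: DegreeDaySeries,
    target_year: int,
    cfg: DegreeDayConfig = DegreeDayConfig(),
) -> DegreeDaySeries:
    """Running degree-day total from the biofix for `target_year`.

    The biofix day's own degree-days are included (cdd starts at that day's
    daily value); days before the biofix are dropped.
    """
    biofix = pd.Timestamp(cfg.biofix_date(target_year))
    if len(series) == 0 or series.dates[0] > biofix:
        first = series.dates[0].date() if len(series) else None
        raise ValueError(
            f"degree-day series starts {first}, after the biofix {biofix.date()}"
        )
    if series.dates[-1] < biofix:
        raise ValueError(
            f"degree-day series ends {series.dates[-1].date()}, before the biofix {biofix.date()}"
        )
    mask = series.dates >= biofix
    dates = series.dates[mask]
    daily = series.daily_dd[mask]
    return DegreeDaySeries(series.location_id, dates, daily,
                           cdd=np.cumsum(daily), biofix=biofix.date())


def date_at_cdd(series: DegreeDaySeries, threshold: float) -> tuple[dt.date, int]:
    """First date whose end-of-day CDD reaches `threshold`.

    Returns the calendar date and its 1-based day-of-year.  Raises if the
    series never accumulates that much, stating the maximum attained.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if series.cdd is None:
        raise ValueError("series has no cumulative degree-days; accumulate first")
    idx = int(np.searchsorted(series.cdd, threshold, side="left"))
    if idx >= len(series.cdd):
        raise ValueError(
            f"threshold {threshold:.2f} DD never reached; "
            f"series attains at most {series.cdd[-1]:.2f} DD"
        )
    ts = series.dates[idx]
    return ts.date(), int(ts.dayofyear)
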