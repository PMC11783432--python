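"""Percentile-based validation of emergence predictions.

Observed trap-catch series are split into the two flight periods, empirical
10/30/50/70/90 % occurrence dates are interpolated within each peak, and
compared with the model's predicted dates (within-peak percentile CDDs
converted to calendar days through the degree-day series).  The same
machinery evaluates the RDA benchmark (fixed 350 / 1895 DD thresholds at
LDT 8.1 °C from January 1).
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .degree_days import (
    DegreeDayConfig,
    DegreeDaySeries,
    accumulate_cdd,
    daily_series_dd,
    date_at_cdd,
)
from .fitting import TrapCatchSeries
from .model import TwoPeakWeibullParams, invert_within_peak
from .reference import RdaBenchmark

__all__ = [
    "split_peaks",
    "empirical_percentile_days",
    "predicted_percentile_days",
    "deviation_summary",
    "rda_predicted_days",
    "DEFAULT_PERCENTS",
]

DEFAULT_PERCENTS = (10, 30, 50, 70, 90)


def split_peaks(
    series: TrapCatchSeries,
    split_date: dt.date | None = None,
) -> tuple[TrapCatchSeries, TrapCatchSeries]:
    """Assign catches to the first or second flight period.

    The two dominant local maxima of a 3-point moving average locate the
    flight peaks (dominance ranked by peak prominence, so two jittery
    spikes inside one flight period are not mistaken for two flights); the
    split falls on the date of minimum raw catch in the trough between
    them (earliest date on ties).  Records up to and including the split
    date form the first-peak series.  Pass `split_date` to override the
    automatic rule.
    """
    from scipy.signal import find_peaks, peak_prominences

    counts = series.counts.astype(float)
    n = len(counts)
    if split_date is None:
        if n < 5:
            raise ValueError(
                "series too short to locate two flight peaks; "
                "supply an explicit split_date"
            )
        # centered 3-point moving average, truncated at the edges
        ma = np.array(
            [counts[max(0, i - 1) : i + 2].mean() for i in range(n)]
        )
        maxima, _ = find_peaks(ma)
        if len(maxima) < 2:
            raise ValueError(
                "could not detect two separated activity peaks; "
                "supply an explicit split_date"
            )
        prom = peak_prominences(ma, maxima)[0]
        top_two = maxima[np.argsort(prom, kind="stable")[::-1][:2]]
        left, right = int(top_two.min()), int(top_two.max())
        if right - left < 2:
            raise ValueError(
                "detected peaks are adjacent (no trough); "
                "supply an explicit split_date"
            )
        trough = counts[left + 1 : right]
        split_idx = left + 1 + int(np.argmin(trough))  # argmin ties -> earliest
    else:
        ts = pd.Timestamp(split_date)
        split_idx = int(np.searchsorted(series.dates, ts, side="right")) - 1
        if split_idx < 0 or split_idx >= n - 1:
            raise ValueError(f"split date {split_date} outside the trap series")

    first = TrapCatchSeries(
        series.site, series.year,
        series.dates[: split_idx + 1], series.counts[: split_idx + 1],
    )
    second = TrapCatchSeries(
        series.site, series.year,
        series.dates[split_idx + 1 :], series.counts[split_idx + 1 :],
    )
    return first, second


def empirical_percentile_days(
    series: TrapCatchSeries,
    percents=DEFAULT_PERCENTS,
) -> dict[int, int]:
    """Observed occurrence day-of-year at each target percent of one peak.

    Cumulative proportions use the peak's own total as denominator.  Each
    target is read off the line through the two sampling points bracketing
    it (exact two-point interpolation); fractional days round half-up.
    """
    total = series.total
    if total <= 0:
        raise ValueError(f"no catches in {series.site} {series.year} peak series")
    cum = np.cumsum(series.counts) / total
    doy = series.dates.dayofyear.to_numpy(dtype=float)
    out: dict[int, int] = {}
    for percent in percents:
        p = percent / 100.0
        hit = np.flatnonzero(np.isclose(cum, p, atol=1e-12))
        if len(hit):
            out[percent] = int(doy[hit[0]])
            continue
        if p < cum[0] or p > cum[-1]:
            raise ValueError(
                f"{percent}% outside the observed cumulative range "
                f"[{cum[0]:.3f}, {cum[-1]:.3f}] for {series.site} {series.year}"
            )
        hi = int(np.searchsorted(cum, p, side="left"))
        lo = hi - 1
        frac = (p - cum[lo]) / (cum[hi] - cum[lo])
        day = doy[lo] + frac * (doy[hi] - doy[lo])
        out[percent] = int(np.floor(day + 0.5))  # round half-up
    return out


def predicted_percentile_days(
    params: TwoPeakWeibullParams,
    weather: pd.DataFrame,
    year: int,
    percents=DEFAULT_PERCENTS,
    cfg: DegreeDayConfig = DegreeDayConfig(),
) -> dict[int, dict[int, int]]:
    """Model-predicted day-of-year per peak per percent.

    The within-peak percentile CDD is inverted from the fitted curve and
    converted to the first calendar date reaching that CDD.
    Returns {peak: {percent: doy}}.
    """
    daily = daily_series_dd(weather, cfg)
    acc = accumulate_cdd(daily, year, cfg)
    out: dict[int, dict[int, int]] = {}
    for peak in (1, 2):
        out[peak] = {}
        for percent in percents:
            dd_target = invert_within_peak(params, peak, percent / 100.0)
            _, doy = date_at_cdd(acc, dd_target)
            out[peak][percent] = doy
    return out


def deviation_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sample SD of |observed − predicted| days per peak × percent.

    `table` needs columns peak, percent, observed_doy, predicted_doy.
    Returns a frame indexed by (peak, percent) with mean_abs_dev,
    sd_abs_dev (ddof=1; NaN for single-row cells) and n.
    """
    t = table.copy()
    t["abs_dev"] = (t["observed_doy"] - t["predicted_doy"]).abs().astype(float)
    grouped = t.groupby(["peak", "percent"])["abs_dev"]
    out = grouped.agg(mean_abs_dev="mean", sd_abs_dev=lambda s: s.std(ddof=1), n="count")
    return out


def rda_predicted_days(
    weather: pd.DataFrame,
    year: int,
    benchmark: RdaBenchmark = RdaBenchmark(),
) -> tuple[int, int]:
    """Peak days-of-year under the RDA fixed-threshold benchmark.

    Accumulation runs through the same single-sine engine, with the
    benchmark's own threshold (8.1 °C) and same-year January 1 biofix.
    """
    cfg = DegreeDayConfig(
        ldt=benchmark.ldt,
        biofix_month=benchmark.biofix_month,
        biofix_day=benchmark.biofix_day,
        biofix_in_previous_year=False,
    )
    acc = accumulate_cdd(daily_series_dd(weather, cfg), year, cfg)
    _, first = date_at_cdd(acc, benchmark.first_peak_dd)
    _, second = date_at_cdd(acc, benchmark.second_peak_dd)
    return first, second
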