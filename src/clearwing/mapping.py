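"""Gridded peak-timing maps from station or scenario temperatures.

Station Tmin/Tmax series are interpolated onto a regular latitude/longitude
grid by inverse-distance weighting (IDW), degree-days are accumulated per
cell with the single-sine engine, and the day-of-year at which each cell
first reaches the 50 % occurrence CDD of each flight peak (beta1 and
beta1 + delta_beta) is mapped.  Differencing two maps (e.g. a warming
scenario minus a baseline) quantifies the phenological shift in days.

Grids are plain ``xarray`` objects: a Dataset with ``tmin``/``tmax`` over
(time, y, x) for temperatures, and a DataArray over (peak, y, x) for
timing maps.  Georeference (origin, cell size, CRS label) travels in attrs
and is never reprojected.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .degree_days import DegreeDayConfig, single_sine_dd
from .model import TwoPeakWeibullParams, peak_cdds

logger = logging.getLogger(__name__)

__all__ = [
    "StationRecord",
    "GridSpec",
    "idw_interpolate",
    "peak_timing_map",
    "timing_difference",
    "great_circle_km",
]

EARTH_RADIUS_KM = 6371.0088  # WGS84 mean radius


@dataclass
class StationRecord:
    """A weather station: coordinates plus its daily Tmin/Tmax frame."""

    station_id: str
    latitude: float
    longitude: float
    weather: pd.DataFrame  # columns date, tmin, tmax

    def __post_init__(self) -> None:
        if not (-90 <= self.latitude <= 90 and -180 <= self.longitude <= 360):
            raise ValueError(f"invalid coordinates for station {self.station_id}")


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid: north-west origin, square cells in degrees."""

    nrows: int
    ncols: int
    lat_origin: float   # latitude of the grid's northern edge
    lon_origin: float   # longitude of the grid's western edge
    cell_size: float    # degrees
    crs: str = "EPSG:4326"

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) arrays of shape (nrows, ncols), row 0 northmost."""
        lats = self.lat_origin - (np.arange(self.nrows) + 0.5) * self.cell_size
        lons = self.lon_origin + (np.arange(self.ncols) + 0.5) * self.cell_size
        return np.meshgrid(lats, lons, indexing="ij")


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine distance on the WGS84 mean sphere, in km (broadcasts)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def idw_interpolate(
    stations: list[StationRecord],
    grid_spec: GridSpec,
    power: float = 2.0,
    k: int | None = None,
) -> xr.Dataset:
    """Inverse-distance-weighted daily Tmin/Tmax fields on a regular grid.

    Per cell and day, the value is the d^(-power)-weighted mean over the k
    nearest stations by great-circle distance (all stations by default).
    A cell whose centre coincides with a station (< 1 m) takes that
    station's value exactly.
    """
    if not stations:
        raise ValueError("at least one station is required")
    if power <= 0:
        raise ValueError("power must be positive")
    dates = pd.DatetimeIndex(stations[0].weather["date"])
    for s in stations[1:]:
        if not dates.equals(pd.DatetimeIndex(s.weather["date"])):
            raise ValueError(f"station {s.station_id} covers a different period")

    lat_c, lon_c = grid_spec.cell_centers()
    ncell = grid_spec.nrows * grid_spec.ncols
    nsta = len(stations)
    dist = np.empty((ncell, nsta))
    for j, s in enumerate(stations):
        dist[:, j] = great_circle_km(lat_c.ravel(), lon_c.ravel(), s.latitude, s.longitude)

    k_eff = nsta if k is None else min(max(k, 1), nsta)
    weights = np.zeros((ncell, nsta))
    # nearest-k mask per cell
    nearest = np.argsort(dist, axis=1)[:, :k_eff]
    rows = np.repeat(np.arange(ncell), k_eff)
    sel = np.zeros_like(dist, dtype=bool)
    sel[rows, nearest.ravel()] = True

    coincident = dist < 1e-3  # < 1 m
    with np.errstate(divide="ignore"):
        w = np.where(sel, dist ** (-power), 0.0)
    hit = coincident.any(axis=1)
    if hit.any():
        w[hit] = 0.0
        first_hit = np.argmax(coincident[hit], axis=1)
        w[np.flatnonzero(hit), first_hit] = 1.0
    weights = w / w.sum(axis=1, keepdims=True)

    tmin_sta = np.column_stack([s.weather["tmin"].to_numpy(dtype=float) for s in stations])
    tmax_sta = np.column_stack([s.weather["tmax"].to_numpy(dtype=float) for s in stations])
    shape = (len(dates), grid_spec.nrows, grid_spec.ncols)
    tmin = (tmin_sta @ weights.T).reshape(shape)
    tmax = (tmax_sta @ weights.T).reshape(shape)

    return xr.Dataset(
        {
            "tmin": (("time", "y", "x"), tmin),
            "tmax": (("time", "y", "x"), tmax),
        },
        coords={
            "time": dates,
            "lat": (("y", "x"), lat_c),
            "lon": (("y", "x"), lon_c),
        },
        attrs={
            "lat_origin": grid_spec.lat_origin,
            "lon_origin": grid_spec.lon_origin,
            "cell_size": grid_spec.cell_size,
            "crs": grid_spec.crs,
            "idw_power": power,
            "idw_k": k_eff,
        },
    )


def peak_timing_map(
    grid: xr.Dataset,
    params: TwoPeakWeibullParams,
    cfg: DegreeDayConfig = DegreeDayConfig(),
    target_year: int | None = None,
    climate_label: str = "",
) -> xr.DataArray:
    """Day-of-year maps of the 50 % occurrence of each flight peak.

    Degree-days are accumulated per cell from the biofix; each cell records
    the day-of-year at which its CDD first reaches beta1 (peak 1) and
    beta1 + delta_beta (peak 2).  Cells never reaching a threshold are NaN
    (their count is logged).  `target_year` defaults to the year of the
    grid's last day.
    """
    times = pd.DatetimeIndex(grid["time"].values)
    if target_year is None:
        target_year = int(times[-1].year)
    biofix = pd.Timestamp(cfg.biofix_date(target_year))
    if not (times[0] <= biofix <= times[-1]):
        raise ValueError(
            f"grid period {times[0].date()}..{times[-1].date()} does not include "
            f"the biofix {biofix.date()}"
        )

    sub = grid.sel(time=slice(biofix, None))
    tmin = sub["tmin"].values
    tmax = sub["tmax"].values
    daily = single_sine_dd(tmin, tmax, cfg.ldt)  # (time, y, x)
    cdd = np.cumsum(daily, axis=0)
    doys = pd.DatetimeIndex(sub["time"].values).dayofyear.to_numpy()

    thresholds = peak_cdds(params)
    layers = []
    for thr in thresholds:
        reached = cdd >= thr
        first = reached.argmax(axis=0)            # 0 where never reached too
        ok = reached.any(axis=0)
        layer = np.where(ok, doys[first], np.nan).astype(float)
        n_missing = int((~ok).sum())
        if n_missing:
            logger.info(
                "%d cell(s) never reach %.1f DD within the grid period",
                n_missing, thr,
            )
        layers.append(layer)

    out = xr.DataArray(
        np.stack(layers),
        dims=("peak", "y", "x"),
        coords={"peak": [1, 2], "lat": grid["lat"], "lon": grid["lon"]},
        name="peak_doy",
        attrs={
            **grid.attrs,
            "params": params.as_dict(),
            "ldt": cfg.ldt,
            "biofix": str(biofix.date()),
            "target_year": target_year,
            "climate_label": climate_label,
        },
    )
    return out


def timing_difference(map_a: xr.DataArray, map_b: xr.DataArray) -> xr.DataArray:
    """Cellwise day difference map_a − map_b; NaN propagates.

    Both maps must share grid geometry and peak layers.
    """
    if map_a.shape != map_b.shape or not np.array_equal(
        map_a["peak"].values, map_b["peak"].values
    ):
        raise ValueError("timing maps have mismatched geometry or peak layers")
    if not (
        np.allclose(map_a["lat"].values, map_b["lat"].values)
        and np.allclose(map_a["lon"].values, map_b["lon"].values)
    ):
        raise ValueError("timing maps are on different grids")
    diff = map_a - map_b
    diff.name = "doy_difference"
    diff.attrs = {
        "description": "day-of-year difference (a - b)",
        "a_label": map_a.attrs.get("climate_label", ""),
        "b_label": map_b.attrs.get("climate_label", ""),
    }
    return diff
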