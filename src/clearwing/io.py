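"""Readers and writers for the pipeline's delimited-text formats.

Every writer prepends a comment header (``# clearwing <version> ...``)
recording the package version and, where relevant, the seed and a config
hash, so artifacts are traceable; every reader tolerates such comment
lines.  Schemas are checked on read — malformed rows raise with the row
number rather than being silently dropped or sorted.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import TrapCatchSeries
from .model import TwoPeakWeibullParams

__all__ = [
    "read_weather",
    "write_weather",
    "read_traps",
    "write_traps",
    "read_params",
    "write_params",
    "write_report",
    "read_grid_long",
    "write_timing_ascii_grid",
    "metadata_header",
]

PARAM_KEYS = ("alpha1", "beta1", "gamma1", "delta_beta", "gamma2")


def config_hash(obj: Any) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def metadata_header(seed: int | None = None, cfg: Any = None) -> str:
    parts = [f"# clearwing {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg is not None:
        parts.append(f"config={config_hash(cfg)}")
    return " ".join(parts)


def _write_csv(frame: pd.DataFrame, path: Path, seed=None, cfg=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(metadata_header(seed, cfg) + "\n")
        frame.to_csv(fh, index=False)


def read_weather(path: str | Path) -> pd.DataFrame:
    """Read ``location_id,date,tmin,tmax`` weather; validates the schema."""
    frame = pd.read_csv(path, comment="#")
    missing = {"date", "tmin", "tmax"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    from .degree_days import validate_weather_frame

    return validate_weather_frame(frame)


def write_weather(frame: pd.DataFrame, path: str | Path, seed=None, cfg=None) -> None:
    out = frame.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date
    _write_csv(out, Path(path), seed, cfg)


def read_traps(path: str | Path) -> list[TrapCatchSeries]:
    """Read ``site,year,date,count`` trap catches into per-site-year series.

    Unsorted dates within a site-year are an error, never silently sorted.
    """
    frame = pd.read_csv(path, comment="#")
    missing = {"site", "year", "date", "count"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    frame["date"] = pd.to_datetime(frame["date"])
    out = []
    for (site, year), grp in frame.groupby(["site", "year"], sort=False):
        dates = pd.DatetimeIndex(grp["date"])
        if not dates.is_monotonic_increasing or dates.duplicated().any():
            raise ValueError(f"{path}: trap dates not strictly increasing for {site} {year}")
        out.append(TrapCatchSeries(str(site), int(year), dates, grp["count"].to_numpy(dtype=int)))
    return out


def write_traps(series_list: list[TrapCatchSeries], path: str | Path,
                seed=None, cfg=None) -> None:
    frames = [s.to_frame() for s in series_list]
    out = pd.concat(frames, ignore_index=True)
    out["date"] = pd.to_datetime(out["date"]).dt.date
    _write_csv(out, Path(path), seed, cfg)


def read_params(path: str | Path) -> TwoPeakWeibullParams:
    """Read a YAML parameter file (alpha1, beta1, gamma1, delta_beta, gamma2)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    missing = set(PARAM_KEYS) - set(raw)
    if missing:
        raise ValueError(f"{path}: missing parameter keys {sorted(missing)}")
    return TwoPeakWeibullParams(**{k: float(raw[k]) for k in PARAM_KEYS})


def write_params(params: TwoPeakWeibullParams, path: str | Path,
                 extra: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {k: float(v) for k, v in params.as_dict().items()}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        fh.write(metadata_header() + "\n")
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_report(report: dict, path: str | Path, seed=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"_meta": metadata_header(seed), **report}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (dt.date, dt.datetime, pd.Timestamp)):
        return str(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_grid_long(path: str | Path):
    """Read a long-format temperature grid: ``row,col,date,tmin,tmax``.

    Returns an xarray Dataset shaped like ``idw_interpolate`` output, with
    placeholder georeference attrs if none are recorded.
    """
    import xarray as xr

    frame = pd.read_csv(path, comment="#")
    missing = {"row", "col", "date", "tmin", "tmax"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    frame["date"] = pd.to_datetime(frame["date"])
    if (frame["tmax"] < frame["tmin"]).any():
        bad = int(np.flatnonzero(frame["tmax"] < frame["tmin"])[0])
        raise ValueError(f"{path}: tmax < tmin at row {bad}")
    pv_min = frame.pivot_table(index="date", columns=["row", "col"], values="tmin")
    pv_max = frame.pivot_table(index="date", columns=["row", "col"], values="tmax")
    if pv_min.isna().any().any() or pv_max.isna().any().any():
        raise ValueError(f"{path}: grid period is not uniform across cells")
    nrows = int(frame["row"].max()) + 1
    ncols = int(frame["col"].max()) + 1
    times = pv_min.index
    tmin = np.full((len(times), nrows, ncols), np.nan)
    tmax = np.full((len(times), nrows, ncols), np.nan)
    for (r, c) in pv_min.columns:
        tmin[:, int(r), int(c)] = pv_min[(r, c)].to_numpy()
        tmax[:, int(r), int(c)] = pv_max[(r, c)].to_numpy()
    lat = np.zeros((nrows, ncols))
    lon = np.zeros((nrows, ncols))
    return xr.Dataset(
        {"tmin": (("time", "y", "x"), tmin), "tmax": (("time", "y", "x"), tmax)},
        coords={"time": times, "lat": (("y", "x"), lat), "lon": (("y", "x"), lon)},
        attrs={"crs": "unspecified", "cell_size": 1.0,
               "lat_origin": 0.0, "lon_origin": 0.0},
    )


def write_timing_ascii_grid(timing, prefix: str | Path, nodata: float = -9999) -> list[Path]:
    """Write each peak layer of a timing map as an ESRI ASCII grid (.asc).

    Plain-text raster readable by standard GIS software; cell values are
    day-of-year, missing cells the nodata value.  Returns written paths.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    cell = float(timing.attrs.get("cell_size", 1.0))
    lat0 = float(timing.attrs.get("lat_origin", 0.0))
    lon0 = float(timing.attrs.get("lon_origin", 0.0))
    for peak in timing["peak"].values:
        layer = timing.sel(peak=peak).values
        nrows, ncols = layer.shape
        path = Path(f"{prefix}_peak{int(peak)}.asc")
        with open(path, "w") as fh:
            fh.write(f"ncols {ncols}\n")
            fh.write(f"nrows {nrows}\n")
            fh.write(f"xllcorner {lon0}\n")
            fh.write(f"yllcorner {lat0 - nrows * cell}\n")
            fh.write(f"cellsize {cell}\n")
            fh.write(f"NODATA_value {nodata}\n")
            body = np.where(np.isnan(layer), nodata, layer)
            for row in body:
                fh.write(" ".join(f"{v:g}" for v in row) + "\n")
        paths.append(path)
    return paths
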