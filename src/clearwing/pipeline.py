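"""End-to-end pipeline: simulate -> degree-days -> fit -> validate -> map.

``run_pipeline`` executes the requested stages in dependency order from a
single config mapping (typically loaded from YAML).  Every artifact carries
a metadata header with the package version, seed and config hash; a failing
stage raises a ``StageError`` naming the stage, and the CLI converts that
into a nonzero exit.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io as cwio
from .degree_days import DegreeDayConfig, accumulate_cdd, daily_series_dd
from .fitting import fit_two_peak_weibull, to_cumulative_proportions
from .model import invert_within_peak
from .reference import REFERENCE_PARAMS
from .synthetic import TrapGenConfig, WeatherGenConfig, gen_trap_catches, gen_weather
from .validation import (
    DEFAULT_PERCENTS,
    deviation_summary,
    empirical_percentile_days,
    predicted_percentile_days,
    rda_predicted_days,
    split_peaks,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "dd", "fit", "predict", "validate", "map")


class StageError(RuntimeError):
    """Raised when one pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _dd_config(cfg: dict) -> DegreeDayConfig:
    dd = cfg.get("degree_days", {})
    biofix = str(dd.get("biofix", "10-01"))
    month, day = (int(x) for x in biofix.split("-"))
    return DegreeDayConfig(
        ldt=float(dd.get("ldt", 4.0)),
        biofix_month=month,
        biofix_day=day,
        biofix_in_previous_year=bool(dd.get("biofix_in_previous_year", True)),
        fill_gaps=bool(dd.get("fill_gaps", False)),
    )


def run_pipeline(cfg: dict, stages=ALL_STAGES) -> dict:
    """Run the configured stages; returns a manifest of written artifacts.

    Config keys: ``out_dir``, ``seed``, ``year``, ``degree_days`` (ldt,
    biofix, ...), ``simulate`` (n_sites, total, interval_days), ``params``
    (path; defaults to the packaged reference set), plus optional per-stage
    input paths (``weather``, ``traps``) when simulate is skipped.
    """
    out_dir = Path(cfg.get("out_dir", "clearwing_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    # hash the scientific config only, so reruns into a different directory
    # produce byte-identical artifacts
    cfg_for_hash = {k: v for k, v in cfg.items() if k != "out_dir"}
    year = int(cfg.get("year", 2014))
    ddcfg = _dd_config(cfg)
    manifest: dict[str, str] = {}

    weather = None
    trap_series = []

    if "simulate" in stages:
        sim = cfg.get("simulate", {})
        n_sites = int(sim.get("n_sites", 3))
        wcfg = WeatherGenConfig(seed=seed)
        weather = gen_weather(wcfg)
        wpath = out_dir / "weather.csv"
        cwio.write_weather(weather, wpath, seed=seed, cfg=cfg_for_hash)
        manifest["weather"] = str(wpath)
        acc = accumulate_cdd(daily_series_dd(weather, ddcfg), year, ddcfg)
        for i in range(n_sites):
            tcfg = TrapGenConfig(
                true_params=REFERENCE_PARAMS,
                total=int(sim.get("total", 300)),
                interval_days=int(sim.get("interval_days", 7)),
                seed=seed + 100 + i,
                site=f"site{i:02d}",
            )
            trap_series.append(gen_trap_catches(tcfg, acc))
        tpath = out_dir / "traps.csv"
        cwio.write_traps(trap_series, tpath, seed=seed, cfg=cfg_for_hash)
        manifest["traps"] = str(tpath)
    else:
        if "weather" in cfg:
            weather = cwio.read_weather(cfg["weather"])
        if "traps" in cfg:
            trap_series = cwio.read_traps(cfg["traps"])

    if "dd" in stages:
        if weather is None:
            raise StageError("dd", "config key 'weather' is required")
        acc = accumulate_cdd(daily_series_dd(weather, ddcfg), year, ddcfg)
        dpath = out_dir / "degree_days.csv"
        cwio._write_csv(acc.to_frame(), dpath, seed=seed, cfg=cfg_for_hash)
        manifest["degree_days"] = str(dpath)

    params = REFERENCE_PARAMS
    if cfg.get("params"):
        params = cwio.read_params(cfg["params"])

    if "fit" in stages:
        if weather is None or not trap_series:
            raise StageError("fit", "config keys 'weather' and 'traps' are required")
        acc = accumulate_cdd(daily_series_dd(weather, ddcfg), year, ddcfg)
        points = pd.concat(
            [to_cumulative_proportions(s, acc) for s in trap_series],
            ignore_index=True,
        )
        result = fit_two_peak_weibull(points)
        params = result.params
        ppath = out_dir / "params.yaml"
        cwio.write_params(params, ppath)
        manifest["params"] = str(ppath)
        rpath = out_dir / "fit.json"
        cwio.write_report(
            {
                "params": params.as_dict(),
                "sem": result.sem,
                "sse": result.sse,
                "n_obs": result.n_obs,
                "f_stats": {k: list(v) for k, v in result.f_stats.items()},
                "converged": result.converged,
            },
            rpath,
            seed=seed,
        )
        manifest["fit_report"] = str(rpath)

    if "predict" in stages:
        if weather is None:
            raise StageError("predict", "config key 'weather' is required")
        pred = predicted_percentile_days(params, weather, year, DEFAULT_PERCENTS, ddcfg)
        rows = [
            {"peak": peak, "percent": pct, "predicted_doy": doy,
             "dd_target": invert_within_peak(params, peak, pct / 100.0)}
            for peak, by_pct in pred.items() for pct, doy in by_pct.items()
        ]
        ppath = out_dir / "predicted_percentiles.csv"
        cwio._write_csv(pd.DataFrame(rows), ppath, seed=seed, cfg=cfg_for_hash)
        manifest["predicted_percentiles"] = str(ppath)

    if "validate" in stages:
        if weather is None or not trap_series:
            raise StageError("validate", "config keys 'weather' and 'traps' are required")
        pred = predicted_percentile_days(params, weather, year, DEFAULT_PERCENTS, ddcfg)
        rows = []
        for s in trap_series:
            try:
                first, second = split_peaks(s)
            except ValueError as exc:
                raise StageError("validate", f"{s.site_year}: {exc}") from exc
            for peak, sub in ((1, first), (2, second)):
                obs = empirical_percentile_days(sub, DEFAULT_PERCENTS)
                for pct in DEFAULT_PERCENTS:
                    rows.append(
                        {"site": s.site, "peak": peak, "percent": pct,
                         "observed_doy": obs[pct], "predicted_doy": pred[peak][pct]}
                    )
        table = pd.DataFrame(rows)
        summary = deviation_summary(table).reset_index()
        vpath = out_dir / "validation.csv"
        cwio._write_csv(table, vpath, seed=seed, cfg=cfg_for_hash)
        spath = out_dir / "validation_summary.csv"
        cwio._write_csv(summary, spath, seed=seed, cfg=cfg_for_hash)
        manifest["validation"] = str(vpath)
        manifest["validation_summary"] = str(spath)
        if cfg.get("rda", False):
            rda_first, rda_second = rda_predicted_days(weather, year)
            rpath = out_dir / "rda_benchmark.json"
            cwio.write_report(
                {"rda_first_peak_doy": rda_first, "rda_second_peak_doy": rda_second},
                rpath, seed=seed,
            )
            manifest["rda_benchmark"] = str(rpath)

    if "map" in stages:
        from .mapping import GridSpec, idw_interpolate, peak_timing_map
        from .synthetic import gen_station_network

        mp = cfg.get("map", {})
        if "grid" in cfg:
            grid = cwio.read_grid_long(cfg["grid"])
        else:
            stations = gen_station_network(
                n=int(mp.get("n_stations", 6)),
                bbox=tuple(mp.get("bbox", (34.0, 38.0, 126.0, 129.0))),
                weather_cfg=WeatherGenConfig(seed=seed),
                lapse_per_deg_lat=float(mp.get("lapse", -0.8)),
                seed=seed + 500,
            )
            spec = GridSpec(
                nrows=int(mp.get("nrows", 8)), ncols=int(mp.get("ncols", 8)),
                lat_origin=38.0, lon_origin=126.0,
                cell_size=float(mp.get("cell_size", 0.5)),
            )
            grid = idw_interpolate(stations, spec)
        timing = peak_timing_map(grid, params, ddcfg, target_year=year)
        for p in cwio.write_timing_ascii_grid(timing, out_dir / "peak_timing"):
            manifest[p.name] = str(p)

    mpath = out_dir / "manifest.json"
    cwio.write_report({"artifacts": manifest, "stages": list(stages)}, mpath, seed=seed)
    manifest["manifest"] = str(mpath)
    return manifest
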