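"""End-to-end orchestration: simulate -> cjs -> telemetry -> fuel -> pace.

Each stage reads the delimited-text tables the previous stage wrote, so any
stage can also be re-run standalone from cached outputs. A Markdown report
collects the headline quantities: apparent vs capture-recapture stopover by
year, the DFL~FDR regression, the flight-range distribution, the pace model
table and the direct-flight list.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from . import fuel as fuel_mod
from . import pace as pace_mod
from . import telemetry as tel
from .capture_recapture import (
    build_capture_histories,
    fit_candidate_set,
    select_and_average,
)
from .config import PipelineConfig
from .simulate import simulate_dataset

__all__ = ["run_pipeline", "stage_simulate", "stage_cjs", "stage_telemetry",
           "stage_fuel", "stage_pace"]


def _path(config: PipelineConfig, name: str) -> str:
    return os.path.join(config.out_dir, name)


def stage_simulate(config: PipelineConfig) -> None:
    sim_cfg = config.simulation.replace(rng_seed=config.seed)
    ds = simulate_dataset(sim_cfg)
    ds.write(config.out_dir)


def stage_cjs(config: PipelineConfig) -> None:
    banding = pd.read_csv(_path(config, "banding.csv"), keep_default_na=False)
    banding["mass_g"] = pd.to_numeric(banding["mass_g"])
    # the capture-recapture analysis covers birds not carrying a radio tag
    untagged = banding[banding["tag_id"].astype(str) == ""]
    histories = build_capture_histories(untagged)
    fits = fit_candidate_set(histories)
    avg = select_and_average(fits, delta_max=config.delta_max)
    avg.table.to_csv(_path(config, "cjs_models.csv"), index=False)
    rows = [{"year": "all", "ts_days": avg.ts_days, "ts_se": avg.ts_se}]
    rows += [
        {"year": y, "ts_days": t, "ts_se": np.nan} for y, t in avg.ts_by_year.items()
    ]
    pd.DataFrame(rows).to_csv(_path(config, "stopover_estimates.csv"), index=False)


def stage_telemetry(config: PipelineConfig) -> None:
    detections = pd.read_csv(_path(config, "detections.csv"))
    tags = pd.read_csv(_path(config, "tags.csv"))
    stations = pd.read_csv(_path(config, "stations.csv"))
    runs = tel.filter_bursts(
        detections, tags, tolerance=config.gap_tolerance,
        max_missed=config.max_missed_bursts,
    )
    local = set(stations.loc[stations["region"] == "Local", "station_id"])
    records = tel.build_stopover_records(
        runs,
        tags,
        local,
        window=config.simulation.departure_window,
        dismantle_dates=config.dismantle_dates,
    )
    tel.runs_to_frame(runs).to_csv(_path(config, "runs.csv"), index=False)
    tel.records_to_frame(records).to_csv(
        _path(config, "stopover_records.csv"), index=False
    )


def stage_fuel(config: PipelineConfig) -> None:
    banding = pd.read_csv(_path(config, "banding.csv"), keep_default_na=False)
    banding["mass_g"] = pd.to_numeric(banding["mass_g"])
    records = pd.read_csv(_path(config, "stopover_records.csv"), keep_default_na=False)
    lbm = fuel_mod.fit_lbm(banding)
    pairs = fuel_mod.recapture_pairs(banding)
    mc = fuel_mod.MassChangeModel(pairs).fit()
    mc.table.to_csv(_path(config, "mass_change_models.csv"), index=False)
    reliable = records[records["reliability"] == "reliable"].copy()
    first = banding.sort_values("date").drop_duplicates("bird_id")
    tagged = reliable.merge(
        first[["bird_id", "mass_g", "wing_mm", "year", "age", "date"]], on="bird_id"
    )
    tagged = tagged.rename(columns={"mass_g": "mass_t0"})
    tagged["st_days"] = pd.to_numeric(tagged["apparent_stopover_days"])
    tagged["date_first"] = pd.to_datetime(tagged["date"]).dt.dayofyear
    tagged["tagged"] = True
    tagged["mass_first"] = tagged["mass_t0"]
    est = fuel_mod.fuel_estimates(tagged, mc, lbm, U=config.airspeed_U)
    est.to_csv(_path(config, "fuel_estimates.csv"), index=False)


def stage_pace(config: PipelineConfig) -> None:
    runs = pd.read_csv(_path(config, "runs.csv"))
    stations = pd.read_csv(_path(config, "stations.csv"))
    records = pd.read_csv(_path(config, "stopover_records.csv"), keep_default_na=False)
    fuel = pd.read_csv(_path(config, "fuel_estimates.csv"))
    tags = pd.read_csv(_path(config, "tags.csv"))
    obs = pace_mod.build_pace_observations(
        runs, stations, records, fuel=fuel, tags=tags
    )
    obs.to_csv(_path(config, "pace_observations.csv"), index=False)
    direct = pace_mod.classify_direct_flights(obs, speed_band=config.speed_band)
    direct.to_csv(_path(config, "direct_flights.csv"), index=False)
    if len(obs) >= 4 and obs["bird_id"].nunique() >= 2:
        res = pace_mod.PaceModel(obs).fit()
        res.table.to_csv(_path(config, "pace_models.csv"), index=False)
        with open(_path(config, "pace_summary.txt"), "w") as fh:
            fh.write(res.summary() + "\n")


def _report(config: PipelineConfig) -> str:
    lines = ["# Stopover-to-pace pipeline report", ""]
    lines.append(f"Seed: {config.seed}")
    lines.append("")

    def _maybe(name):
        p = _path(config, name)
        return pd.read_csv(p, keep_default_na=False) if os.path.exists(p) else None

    records = _maybe("stopover_records.csv")
    if records is not None:
        rel = records[records["reliability"] == "reliable"].copy()
        rel["year"] = pd.to_datetime(rel["departure_datetime"]).dt.year
        rel["st"] = pd.to_numeric(rel["apparent_stopover_days"])
        lines.append("## Apparent stopover (radio-tagged, reliable departures)")
        lines.append("")
        lines.append("| year | mean (d) | sd | n |")
        lines.append("|---|---|---|---|")
        for y, g in rel.groupby("year"):
            lines.append(
                f"| {y} | {g['st'].mean():.1f} | {g['st'].std():.1f} | {len(g)} |"
            )
        counts = records["reliability"].value_counts().to_dict()
        lines.append("")
        lines.append(f"Reliability classes: {counts}")
        lines.append("")
    est = _maybe("stopover_estimates.csv")
    if est is not None:
        lines.append("## Capture-recapture total stopover (untagged birds)")
        lines.append("")
        for _, r in est.iterrows():
            se = f" +- {float(r['ts_se']):.1f}" if str(r["ts_se"]) not in ("", "nan") else ""
            lines.append(f"- {r['year']}: {float(r['ts_days']):.1f}{se} d")
        lines.append("")
    fuel = _maybe("fuel_estimates.csv")
    if fuel is not None:
        for c in fuel.columns:
            if c != "bird_id":
                fuel[c] = pd.to_numeric(fuel[c], errors="coerce")
        lines.append("## Fuel and flight range")
        lines.append("")
        reg = fuel_mod.dfl_vs_fdr(fuel)
        lines.append(
            f"- DFL ~ FDR: slope {reg['slope']:.2f}, R^2 {reg['r_squared']:.2f}, "
            f"p {reg['p_value']:.2g} (n = {reg['n']})"
        )
        if "year" in fuel.columns:
            for y, g in fuel.groupby("year"):
                rng_km = fuel_mod.round_range_km(float(g["flight_range_km"].mean()))
                lines.append(
                    f"- {y}: mean DFL {g['dfl'].mean():.2f} LBM, "
                    f"mean flight range ~{rng_km} km (n = {len(g)})"
                )
        lines.append("")
    pace_tab = _maybe("pace_models.csv")
    if pace_tab is not None:
        lines.append("## Pace of migration: model table")
        lines.append("")
        lines.append(pace_tab.to_markdown(index=False))
        lines.append("")
    direct = _maybe("direct_flights.csv")
    if direct is not None and len(direct):
        nd = (direct["direct_flight"] == "direct").sum()
        lines.append(
            f"Direct flights inferred: {nd} of {len(direct)} continental detections"
        )
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> str:
    """Execute enabled stages in dependency order; returns the report path.

    Any stage failure raises with the failing stage named.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    stages = [("simulate", stage_simulate)]
    if config.run_cjs:
        stages.append(("cjs", stage_cjs))
    if config.run_telemetry:
        stages.append(("telemetry", stage_telemetry))
    if config.run_fuel and config.run_telemetry:
        stages.append(("fuel", stage_fuel))
    if config.run_pace and config.run_fuel and config.run_telemetry:
        stages.append(("pace", stage_pace))
    for name, fn in stages:
        try:
            fn(config)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    report = _report(config)
    report_path = _path(config, "report.md")
    with open(report_path, "w") as fh:
        fh.write(report)
    return report_path
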