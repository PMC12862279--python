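"""End-to-end pipeline driver: simulate (optional) -> detect -> classify ->
geolocate -> shelf -> diel -> summarize, with a manifest recording the
configuration hash and per-stage row counts.

Every CSV the pipeline writes starts with provenance comment lines
(config hash, stage, write time); read them back with ``comment='#'``.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import classify as _classify
from . import diel as _diel
from . import geo as _geo
from . import shelf as _shelf
from . import summarize as _summarize
from . import tdr as _tdr
from .config import PipelineConfig
from .synthetic import CohortData, SimConfig, simulate_cohort


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def write_csv(df: pd.DataFrame, path, config: PipelineConfig, stage: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stamp = datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")
    with open(path, "w") as fh:
        fh.write(f"# pinchpoint stage={stage} config={config.hash()} written={stamp}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def thresholds_from_config(cfg: PipelineConfig) -> _classify.ClassifierThresholds:
    return _classify.ClassifierThresholds(
        fii_threshold=cfg.fii_threshold,
        drift_peak_height=cfg.drift_peak_height,
        benthic_speed_window=cfg.benthic_speed_window,
        benthic_peak_height=cfg.benthic_peak_height,
        corner_distance_max=cfg.corner_distance_max,
        bathy_diff_max=cfg.bathy_diff_max,
    )


def process_trip(trip, cohort: CohortData, cfg: PipelineConfig,
                 areas: Optional[_geo.PredatorAreas] = None) -> dict:
    """Run one trip through detection, geolocation, and classification.

    Returns the corrected series, the classified dives, the shelf
    crossings, and assorted per-trip tables.
    """
    series = _tdr.DepthSeries(trip.animal_id, trip.time, trip.depth_raw, trip.interval)
    series, dives = _tdr.process_series(
        series, min_depth=cfg.min_depth, min_duration=cfg.min_duration,
        wiggle_threshold=cfg.wiggle_threshold, zoc_window=cfg.zoc_window_min,
        resample=cfg.resample if cfg.resample > trip.interval else None,
    )
    track = _geo.interpolate_track(trip.track, step=cfg.step_h, vmax=cfg.vmax)
    if areas is None:
        areas = _geo.PredatorAreas(
            {f["properties"]["name"]: _geo.shape(f["geometry"])
             for f in cohort.predator_geojson["features"]})
    loc_table = _geo.geolocate_dives(
        dives, track, grid=cohort.bathymetry, areas=areas,
        colony=(cfg.colony_lon, cfg.colony_lat))
    thr = thresholds_from_config(cfg)
    _classify.classify_dives(dives, series, thresholds=thr)
    crossings = _shelf.trip_shelf_crossings(
        dives, animal_id=trip.animal_id, shelf_depth=cfg.shelf_depth,
        min_run=cfg.min_run, window_h=cfg.window_h)
    phase_table = _shelf.phase_shelf_table(dives, crossings, trip.animal_id,
                                           window_h=cfg.window_h)
    dive_table = _tdr.dives_to_frame(dives)
    dive_table.insert(0, "animal_id", trip.animal_id)
    dive_table["season"] = trip.season
    dive_table = dive_table.merge(
        loc_table[["dive_id", "in_shark", "in_orca", "in_overlap"]], on="dive_id")
    return {
        "series": series, "dives": dives, "track": track,
        "dive_table": dive_table, "loc_table": loc_table,
        "crossings": crossings, "phase_table": phase_table,
    }


def run_pipeline(config: PipelineConfig, outdir,
                 cohorts: Optional[list[CohortData]] = None) -> dict:
    """Execute the full pipeline and write all outputs under ``outdir``.

    Without explicit ``cohorts`` a synthetic cohort is generated for each
    season from ``config.sim`` overrides and ``config.seed``; this makes a
    bare run self-contained. Deterministic for a given config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "config_hash": config.hash(), "stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                manifest["stages"][name] = {"error": str(exc)}
                with open(outdir / "manifest.json", "w") as fh:
                    json.dump(manifest, fh, indent=2, default=str)
                raise StageError(name, exc) from exc
        return wrap

    if cohorts is None:
        def make_cohorts():
            out = []
            for i, season in enumerate(("post_breeding", "post_molt")):
                sim = SimConfig(**{**config.sim, "season": season,
                                   "seed": config.seed + i})
                out.append(simulate_cohort(sim))
            return out
        cohorts = stage("simulate")(make_cohorts)

    results = []
    for cohort in cohorts:
        for trip in cohort.trips:
            res = stage(f"process:{trip.animal_id}")(
                lambda t=trip, c=cohort: process_trip(t, c, config))
            res["trip"] = trip
            results.append(res)

    dive_table = pd.concat([r["dive_table"] for r in results], ignore_index=True)
    manifest["stages"]["detect"] = {"n_dives": int(len(dive_table))}
    manifest["stages"]["classify"] = {
        "n_classified": int(dive_table["type"].notna().sum()),
        "counts": dive_table["type"].value_counts().to_dict(),
    }
    write_csv(dive_table, outdir / "dives.csv", config, "classify")

    crossings = [c for r in results for c in r["crossings"]]
    crossing_table = _shelf.crossings_to_frame(crossings)
    season_by_id = {r["trip"].animal_id: r["trip"].season for r in results}
    crossing_table["season"] = crossing_table["animal_id"].map(season_by_id)
    write_csv(crossing_table, outdir / "shelf_crossings.csv", config, "shelf")
    manifest["stages"]["shelf"] = {
        "n_crossings": int(len(crossing_table)),
        "n_missing": int(crossing_table["missing"].sum()),
    }

    phase_table = pd.concat([r["phase_table"] for r in results], ignore_index=True)
    metric_summary = (_shelf.phase_shelf_metric_summary(phase_table)
                      if len(phase_table) else pd.DataFrame())
    write_csv(metric_summary, outdir / "shelf_metric_summary.csv", config, "shelf")

    def diel_stage():
        rows = []
        for r in results:
            t = r["trip"]
            for phase, when in (("departure", t.departure_time),
                                ("arrival", t.arrival_time)):
                dives = r["dives"]
                d = dives[0] if phase == "departure" else dives[-1]
                rows.append({
                    "animal_id": t.animal_id, "season": t.season, "phase": phase,
                    "time": when, "lon": d.lon, "lat": d.lat,
                    "day_night": _diel.assign_day_night(when, d.lon, d.lat),
                    "local_hour": _diel.local_hour(when, config.colony_utc_offset_h),
                })
        events = pd.DataFrame(rows)
        summary = _diel.departure_arrival_summary(
            events, utc_offset_h=config.colony_utc_offset_h)
        return events, summary
    events, diel_summary = stage("diel")(diel_stage)
    write_csv(events, outdir / "diel_events.csv", config, "diel")
    write_csv(diel_summary, outdir / "diel_summary.csv", config, "diel")
    manifest["stages"]["diel"] = {"n_events": int(len(events))}

    def summarize_stage():
        type_table = _summarize.dive_type_table(dive_table)
        benthic = dive_table[dive_table["type"] == "benthic"]
        pred = _summarize.predator_area_percentages(benthic)
        binned = {
            "bathymetry": _summarize.binned_proportions(
                dive_table, _summarize.BinSpec("bathymetry", config.bathy_bin_m)),
            "distance": _summarize.binned_proportions(
                dive_table, _summarize.BinSpec("distance", config.dist_bin_km)),
        }
        return type_table, pred, binned
    type_table, pred_pct, binned = stage("summarize")(summarize_stage)
    write_csv(type_table, outdir / "dive_type_table.csv", config, "summarize")
    write_csv(pd.DataFrame([pred_pct]), outdir / "predator_area_pct.csv",
              config, "summarize")
    for var, df in binned.items():
        write_csv(df, outdir / f"binned_proportions_{var}.csv", config, "summarize")
    manifest["stages"]["summarize"] = {"benthic_pct": pred_pct}

    meta = pd.DataFrame([{
        "animal_id": r["trip"].animal_id, "season": r["trip"].season,
        "departure_mass_kg": r["trip"].departure_mass_kg,
        "age_yr": r["trip"].age_yr, "tag_type": r["trip"].tag_type,
    } for r in results])
    seal_phase = crossing_table.merge(meta, on=["animal_id", "season"], how="left")
    _summarize.export_model_tables(dive_table, seal_phase, outdir)

    manifest["row_counts_consistent"] = bool(
        manifest["stages"]["detect"]["n_dives"]
        == manifest["stages"]["classify"]["n_classified"])
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {
        "manifest": manifest, "results": results, "dive_table": dive_table,
        "crossing_table": crossing_table, "metric_summary": metric_summary,
        "diel_events": events, "diel_summary": diel_summary,
        "type_table": type_table, "predator_pct": pred_pct, "binned": binned,
    }
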