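"""Descriptive summary surfaces: dive-type count tables, predator-area
benthic percentages, and binned dive-type proportions by bathymetry or
colony distance.

Bins follow the lower-exclusive / upper-inclusive convention (a, b]: a
bathymetry of exactly 200 m with 200-m bins falls in (0, 200].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import DIVE_TYPES

BATHY_BIN_M = 200.0
DIST_BIN_KM = 300.0


@dataclass
class BinSpec:
    variable: str          # "bathymetry" | "distance"
    width: float           # 200 m or 300 km

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("bin width must be > 0")
        if self.variable not in ("bathymetry", "distance"):
            raise ValueError(f"unknown bin variable {self.variable!r}")


def dive_type_table(dives: pd.DataFrame, season_col: str = "season") -> pd.DataFrame:
    """Counts and benthic proportions per season and overall.

    ``dives`` needs columns type, animal_id and optionally season and lon.
    Rows without an assignable location are counted in ``wo_location`` but
    are retained in the totals (as in deposited-data summaries).
    """
    def summarize(grp: pd.DataFrame, label: str) -> dict:
        total = len(grp)
        benthic = int((grp["type"] == "benthic").sum())
        wo_loc = int(grp["lon"].isna().sum()) if "lon" in grp.columns else 0
        return {
            "stratum": label,
            "n_seals": grp["animal_id"].nunique() if "animal_id" in grp.columns else np.nan,
            "total_dives": total,
            "wo_location": wo_loc,
            "benthic_dives": benthic,
            "benthic_proportion_pct": 100.0 * benthic / total if total else np.nan,
        }

    rows = []
    if season_col in dives.columns:
        for season, grp in dives.groupby(season_col):
            rows.append(summarize(grp, str(season)))
    rows.append(summarize(dives, "overall"))
    return pd.DataFrame(rows)


def predator_area_percentages(benthic: pd.DataFrame) -> dict:
    """Percentages of benthic dives inside the shark area, the orca area,
    either (total = union), and both (overlap = intersection).

    ``benthic`` needs boolean columns in_shark and in_orca. Zero benthic
    dives yield NaNs with a flag.
    """
    n = len(benthic)
    if n == 0:
        return {"shark_pct": np.nan, "orca_pct": np.nan, "total_pct": np.nan,
                "overlap_pct": np.nan, "n_benthic": 0, "undefined": True}
    shark = benthic["in_shark"].to_numpy(dtype=bool)
    orca = benthic["in_orca"].to_numpy(dtype=bool)
    return {
        "shark_pct": 100.0 * shark.mean(),
        "orca_pct": 100.0 * orca.mean(),
        "total_pct": 100.0 * (shark | orca).mean(),
        "overlap_pct": 100.0 * (shark & orca).mean(),
        "n_benthic": n,
        "undefined": False,
    }


def bin_index(values, width: float) -> np.ndarray:
    """1-based bin index k such that value falls in ((k-1)*w, k*w]."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("negative values cannot be binned")
    k = np.ceil(v / width).astype(int)
    return np.maximum(k, 1)  # 0 maps to the first bin (0, w]


def binned_proportions(dives: pd.DataFrame, spec: BinSpec) -> pd.DataFrame:
    """Per-bin dive-type proportions over the four types; empty bins are
    omitted and each bin's proportions sum to 1."""
    col = {"bathymetry": "bathymetry", "distance": "dist_colony_km"}[spec.variable]
    df = dives.dropna(subset=[col]).copy()
    df["bin"] = bin_index(df[col], spec.width)
    rows = []
    for k, grp in df.groupby("bin"):
        total = len(grp)
        row = {
            "bin": int(k),
            "bin_lower_excl": (k - 1) * spec.width,
            "bin_upper_incl": k * spec.width,
            "n_dives": total,
        }
        for t in DIVE_TYPES:
            row[f"prop_{t}"] = float((grp["type"] == t).sum()) / total
        rows.append(row)
    return pd.DataFrame(rows)


DIVE_TABLE_DICTIONARY = {
    "animal_id": "seal identifier",
    "dive_id": "per-trip dive index",
    "season": "post_breeding or post_molt foraging trip",
    "start_time": "dive start, UTC ISO-8601",
    "max_depth": "maximum dive depth, m",
    "duration_s": "dive duration, s",
    "type": "dive type: transit, foraging, drift, benthic",
    "W": "bottom-phase wiggle count",
    "V": "bottom-phase total vertical distance, m",
    "R": "bottom-phase depth range, m",
    "T": "bottom-phase duration, s",
    "descent_rate": "descent rate, m/s",
    "ascent_rate": "ascent rate, m/s",
    "bottom_time": "bottom duration, s",
    "post_dive_interval": "surface time to next dive, s",
    "mean_depth": "mean depth over the dive, m",
    "lon": "dive longitude, WGS84 deg",
    "lat": "dive latitude, WGS84 deg",
    "bathymetry": "seafloor depth at dive location, m positive down",
    "dist_colony_km": "great-circle distance from the colony, km",
    "in_shark": "dive inside the white-shark area",
    "in_orca": "dive inside the orca area",
    "in_overlap": "dive inside both predator areas",
    "phase": "departure, arrival, or mid-trip",
    "shelf_status": "on/off continental shelf around the crossing",
    "departure_mass_kg": "seal mass at departure, kg",
    "age_yr": "seal age, years",
}

SEAL_PHASE_DICTIONARY = {
    "animal_id": "seal identifier",
    "season": "post_breeding or post_molt",
    "phase": "departure or arrival",
    "on_shelf_duration_h": "shelf-use duration, h (missing if no qualifying block)",
    "transition_time": "shelf transition timestamp, UTC",
    "tag_type": "satellite tag type",
}


def export_model_tables(dive_table: pd.DataFrame, seal_phase_table: pd.DataFrame,
                        outdir) -> dict:
    """Write analysis-ready flat files plus a data dictionary; returns the
    paths written. Row counts are preserved exactly."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dives": outdir / "model_dives.csv",
        "seal_phase": outdir / "model_seal_phase.csv",
        "dictionary": outdir / "data_dictionary.csv",
    }
    dive_table.to_csv(paths["dives"], index=False)
    seal_phase_table.to_csv(paths["seal_phase"], index=False)
    dictionary = pd.DataFrame(
        [{"table": "dives", "column": c, "description": d}
         for c, d in DIVE_TABLE_DICTIONARY.items() if c in dive_table.columns]
        + [{"table": "seal_phase", "column": c, "description": d}
           for c, d in SEAL_PHASE_DICTIONARY.items() if c in seal_phase_table.columns]
    )
    dictionary.to_csv(paths["dictionary"], index=False)
    return paths
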