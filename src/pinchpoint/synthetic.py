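"""Seeded synthetic biologging data with ground-truth labels.

The generator emulates the statistical structure a time-depth-recorder
pipeline assumes for adult female elephant seals: regularly sampled depth
(1-8 s) with slow pressure-transducer surface-offset drift and bounded
sensor noise; four dive archetypes (V-shaped transit, foraging with
bottom-phase wiggles, drift at one constant vertical rate, flat-bottomed
benthic dives tracking the seafloor); trips that open and close with a run
of consecutive benthic dives over a shallow (< 140 m) shelf grading into
deep open ocean; 3-h-scale track fixes; and a monotone shelf/slope/abyss
bathymetry raster. Every dive carries a truth record so downstream
detection, classification, and shelf-crossing stages can be scored.

Dive geometry is built so each archetype satisfies the defining numeric
property its classifier criterion tests (wiggle amplitudes >= 5 m for
foraging; >= 60% of samples at one vertical rate for drift; flat bottoms
within 5 m of the seafloor with sharp corners for benthic), with margins
wide enough that label recovery is limited by sensor noise, not geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .diel import COLONY_UTC_OFFSET_H
from .geo import EARTH_RADIUS_KM, BathymetryGrid, great_circle_distance

DIVE_TYPES = ("transit", "foraging", "drift", "benthic")
DEFAULT_DIVE_MIX = {"transit": 0.40, "foraging": 0.35, "drift": 0.20, "benthic": 0.05}


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Depths in metres, distances in km, rates in m per hour where noted.
    ``dive_mix`` governs the interior (off-shelf) portion of each trip;
    trips always open and close with ``shelf_run_length`` consecutive
    benthic dives over the shelf.
    """

    seed: int = 0
    n_seals: int = 10
    season: str = "post_breeding"  # post_breeding | post_molt
    sampling_interval: float = 8.0  # s
    dive_mix: dict = field(default_factory=lambda: dict(DEFAULT_DIVE_MIX))
    n_dives: int = 170              # interior (deep-water) dives per trip
    shelf_run_length: int = 6       # benthic dives opening/closing the trip
    shelf_width_km: float = 10.0
    slope_width_km: float = 10.0
    shelf_depth: float = 120.0      # m at the shelf edge (< 140-m break)
    open_depth: float = 600.0       # m beyond the slope
    surface_offset_drift: float = 2.0  # m/h, sign randomized per trip
    depth_noise_sd: float = 0.3     # m, truncated at +/-3 sd
    colony: tuple = (-122.34, 37.11)  # (lon, lat)
    departure_hour_mean: float = 19.0  # local clock hour of departures
    departure_hour_kappa: float = 0.4  # von Mises concentration (weak)
    travel_speed_ms: float = 1.2    # ground speed while diving on/off shelf
    approach_speed_ms: float = 2.3  # ground speed while crossing the slope
    n_subthreshold: int = 2         # shallow excursions below detection limits
    grid_cell_deg: float = 4.0 / 60.0  # 4 arc-minutes

    def __post_init__(self) -> None:
        if abs(sum(self.dive_mix.values()) - 1.0) > 1e-9:
            raise ValueError("dive_mix proportions must sum to 1")
        if set(self.dive_mix) != set(DIVE_TYPES):
            raise ValueError(f"dive_mix must cover exactly {DIVE_TYPES}")
        if self.season not in ("post_breeding", "post_molt"):
            raise ValueError("season must be post_breeding or post_molt")
        for name in ("sampling_interval", "shelf_width_km", "slope_width_km",
                     "shelf_depth", "open_depth", "depth_noise_sd", "grid_cell_deg",
                     "travel_speed_ms", "approach_speed_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (self.shelf_depth < 140.0 < self.open_depth):
            raise ValueError("need shelf_depth < 140 m < open_depth")


def seafloor_depth(dist_km, cfg: SimConfig):
    """Analytic seafloor depth (m, positive down) vs distance from the
    colony: linear shelf to ``shelf_depth``, linear slope to ``open_depth``,
    then flat abyssal plain. Monotone non-decreasing."""
    d = np.asarray(dist_km, dtype=float)
    w, s = cfg.shelf_width_km, cfg.slope_width_km
    depth = np.where(
        d <= w,
        cfg.shelf_depth * d / w,
        np.where(
            d <= w + s,
            cfg.shelf_depth + (cfg.open_depth - cfg.shelf_depth) * (d - w) / s,
            cfg.open_depth,
        ),
    )
    return float(depth) if depth.ndim == 0 else depth


def shelf_break_distance_km(cfg: SimConfig, isobath: float = 140.0,
                            tol: float = 1e-9) -> float:
    """Distance of an isobath from the colony, by bisection on the
    monotone analytic profile."""
    lo, hi = 0.0, cfg.shelf_width_km + cfg.slope_width_km + 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if seafloor_depth(mid, cfg) < isobath:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def simulate_bathymetry(cfg: SimConfig, extent_km: Optional[float] = None
                        ) -> BathymetryGrid:
    """Regular lon/lat raster of the analytic seafloor around the colony.

    Cells east of the colony meridian are land (depth 0); ocean-side depth
    increases monotonically with distance from the colony.
    """
    lon_c, lat_c = cfg.colony
    if extent_km is None:
        # generous bound on the farthest interior dive
        extent_km = (cfg.shelf_width_km + cfg.slope_width_km + 1.0
                     + 2.4 * (cfg.n_dives // 2 + 1) + 25.0)
    km_per_deg_lon = np.pi / 180.0 * EARTH_RADIUS_KM * np.cos(np.radians(lat_c))
    lon_span = extent_km / km_per_deg_lon
    cs = cfg.grid_cell_deg
    lons = np.arange(lon_c - lon_span - 2 * cs, lon_c + 3 * cs, cs)
    lats = np.arange(lat_c - 0.6, lat_c + 0.6 + cs, cs)
    depth = np.zeros((len(lats), len(lons)))
    for i, la in enumerate(lats):
        for j, lo in enumerate(lons):
            if lo > lon_c:  # land side
                continue
            d = great_circle_distance((lo, la), (lon_c, lat_c))
            depth[i, j] = seafloor_depth(d, cfg)
    return BathymetryGrid(lon0=float(lons[0]), lat0=float(lats[0]),
                          cellsize=cs, depth=depth)


def default_predator_areas(cfg: SimConfig) -> dict:
    """Shark and orca polygons as GeoJSON-style dicts: coastal boxes around
    the colony, the orca area extending farther offshore (so the shark box
    is nested inside it, mirroring the nearshore predator concentration)."""
    lon_c, lat_c = cfg.colony
    km_per_deg = np.pi / 180.0 * EARTH_RADIUS_KM * np.cos(np.radians(lat_c))

    def box(reach_km, half_lat):
        w = reach_km / km_per_deg
        return [[[lon_c + 0.2, lat_c - half_lat], [lon_c + 0.2, lat_c + half_lat],
                 [lon_c - w, lat_c + half_lat], [lon_c - w, lat_c - half_lat],
                 [lon_c + 0.2, lat_c - half_lat]]]

    return {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"name": "shark"},
             "geometry": {"type": "Polygon", "coordinates": box(60.0, 0.5)}},
            {"type": "Feature", "properties": {"name": "orca"},
             "geometry": {"type": "Polygon", "coordinates": box(150.0, 0.5)}},
        ],
    }


# ----------------------------------------------------------------------
# dive archetype builders (noise-free structure; trip assembly adds the
# sensor noise and surface-offset drift)

def _ramp_down(rng, target: float, rate: float, dt: float,
               jitter: float = 0.1) -> np.ndarray:
    """Descending depth samples from the surface to ``target`` m."""
    n = max(int(np.ceil(target / (rate * dt))), 2)
    speeds = rate * (1.0 + rng.normal(0.0, jitter, n))
    d = np.cumsum(np.abs(speeds)) * dt
    d = d * (target / d[-1])
    d[0] = max(d[0], min(5.0, target))  # crisp duck-under past the surface gate
    return d


def _ramp_up(rng, start: float, rate: float, dt: float,
             jitter: float = 0.1, floor: float = 3.5) -> np.ndarray:
    """Ascending samples from ``start`` m to the surface; samples shallower
    than ``floor`` are dropped so the dive boundary stays crisp."""
    n = max(int(np.ceil(start / (rate * dt))) + 1, 2)
    speeds = rate * (1.0 + rng.normal(0.0, jitter, n))
    d = start - np.cumsum(np.abs(speeds)) * dt
    return d[d > floor]


def _build_transit(rng, bathy: float, dt: float, max_depth: Optional[float] = None
                   ) -> np.ndarray:
    D = max_depth if max_depth is not None else min(
        rng.uniform(250.0, 450.0), max(0.72 * bathy, 30.0))
    down = _ramp_down(rng, D, rng.uniform(1.2, 1.8), dt)
    up = _ramp_up(rng, D - rng.uniform(1.2, 1.7) * dt, rng.uniform(1.1, 1.7), dt)
    return np.concatenate([down, up])


def _build_foraging(rng, bathy: float, dt: float) -> np.ndarray:
    D = min(rng.uniform(350.0, 550.0), bathy - 60.0)
    D = max(D, 120.0)
    down = _ramp_down(rng, D, rng.uniform(1.2, 1.6), dt)
    segs = [down]
    depth = D
    for _ in range(int(rng.integers(4, 9))):  # wiggles: up then back down
        amp = rng.uniform(8.0, 15.0)
        for sign in (-1.0, 1.0):
            w_rate = rng.uniform(0.4, 0.9)
            n = max(int(np.ceil(amp / (w_rate * dt))), 2)
            step = sign * amp / n
            seg = depth + step * np.arange(1, n + 1) + rng.normal(0, 0.3, n)
            depth = depth + step * n
            segs.append(seg)
    segs.append(_ramp_up(rng, depth - 1.0 * dt, rng.uniform(1.1, 1.5), dt))
    return np.concatenate(segs)


def _build_drift(rng, bathy: float, dt: float) -> np.ndarray:
    # keep the drift segment >= ~3/4 of the dive so the whole-dive
    # vertical-speed density concentrates sharply at the drift rate
    rate = rng.choice([-1.0, 1.0]) * rng.uniform(0.22, 0.38)
    deep_cap = min(bathy - 80.0, 480.0)
    shallow = rng.uniform(70.0, 110.0)
    t_drift = min(rng.uniform(900.0, 1100.0), (deep_cap - shallow) / abs(rate))
    n = int(round(t_drift / dt))
    speeds = rate + rng.normal(0.0, 0.05, n)
    if rate > 0:  # sinking: shallow start, deep end
        start = shallow
    else:  # rising: deep start, shallow end
        start = shallow + abs(rate) * t_drift
    down = _ramp_down(rng, start, 1.8, dt, jitter=0.05)
    drift = start + np.cumsum(speeds) * dt
    up = _ramp_up(rng, drift[-1] - 1.8 * dt, 1.8, dt, jitter=0.05)
    return np.concatenate([down, drift, up])


def _build_benthic(rng, bathy: float, dt: float) -> np.ndarray:
    if bathy <= 25.0:
        raise ValueError("benthic dive requested over bathymetry <= 25 m")
    level = bathy - rng.uniform(0.3, 1.5)
    # shallow dives descend slowly so the bottom phase stays under ~45% of
    # the dive (a bottom-dominated speed sample would mimic a drift dive)
    t_desc = max(level / rng.uniform(1.4, 1.6), 75.0)
    t_asc = max(level / rng.uniform(1.2, 1.4), 85.0)
    r_d, r_a = level / t_desc, level / t_asc
    down = _ramp_down(rng, level, r_d, dt, jitter=0.05)
    t_bottom = max(0.75 * (t_desc + t_asc), 140.0)
    n = int(round(t_bottom / dt))
    # flat holds punctuated by small alternating steps: a sharp density
    # peak of bottom vertical speed at ~0 m/s without a degenerate KDE
    cur, step = level, float(rng.choice([-2.0, 2.0])) * -1.0
    if step > 0:
        cur = level - 2.0  # keep the trace at or below the seafloor level
    levels = np.empty(n)
    for i in range(n):
        if i % 5 == 4:
            cur += step
            step = -step
        levels[i] = cur
    bottom = levels + rng.normal(0.0, 0.2, n)
    up = _ramp_up(rng, bottom[-1] - r_a * dt, r_a, dt, jitter=0.05)
    return np.concatenate([down, bottom, up])


def _build_subthreshold(rng, dt: float) -> np.ndarray:
    """Shallow excursion below the 25-m detection limit."""
    return _build_transit(rng, bathy=1000.0, dt=dt, max_depth=rng.uniform(12.0, 20.0))


def simulate_dive(dive_type: str, bathymetry_here: float, rng,
                  cfg: Optional[SimConfig] = None,
                  subthreshold: bool = False) -> tuple[np.ndarray, dict]:
    """One dive's noise-free depth segment plus its truth record fields."""
    cfg = cfg or SimConfig()
    dt = cfg.sampling_interval
    if subthreshold:
        depths = _build_subthreshold(rng, dt)
    elif dive_type == "transit":
        depths = _build_transit(rng, bathymetry_here, dt)
    elif dive_type == "foraging":
        depths = _build_foraging(rng, bathymetry_here, dt)
    elif dive_type == "drift":
        depths = _build_drift(rng, bathymetry_here, dt)
    elif dive_type == "benthic":
        depths = _build_benthic(rng, bathymetry_here, dt)
    else:
        raise ValueError(f"unknown dive type {dive_type!r}")
    truth = {
        "true_type": dive_type,
        "subthreshold": subthreshold,
        "true_max_depth": float(depths.max()),
        "bathymetry_true": float(bathymetry_here),
    }
    return depths, truth


@dataclass
class TripData:
    """One simulated trip: raw depth record, track fixes, per-dive truth."""

    animal_id: str
    season: str
    time: np.ndarray          # datetime64[ns]
    depth_raw: np.ndarray     # with offset drift + noise
    depth_true: np.ndarray    # noise- and offset-free
    interval: float
    track: pd.DataFrame       # time, lon, lat at 3-h steps
    truth: pd.DataFrame       # one row per generated dive
    departure_time: pd.Timestamp
    arrival_time: pd.Timestamp
    shelf_truth: dict         # departure/arrival run timestamps
    departure_mass_kg: float = np.nan
    age_yr: int = 0
    tag_type: str = "Argos"


def _trip_start(cfg: SimConfig, rng) -> pd.Timestamp:
    base = {"post_breeding": pd.Timestamp("2016-02-16"),
            "post_molt": pd.Timestamp("2016-06-06")}[cfg.season]
    day_jitter = int(rng.integers(-9, 10))
    # weak evening concentration of departures (von Mises on the 24-h clock)
    local_hour = (cfg.departure_hour_mean
                  + rng.vonmises(0.0, cfg.departure_hour_kappa)
                  * 24.0 / (2 * np.pi)) % 24.0
    utc_hour = (local_hour - COLONY_UTC_OFFSET_H) % 24.0  # colony local -> UTC
    return (base + pd.Timedelta(days=day_jitter)
            + pd.Timedelta(seconds=round(utc_hour * 3600.0)))


def simulate_trip(cfg: SimConfig, rng, animal_id: str = "seal",
                  ) -> TripData:
    """Assemble a full trip.

    Phase structure: an opening run of benthic dives over the shelf
    (``departure_run``), transit dives crossing the slope (``approach``),
    the interior mixture over deep water out and back (``interior``), a
    returning slope crossing, and a closing benthic run (``arrival_run``).
    Horizontal distance advances at a constant ground speed per phase, so
    the 3-h track fixes resolve the crossings.
    """
    dt = cfg.sampling_interval
    run = cfg.shelf_run_length
    n_int = cfg.n_dives
    d0 = cfg.shelf_width_km + cfg.slope_width_km + 1.0  # start of deep water
    shelf_edge = 0.92 * cfg.shelf_width_km

    lead_in = int(round(120.0 / dt))
    segments = [np.zeros(lead_in)]
    records = []
    state = {"idx": lead_in, "dive_index": 0, "d": 0.5 * cfg.shelf_width_km}

    def emit(dive_type, phase, direction, speed_ms, sub=False,
             d_min=4.5, d_max=None):
        bathy = seafloor_depth(state["d"], cfg)
        depths, truth = simulate_dive(dive_type, bathy, rng, cfg, subthreshold=sub)
        n_surf = int(round(rng.uniform(90.0, 180.0) / dt))
        truth.update({
            "dive_index": state["dive_index"],
            "trip_phase": phase,
            "start_idx": state["idx"],
            "end_idx": state["idx"] + len(depths) - 1,
            "dist_colony_km": float(state["d"]),
            "true_on_shelf": (dive_type == "benthic" and not sub
                              and float(depths.max()) <= 140.0),
        })
        records.append(truth)
        segments.append(depths)
        segments.append(np.zeros(n_surf))
        state["idx"] += len(depths) + n_surf
        state["dive_index"] += 1
        step = direction * speed_ms / 1000.0 * (len(depths) + n_surf) * dt
        new_d = state["d"] + step
        if d_max is not None:
            new_d = min(new_d, d_max)
        state["d"] = max(new_d, d_min)

    for _ in range(run):  # departure shelf run, moving offshore
        emit("benthic", "departure_run", +1, cfg.travel_speed_ms)
    while state["d"] < d0:  # directed travel across the slope
        emit("transit", "approach", +1, cfg.approach_speed_ms)
    types = rng.choice(DIVE_TYPES, size=n_int, p=[cfg.dive_mix[t] for t in DIVE_TYPES])
    sub_slots = (set(rng.choice(np.arange(n_int), size=cfg.n_subthreshold,
                                replace=False).tolist())
                 if cfg.n_subthreshold > 0 else set())
    n_out = (n_int + 1) // 2
    for i, dive_type in enumerate(types):  # deep-water interior, out and back
        if i in sub_slots:
            emit(str(dive_type), "interior", 0, 0.0, sub=True, d_min=d0)
        direction = +1 if i < n_out else -1
        emit(str(dive_type), "interior", direction, cfg.travel_speed_ms, d_min=d0)
    while state["d"] > shelf_edge:  # homeward slope crossing
        emit("transit", "approach", -1, cfg.approach_speed_ms)
    for _ in range(run):  # arrival shelf run, moving inshore
        emit("benthic", "arrival_run", -1, cfg.travel_speed_ms)

    depth_true = np.concatenate(segments)
    n = len(depth_true)
    t0 = _trip_start(cfg, rng)
    time = (np.datetime64(t0.to_datetime64(), "ns")
            + (np.arange(n) * int(dt * 1e9)).astype("timedelta64[ns]"))
    elapsed_h = np.arange(n) * dt / 3600.0
    offset = rng.choice([-1.0, 1.0]) * cfg.surface_offset_drift * elapsed_h
    noise = np.clip(rng.normal(0.0, cfg.depth_noise_sd, n),
                    -3 * cfg.depth_noise_sd, 3 * cfg.depth_noise_sd)
    depth_raw = depth_true + offset + noise

    truth_df = pd.DataFrame(records)
    truth_df["start_time"] = time[truth_df["start_idx"].to_numpy()]
    truth_df["end_time"] = time[truth_df["end_idx"].to_numpy()]

    real = truth_df[~truth_df["subthreshold"]].reset_index(drop=True)
    flags = real["true_on_shelf"].to_numpy()
    dep_last = run - 1
    arr_first = len(real) - run
    shelf_truth = {
        "departure_block_start": pd.Timestamp(real.loc[0, "start_time"]),
        "departure_block_end": pd.Timestamp(real.loc[dep_last, "start_time"]),
        "departure_transition": pd.Timestamp(real.loc[dep_last + 1, "start_time"]),
        "departure_duration_h": (pd.Timestamp(real.loc[dep_last, "start_time"])
                                 - pd.Timestamp(real.loc[0, "start_time"])
                                 ).total_seconds() / 3600.0,
        "arrival_transition": pd.Timestamp(real.loc[arr_first, "start_time"]),
        "arrival_block_end": pd.Timestamp(real.loc[len(real) - 1, "start_time"]),
        "arrival_duration_h": (pd.Timestamp(real.loc[len(real) - 1, "start_time"])
                               - pd.Timestamp(real.loc[arr_first, "start_time"])
                               ).total_seconds() / 3600.0,
    }
    assert flags[:run].all() and flags[arr_first:].all()

    # 3-h track fixes following the distance profile along a due-west path
    lon_c, lat_c = cfg.colony
    km_per_deg = np.pi / 180.0 * EARTH_RADIUS_KM * np.cos(np.radians(lat_c))
    mid_s = ((truth_df["start_idx"] + truth_df["end_idx"]) / 2.0 * dt).to_numpy()
    dists = truth_df["dist_colony_km"].to_numpy(dtype=float)
    fix_s = np.arange(0.0, (n - 1) * dt, 3.0 * 3600.0)
    fix_s = np.append(fix_s, (n - 1) * dt)  # final fix at the record end
    fix_d = np.interp(fix_s, mid_s, dists)
    track = pd.DataFrame({
        "time": time[0] + (fix_s * 1e9).astype(np.int64).astype("timedelta64[ns]"),
        "lon": lon_c - fix_d / km_per_deg,
        "lat": np.full(len(fix_s), lat_c),
    })

    mass = float(rng.normal(330.0 if cfg.season == "post_breeding" else 400.0, 40.0))
    return TripData(
        animal_id=animal_id, season=cfg.season,
        time=time, depth_raw=depth_raw, depth_true=depth_true, interval=dt,
        track=track, truth=truth_df,
        departure_time=pd.Timestamp(real.loc[0, "start_time"]),
        arrival_time=pd.Timestamp(real.loc[len(real) - 1, "start_time"]),
        shelf_truth=shelf_truth,
        departure_mass_kg=mass,
        age_yr=int(rng.integers(3, 15)),
        tag_type=str(rng.choice(["Argos", "Argos+GPS"], p=[0.78, 0.22])),
    )


@dataclass
class CohortData:
    config: SimConfig
    trips: list
    bathymetry: BathymetryGrid
    predator_geojson: dict


def simulate_cohort(cfg: SimConfig) -> CohortData:
    """n_seals independent trips sharing one bathymetry and predator map;
    fully determined by cfg.seed."""
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_seals)
    tag = "".join(w[0] for w in cfg.season.split("_"))  # pb / pm
    trips = [
        simulate_trip(cfg, np.random.default_rng(ss), animal_id=f"{tag}{k:03d}")
        for k, ss in enumerate(streams)
    ]
    return CohortData(config=cfg, trips=trips,
                      bathymetry=simulate_bathymetry(cfg),
                      predator_geojson=default_predator_areas(cfg))


def write_cohort(cohort: CohortData, outdir) -> dict:
    """Write the cohort as plain-text files: per-seal depth/track/truth CSVs,
    an ESRI ASCII bathymetry grid, predator GeoJSON, and seal metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"seals": []}
    meta_rows = []
    for trip in cohort.trips:
        stem = outdir / trip.animal_id
        pd.DataFrame({"time": trip.time, "depth": trip.depth_raw}).to_csv(
            f"{stem}_depth.csv", index=False)
        trip.track.to_csv(f"{stem}_track.csv", index=False)
        trip.truth.to_csv(f"{stem}_truth.csv", index=False)
        paths["seals"].append(str(stem))
        meta_rows.append({
            "animal_id": trip.animal_id, "season": trip.season,
            "departure_mass_kg": round(trip.departure_mass_kg, 1),
            "age_yr": trip.age_yr, "tag_type": trip.tag_type,
        })
    cohort.bathymetry.to_ascii(outdir / "bathymetry.asc")
    with open(outdir / "predators.geojson", "w") as fh:
        json.dump(cohort.predator_geojson, fh)
    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.csv", index=False)
    paths["bathymetry"] = str(outdir / "bathymetry.asc")
    paths["predators"] = str(outdir / "predators.geojson")
    paths["metadata"] = str(outdir / "metadata.csv")
    return paths
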