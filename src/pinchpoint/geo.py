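"""Track interpolation, geodesy, bathymetry lookup, and predator-area
membership.

Tracks arrive as irregular satellite fixes; downstream analyses need a
regular 3-h track. Fixes implying travel faster than a 3 m/s cap are
dropped (forward pass), and the survivors are interpolated along great
circles. Bathymetry is a regular lon/lat raster of seafloor depth in
metres positive down (land = 0), read/written as ESRI ASCII grid, with
nearest-cell lookup. Predator areas are GeoJSON polygons (WGS84 lon/lat).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape

EARTH_RADIUS_KM = 6371.0088
COLONY_LONLAT = (-122.34, 37.11)  # Ano Nuevo colony


def normalize_lon(lon):
    """Wrap longitude into (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    wrapped = -((-lon + 180.0) % 360.0 - 180.0)
    out = np.where(wrapped == -180.0, 180.0, wrapped)
    return float(out) if out.ndim == 0 else out


def great_circle_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Haversine distance in km between (lon, lat) points on a sphere of
    radius 6371.0088 km."""
    lon1, lat1 = np.radians(a[0]), np.radians(a[1])
    lon2, lat2 = np.radians(b[0]), np.radians(b[1])
    s = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0))))


def _to_cartesian(lon: float, lat: float) -> np.ndarray:
    lam, phi = np.radians(lon), np.radians(lat)
    return np.array([np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)])


def _to_lonlat(v: np.ndarray) -> tuple[float, float]:
    v = v / np.linalg.norm(v)
    lat = np.degrees(np.arcsin(np.clip(v[2], -1, 1)))
    lon = np.degrees(np.arctan2(v[1], v[0]))
    return normalize_lon(lon), float(lat)


def great_circle_interpolate(a: Sequence[float], b: Sequence[float],
                             f: float) -> tuple[float, float]:
    """Point a fraction f of the way from a to b along the great circle."""
    va, vb = _to_cartesian(*a), _to_cartesian(*b)
    dot = float(np.clip(np.dot(va, vb), -1.0, 1.0))
    omega = np.arccos(dot)
    if omega < 1e-12:
        return normalize_lon(a[0]), float(a[1])
    v = (np.sin((1 - f) * omega) * va + np.sin(f * omega) * vb) / np.sin(omega)
    return _to_lonlat(v)


def speed_filter(fixes: pd.DataFrame, vmax: float = 3.0) -> pd.DataFrame:
    """Forward-pass filter: drop fixes implying speed > vmax (m/s) relative
    to the last retained fix."""
    t = pd.to_datetime(fixes["time"]).to_numpy(dtype="datetime64[ns]")
    lon = fixes["lon"].to_numpy(dtype=float)
    lat = fixes["lat"].to_numpy(dtype=float)
    keep = [0]
    for i in range(1, len(fixes)):
        j = keep[-1]
        dt = (t[i] - t[j]).astype("timedelta64[ns]").astype(np.int64) / 1e9
        if dt <= 0:
            continue
        d_m = great_circle_distance((lon[j], lat[j]), (lon[i], lat[i])) * 1000.0
        if d_m / dt <= vmax:
            keep.append(i)
    return fixes.iloc[keep].reset_index(drop=True)


def interpolate_track(fixes: pd.DataFrame, step: float = 3.0,
                      vmax: float = 3.0) -> pd.DataFrame:
    """Regularize a fix sequence to exact ``step``-hour timestamps spanning
    the trip, interpolating along great circles after speed filtering.

    ``fixes`` needs columns time, lon, lat. Raises on < 2 surviving fixes.
    """
    fixes = fixes.sort_values("time").reset_index(drop=True)
    filt = speed_filter(fixes, vmax=vmax)
    if len(filt) < 2:
        raise ValueError("fewer than 2 fixes survive the speed filter")
    t = pd.to_datetime(filt["time"]).to_numpy(dtype="datetime64[ns]")
    lon = filt["lon"].to_numpy(dtype=float)
    lat = filt["lat"].to_numpy(dtype=float)
    step_ns = np.timedelta64(int(step * 3600 * 1e9), "ns")
    grid = np.arange(t[0], t[-1], step_ns)
    # span the whole trip: close with the final fix time so positions near
    # the trip end are interpolated, not pinned to an offshore endpoint
    if len(grid) == 0 or grid[-1] != t[-1]:
        grid = np.append(grid, t[-1])
    out_lon = np.empty(len(grid))
    out_lat = np.empty(len(grid))
    tt = t.astype(np.int64)
    for k, g in enumerate(grid.astype(np.int64)):
        i = int(np.searchsorted(tt, g, side="right")) - 1
        i = min(max(i, 0), len(tt) - 2)
        span = tt[i + 1] - tt[i]
        f = 0.0 if span == 0 else (g - tt[i]) / span
        out_lon[k], out_lat[k] = great_circle_interpolate(
            (lon[i], lat[i]), (lon[i + 1], lat[i + 1]), float(np.clip(f, 0, 1)))
    return pd.DataFrame({"time": grid, "lon": out_lon, "lat": out_lat})


def locate_dive(dive_time, track: pd.DataFrame) -> tuple[float, float, str]:
    """Great-circle time-interpolated position at a dive's start time.

    Times outside the track span map to the nearest endpoint with an
    ``extrapolated`` flag.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    t = pd.to_datetime(track["time"]).to_numpy(dtype="datetime64[ns]").astype(np.int64)
    g = np.datetime64(dive_time, "ns").astype(np.int64)
    lon = track["lon"].to_numpy(dtype=float)
    lat = track["lat"].to_numpy(dtype=float)
    if g <= t[0]:
        return float(lon[0]), float(lat[0]), "extrapolated" if g < t[0] else ""
    if g >= t[-1]:
        return float(lon[-1]), float(lat[-1]), "extrapolated" if g > t[-1] else ""
    i = int(np.searchsorted(t, g, side="right")) - 1
    f = (g - t[i]) / (t[i + 1] - t[i])
    plon, plat = great_circle_interpolate((lon[i], lat[i]), (lon[i + 1], lat[i + 1]), float(f))
    return plon, plat, ""


@dataclass
class BathymetryGrid:
    """Regular lon/lat raster of seafloor depth, metres positive down.

    ``depth[i, j]`` corresponds to latitude ``lat0 + i*cellsize`` and
    longitude ``lon0 + j*cellsize`` (cell centres, row 0 = southernmost).
    Land cells are 0.
    """

    lon0: float
    lat0: float
    cellsize: float
    depth: np.ndarray  # (nlat, nlon)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if np.any(self.depth < 0):
            raise ValueError("seafloor depth must be >= 0 (positive down)")

    @property
    def lons(self) -> np.ndarray:
        return self.lon0 + self.cellsize * np.arange(self.depth.shape[1])

    @property
    def lats(self) -> np.ndarray:
        return self.lat0 + self.cellsize * np.arange(self.depth.shape[0])

    def lookup(self, lon: float, lat: float) -> float:
        """Nearest-cell seafloor depth; raises outside the grid bounds."""
        j = int(round((lon - self.lon0) / self.cellsize))
        i = int(round((lat - self.lat0) / self.cellsize))
        nlat, nlon = self.depth.shape
        if not (0 <= i < nlat and 0 <= j < nlon):
            raise ValueError(f"point ({lon}, {lat}) outside bathymetry grid")
        return float(self.depth[i, j])

    def to_ascii(self, path, nodata: float = -9999.0) -> None:
        """Write as ESRI ASCII grid (rows north-to-south, elevation sign
        flipped so the file stores negative-down values like ETOPO)."""
        nlat, nlon = self.depth.shape
        header = (
            f"ncols {nlon}\n"
            f"nrows {nlat}\n"
            f"xllcorner {self.lon0 - self.cellsize / 2}\n"
            f"yllcorner {self.lat0 - self.cellsize / 2}\n"
            f"cellsize {self.cellsize}\n"
            f"NODATA_value {nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            for row in self.depth[::-1]:  # top row first
                fh.write(" ".join(f"{-v:.1f}" for v in row) + "\n")

    @classmethod
    def from_ascii(cls, path) -> "BathymetryGrid":
        """Read an ESRI ASCII grid of elevations; positive (above-surface)
        values are clamped to 0 and the rest converted to positive-down."""
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                key = parts[0].lower()
                if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                           "cellsize", "nodata_value"):
                    meta[key] = float(parts[1])
                else:
                    rows.append([float(p) for p in parts])
        elev = np.array(rows, dtype=float)[::-1]  # back to south-first
        if elev.shape != (int(meta["nrows"]), int(meta["ncols"])):
            raise ValueError("grid shape does not match header")
        nodata = meta.get("nodata_value")
        if nodata is not None:
            elev[elev == nodata] = 0.0
        depth = np.where(elev > 0, 0.0, -elev)
        cs = meta["cellsize"]
        return cls(lon0=meta["xllcorner"] + cs / 2,
                   lat0=meta["yllcorner"] + cs / 2,
                   cellsize=cs, depth=depth)


def assign_bathymetry(lon: float, lat: float, grid: BathymetryGrid) -> float:
    """Nearest-cell seafloor depth (m, positive down) at a dive location."""
    return grid.lookup(lon, lat)


class PredatorAreas:
    """Named predator polygons loaded from GeoJSON (WGS84 lon/lat)."""

    def __init__(self, polygons: dict):
        self.polygons = {}
        for name, geom in polygons.items():
            if not geom.is_valid:
                raise ValueError(f"invalid polygon ring for {name!r}")
            self.polygons[name] = geom

    @classmethod
    def from_geojson(cls, path) -> "PredatorAreas":
        with open(path) as fh:
            gj = json.load(fh)
        polys = {}
        for feat in gj.get("features", []):
            name = feat.get("properties", {}).get("name", f"area{len(polys)}")
            polys[name] = shape(feat["geometry"])
        return cls(polys)

    def membership(self, lon: float, lat: float) -> dict:
        """Point-in-polygon flags per named area plus the shark/orca overlap
        (boundary points count as inside)."""
        p = Point(lon, lat)
        flags = {name: bool(poly.covers(p)) for name, poly in self.polygons.items()}
        flags["overlap"] = flags.get("shark", False) and flags.get("orca", False)
        return flags


def in_predator_area(lon: float, lat: float, areas: PredatorAreas) -> dict:
    return areas.membership(lon, lat)


def geolocate_dives(dives, track: pd.DataFrame, grid: Optional[BathymetryGrid] = None,
                    areas: Optional[PredatorAreas] = None,
                    colony: Sequence[float] = COLONY_LONLAT) -> pd.DataFrame:
    """Assign location, bathymetry, colony distance and predator-area flags
    to each dive (in place); returns a per-dive location table."""
    rows = []
    for i, d in enumerate(dives):
        lon, lat, flag = locate_dive(d.start_time, track)
        d.lon, d.lat, d.location_flag = lon, lat, flag
        d.dist_colony_km = great_circle_distance((lon, lat), colony)
        if grid is not None:
            try:
                d.bathymetry = assign_bathymetry(lon, lat, grid)
            except ValueError:
                d.bathymetry = None
        memb = areas.membership(lon, lat) if areas is not None else {}
        rows.append({"dive_id": i, "lon": lon, "lat": lat,
                     "bathy_m": d.bathymetry, "dist_colony_km": d.dist_colony_km,
                     "in_shark": memb.get("shark", False),
                     "in_orca": memb.get("orca", False),
                     "in_overlap": memb.get("overlap", False),
                     "location_flag": flag})
    return pd.DataFrame(rows)
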