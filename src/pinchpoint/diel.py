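"""Solar events, day/night assignment, and circular statistics for
departure/arrival timing.

Sunrise and sunset are computed with the NOAA solar-position equations
(fractional-year expansion for the equation of time and solar declination,
zenith 90.833 deg so that standard refraction and the solar radius are
included); accuracy is within about two minutes of the NOAA calculator for
non-polar latitudes. A dive starting between local sunrise (inclusive) and
the subsequent sunset is daytime; otherwise nighttime.

Event clock hours are mapped to angles theta = 2*pi*hour/24 and summarized
by the mean resultant length R_bar, the circular mean hour, and the
Rayleigh test of uniformity (Z = n*R_bar^2, with Zar's series
approximation for the p-value).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SOLAR_ZENITH_DEG = 90.833
COLONY_UTC_OFFSET_H = -7.0  # Pacific Daylight Time at the Ano Nuevo colony


def _fractional_year(ts: pd.Timestamp) -> float:
    doy = ts.dayofyear
    hour = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    return 2.0 * np.pi / 365.0 * (doy - 1 + (hour - 12.0) / 24.0)


def _equation_of_time_min(g: float) -> float:
    return 229.18 * (0.000075 + 0.001868 * np.cos(g) - 0.032077 * np.sin(g)
                     - 0.014615 * np.cos(2 * g) - 0.040849 * np.sin(2 * g))


def _solar_declination_rad(g: float) -> float:
    return (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
            - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
            - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))


def sun_events(lon: float, lat: float, date) -> tuple[Optional[pd.Timestamp],
                                                      Optional[pd.Timestamp]]:
    """(sunrise, sunset) in UTC for the given calendar date at (lon, lat).

    Returns (None, None) for polar day/night (no crossing of the 90.833 deg
    zenith on that date). Longitude positive east.
    """
    date = pd.Timestamp(date).normalize()
    g = _fractional_year(date + pd.Timedelta(hours=12))
    eqt = _equation_of_time_min(g)
    decl = _solar_declination_rad(g)
    phi = np.radians(lat)
    cos_ha = (np.cos(np.radians(SOLAR_ZENITH_DEG)) / (np.cos(phi) * np.cos(decl))
              - np.tan(phi) * np.tan(decl))
    if cos_ha < -1.0 or cos_ha > 1.0:
        return None, None  # polar day or polar night
    ha_deg = np.degrees(np.arccos(cos_ha))
    sunrise_min = 720.0 - 4.0 * (lon + ha_deg) - eqt
    sunset_min = 720.0 - 4.0 * (lon - ha_deg) - eqt
    return (date + pd.Timedelta(minutes=float(sunrise_min)),
            date + pd.Timedelta(minutes=float(sunset_min)))


def assign_day_night(dive_start, lon: float, lat: float) -> str:
    """'day' iff the dive starts in [sunrise, following sunset), else 'night'.

    Raises for polar day/night dates, which do not occur at study latitudes.
    """
    t = pd.Timestamp(dive_start)
    events = []
    for delta in (-1, 0, 1):
        rise, set_ = sun_events(lon, lat, t.normalize() + pd.Timedelta(days=delta))
        if rise is None:
            raise ValueError("polar day/night: day/night assignment undefined")
        events.append((rise, "rise"))
        events.append((set_, "set"))
    events.sort()
    last = None
    for when, kind in events:
        if when <= t:
            last = kind
        else:
            break
    if last is None:  # before all events: night if next event is a sunrise
        return "night" if events[0][1] == "rise" else "day"
    return "day" if last == "rise" else "night"


def hours_to_angles(hours: Sequence[float]) -> np.ndarray:
    """Clock hours in [0, 24) to angles in [0, 2*pi)."""
    return (2.0 * np.pi * np.asarray(hours, dtype=float) / 24.0) % (2.0 * np.pi)


def local_hour(ts, utc_offset_h: float = COLONY_UTC_OFFSET_H) -> float:
    """Fractional clock hour in [0, 24) after applying a fixed UTC offset."""
    t = pd.Timestamp(ts) + pd.Timedelta(hours=utc_offset_h)
    return (t.hour + t.minute / 60.0 + t.second / 3600.0) % 24.0


def solar_hour(ts, lon: float) -> float:
    """Local mean solar hour at the event's longitude (UTC + lon/15)."""
    t = pd.Timestamp(ts)
    return (t.hour + t.minute / 60.0 + t.second / 3600.0 + lon / 15.0) % 24.0


@dataclass
class CircularSummary:
    n: int
    R_bar: float          # mean resultant length in [0, 1]
    mean_hour: float      # circular mean, clock hours in [0, 24)
    rayleigh_p: float     # probability in (0, 1]


def mean_resultant(theta: Sequence[float]) -> tuple[float, float]:
    """Mean resultant length R_bar and circular mean hour of a sample of
    angles (radians)."""
    theta = np.asarray(theta, dtype=float)
    if len(theta) == 0:
        raise ValueError("empty circular sample")
    C, S = np.cos(theta).sum(), np.sin(theta).sum()
    r_bar = float(np.hypot(C, S) / len(theta))
    mean_hour = float((np.arctan2(S, C) * 24.0 / (2.0 * np.pi)) % 24.0)
    return r_bar, mean_hour


def rayleigh_test(theta: Sequence[float], method: str = "series",
                  n_sim: int = 10000, rng=None) -> float:
    """Rayleigh test of circular uniformity; returns the p-value.

    ``series`` uses Zar's large-sample approximation
    p = exp(-Z) * [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]
    with Z = n * R_bar^2, clamped to (0, 1]. ``simulation`` estimates p by
    Monte Carlo under uniformity (useful for very small n).
    """
    theta = np.asarray(theta, dtype=float)
    n = len(theta)
    if n < 3:
        raise ValueError("Rayleigh test requires n >= 3")
    r_bar, _ = mean_resultant(theta)
    if method == "series":
        Z = n * r_bar ** 2
        p = np.exp(-Z) * (1.0 + (2.0 * Z - Z ** 2) / (4.0 * n)
                          - (24.0 * Z - 132.0 * Z ** 2 + 76.0 * Z ** 3
                             - 9.0 * Z ** 4) / (288.0 * n ** 2))
        return float(min(max(p, np.finfo(float).tiny), 1.0))
    if method == "simulation":
        rng = np.random.default_rng(rng)
        sims = rng.uniform(0.0, 2.0 * np.pi, size=(n_sim, n))
        C = np.cos(sims).sum(axis=1)
        S = np.sin(sims).sum(axis=1)
        r_sim = np.hypot(C, S) / n
        return float((1 + np.sum(r_sim >= r_bar)) / (n_sim + 1))
    raise ValueError(f"unknown method {method!r}")


def circular_summary(theta: Sequence[float], method: str = "series") -> CircularSummary:
    theta = np.asarray(theta, dtype=float)
    r_bar, mean_hour = mean_resultant(theta)
    p = rayleigh_test(theta, method=method)
    return CircularSummary(n=len(theta), R_bar=r_bar, mean_hour=mean_hour, rayleigh_p=p)


def departure_arrival_summary(events: pd.DataFrame,
                              utc_offset_h: float = COLONY_UTC_OFFSET_H
                              ) -> pd.DataFrame:
    """Circular summaries of first-dive (departure) and last-dive (arrival)
    timing per phase (and per season when present).

    ``events`` needs columns phase, time (UTC), and optionally season, lon,
    lat. Hours are colony local clock time by default; a per-event solar
    hour is also reported when longitudes are available.
    """
    df = events.copy()
    df["hour"] = [local_hour(t, utc_offset_h) for t in df["time"]]
    keys = ["phase"] + (["season"] if "season" in df.columns else [])
    rows = []
    for key, grp in df.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        theta = hours_to_angles(grp["hour"])
        if len(theta) >= 3:
            s = circular_summary(theta)
            row = dict(zip(keys, key))
            row.update({"n": s.n, "R_bar": s.R_bar, "mean_hour": s.mean_hour,
                        "rayleigh_p": s.rayleigh_p})
            rows.append(row)
    return pd.DataFrame(rows)
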