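"""Time-depth-recorder processing: zero-offset correction, dive detection,
phase segmentation and per-dive metrics.

Depth is positive-down everywhere (metres). A *dive* is a maximal excursion
below a small surface gate whose maximum depth and duration both clear the
detection thresholds (25 m / 32 s by default, the convention for adult
female northern elephant seal records). The *bottom phase* is the span
between the first and last sample deeper than 80% of the dive's maximum
depth, a standard convention in the pinniped literature; descent and ascent
are the samples before and after it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

SURFACE_THRESHOLD_M = 2.0  # surface gate for dive start/end (below 25-m qualifier)
BOTTOM_FRACTION = 0.8  # bottom phase = depth >= this fraction of max depth


@dataclass
class DepthSeries:
    """One animal-trip's regular depth record.

    Parameters
    ----------
    animal_id : str
    time : np.ndarray of datetime64[ns], strictly increasing, regular
    depth : np.ndarray of float, metres positive down
    interval : float, sampling interval in seconds
    """

    animal_id: str
    time: np.ndarray
    depth: np.ndarray
    interval: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype="datetime64[ns]")
        self.depth = np.asarray(self.depth, dtype=float)
        if self.time.shape != self.depth.shape:
            raise ValueError("time and depth must have equal length")
        if len(self.time) > 1:
            dt = np.diff(self.time).astype("timedelta64[ns]").astype(np.int64)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.depth)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "depth": self.depth})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, animal_id: str = "",
                   interval: Optional[float] = None) -> "DepthSeries":
        t = pd.to_datetime(df["time"]).to_numpy(dtype="datetime64[ns]")
        if interval is None:
            if len(t) < 2:
                raise ValueError("cannot infer interval from < 2 samples")
            interval = float(np.diff(t).astype("timedelta64[ns]").astype(np.int64).min()) / 1e9
        return cls(animal_id, t, df["depth"].to_numpy(dtype=float), interval)


@dataclass
class DiveMetrics:
    """Per-dive summary metrics.

    W: wiggle count in the bottom phase (vertical direction reversals with
    amplitude >= the wiggle threshold); V: total vertical distance in the
    bottom phase (m); R: bottom-phase depth range (m); T: bottom duration (s).
    Rates in m/s; intervals in s.
    """

    W: int = 0
    V: float = 0.0
    R: float = 0.0
    T: float = 0.0
    descent_rate: float = 0.0
    ascent_rate: float = 0.0
    bottom_time: float = 0.0
    post_dive_interval: float = np.nan
    mean_depth: float = 0.0


@dataclass
class Dive:
    """One detected dive with boundaries, phases, metrics, and labels."""

    start_idx: int
    end_idx: int  # inclusive index of last submerged sample
    start_time: np.datetime64
    end_time: np.datetime64
    max_depth: float
    duration: float  # s, submerged-sample count * interval
    descent_end_idx: int = 0  # phase boundaries, relative to dive slice
    bottom_end_idx: int = 0
    degenerate_phases: bool = False
    metrics: DiveMetrics = field(default_factory=DiveMetrics)
    lon: Optional[float] = None
    lat: Optional[float] = None
    location_flag: str = ""
    bathymetry: Optional[float] = None
    dist_colony_km: Optional[float] = None
    type: Optional[str] = None

    def slice(self, series: DepthSeries) -> np.ndarray:
        return series.depth[self.start_idx:self.end_idx + 1]

    def times(self, series: DepthSeries) -> np.ndarray:
        return series.time[self.start_idx:self.end_idx + 1]


def zero_offset_correct(series: DepthSeries, window: float = 30.0) -> DepthSeries:
    """Remove slow pressure-transducer drift so surface intervals read 0 m.

    A centred rolling minimum over ``window`` minutes estimates the surface
    baseline at every sample (any window that long contains at least one
    surface interval for dives shorter than the window); the baseline is
    subtracted and the result clipped at 0. Applying the correction twice
    is the same as applying it once.
    """
    if len(series) == 0 or np.all(np.isnan(series.depth)):
        raise ValueError("depth series is empty or all-missing")
    n_win = max(1, int(round(window * 60.0 / series.interval)) | 1)  # odd
    baseline = (
        pd.Series(series.depth)
        .rolling(n_win, center=True, min_periods=1)
        .min()
        .to_numpy()
    )
    corrected = np.clip(series.depth - baseline, 0.0, None)
    return replace(series, depth=corrected)


def downsample(series: DepthSeries, target: float = 8.0) -> DepthSeries:
    """Decimate to the target interval by keeping every k-th sample.

    ``target`` must be an integer multiple of the native interval.
    """
    ratio = target / series.interval
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"target {target}s is not an integer multiple of native interval "
            f"{series.interval}s"
        )
    if k == 1:
        return series
    return DepthSeries(series.animal_id, series.time[::k], series.depth[::k], float(target))


def detect_dives(
    series: DepthSeries,
    min_depth: float = 25.0,
    min_duration: float = 32.0,
    surface_threshold: float = SURFACE_THRESHOLD_M,
) -> list[Dive]:
    """Find dives: maximal spans below the surface gate that reach at least
    ``min_depth`` and last at least ``min_duration`` (both inclusive).

    Duration is counted as submerged samples x interval, so dive durations
    plus surface-interval durations add up exactly to the record span.
    The post-dive interval of dive i is start(i+1) - end(i).
    """
    submerged = series.depth > surface_threshold
    if not submerged.any():
        return []
    # run boundaries of submerged spans
    padded = np.concatenate(([False], submerged, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]  # [start, stop) sample spans
    dives: list[Dive] = []
    for i0, i1 in zip(starts, stops):
        n = i1 - i0
        dur = n * series.interval
        dmax = float(series.depth[i0:i1].max())
        if dmax >= min_depth and dur >= min_duration:
            dives.append(
                Dive(
                    start_idx=int(i0),
                    end_idx=int(i1 - 1),
                    start_time=series.time[i0],
                    end_time=series.time[i1 - 1],
                    max_depth=dmax,
                    duration=float(dur),
                )
            )
    for a, b in zip(dives, dives[1:]):
        a.metrics.post_dive_interval = (
            (b.start_time - a.end_time).astype("timedelta64[ns]").astype(np.int64) / 1e9
        )
    return dives


def segment_phases(dive: Dive, depths: np.ndarray,
                   bottom_fraction: float = BOTTOM_FRACTION) -> tuple[int, int]:
    """Locate descent/bottom/ascent boundaries within the dive slice.

    Bottom phase = contiguous span between the first and last sample with
    depth >= bottom_fraction * max_depth. Dives too short to segment get a
    degenerate single-sample bottom phase and are flagged.
    """
    if len(depths) < 5:
        apex = int(np.argmax(depths))
        dive.descent_end_idx = apex
        dive.bottom_end_idx = apex
        dive.degenerate_phases = True
        return apex, apex
    cutoff = bottom_fraction * depths.max()
    deep = np.flatnonzero(depths >= cutoff)
    dive.descent_end_idx = int(deep[0])
    dive.bottom_end_idx = int(deep[-1])
    dive.degenerate_phases = False
    return dive.descent_end_idx, dive.bottom_end_idx


def count_wiggles(bottom: np.ndarray, threshold: float) -> tuple[int, float, float]:
    """Count monotone vertical excursions of amplitude >= threshold in the
    bottom trace; also return V (total vertical distance) and R (range)."""
    if len(bottom) < 2:
        return 0, 0.0, 0.0
    diffs = np.diff(bottom)
    V = float(np.abs(diffs).sum())
    R = float(bottom.max() - bottom.min())
    W = 0
    run = 0.0
    sign = 0
    for d in diffs:
        s = 0 if d == 0 else (1 if d > 0 else -1)
        if s == 0 or s == sign or sign == 0:
            run += d
            if s != 0:
                sign = s
        else:  # reversal: close the current monotone excursion
            if abs(run) >= threshold:
                W += 1
            run = d
            sign = s
    if abs(run) >= threshold:
        W += 1
    return W, V, R


def compute_metrics(dive: Dive, depths: np.ndarray, interval: float,
                    wiggle_threshold: float = 5.0) -> DiveMetrics:
    """Fill in bottom-phase and rate metrics for a segmented dive."""
    d_end, b_end = dive.descent_end_idx, dive.bottom_end_idx
    bottom = depths[d_end:b_end + 1]
    W, V, R = count_wiggles(bottom, wiggle_threshold)
    T = (b_end - d_end) * interval
    desc_dur = max(d_end, 1) * interval
    asc_dur = max(len(depths) - 1 - b_end, 1) * interval
    m = DiveMetrics(
        W=W,
        V=V,
        R=R,
        T=float(T),
        descent_rate=float(depths[d_end] / desc_dur),
        ascent_rate=float(depths[b_end] / asc_dur),
        bottom_time=float(T),
        post_dive_interval=dive.metrics.post_dive_interval,
        mean_depth=float(depths.mean()),
    )
    dive.metrics = m
    return m


def process_series(
    series: DepthSeries,
    min_depth: float = 25.0,
    min_duration: float = 32.0,
    wiggle_threshold: float = 5.0,
    zoc_window: float = 30.0,
    resample: Optional[float] = 8.0,
) -> tuple[DepthSeries, list[Dive]]:
    """Convenience driver: zero-offset correct, optionally downsample,
    detect dives, segment phases and compute metrics."""
    s = zero_offset_correct(series, window=zoc_window)
    if resample is not None and resample > s.interval:
        s = downsample(s, resample)
    dives = detect_dives(s, min_depth=min_depth, min_duration=min_duration)
    for d in dives:
        depths = d.slice(s)
        segment_phases(d, depths)
        compute_metrics(d, depths, s.interval, wiggle_threshold)
    return s, dives


def dives_to_frame(dives: list[Dive]) -> pd.DataFrame:
    """One row per dive with all metrics, suitable for CSV export."""
    rows = []
    for i, d in enumerate(dives):
        m = d.metrics
        rows.append({
            "dive_id": i,
            "start_time": pd.Timestamp(d.start_time),
            "end_time": pd.Timestamp(d.end_time),
            "max_depth": d.max_depth,
            "duration_s": d.duration,
            "W": m.W, "V": m.V, "R": m.R, "T": m.T,
            "descent_rate": m.descent_rate,
            "ascent_rate": m.ascent_rate,
            "bottom_time": m.bottom_time,
            "post_dive_interval": m.post_dive_interval,
            "mean_depth": m.mean_depth,
            "lon": d.lon, "lat": d.lat,
            "bathymetry": d.bathymetry,
            "dist_colony_km": d.dist_colony_km,
            "type": d.type,
        })
    return pd.DataFrame(rows)
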