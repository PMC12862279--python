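"""Dive-type classification: foraging, drift, benthic, or transit.

Each detected dive receives exactly one label, tested in a fixed order:

1. *Foraging* — the foraging intensity index FII = (W*V/R) * (1 + V/T)
   exceeds 35, where W is the bottom-phase wiggle count, V the total
   vertical distance travelled during the bottom phase (m), R the
   bottom-phase depth range (m), and T the bottom duration (s).
2. *Drift* — a Gaussian kernel density estimate of the dive's vertical
   speed (first differences of the depth trace) has a peak whose height
   exceeds a density of 1 s/m: a large fraction of the dive is spent
   sinking or rising at one constant rate (the drift rate = peak location).
3. *Benthic* — the dive tracks the seafloor: (a) |max depth - bathymetry|
   < 100 m; (b) the bottom-phase vertical-speed KDE peaks within
   +/-0.08 m/s of zero with height > 1.5 (flat, consistent bottom); and
   (c) least-squares lines through the descent and bottom phases intersect
   within 15 m (vertically) of the observed trajectory (square corner).
4. *Transit* — anything that meets none of the above.

Thresholds follow the published convention for Ano Nuevo elephant-seal
records and are strict inequalities except the +/-0.08 m/s window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .tdr import Dive, DiveMetrics

DIVE_TYPES = ("transit", "foraging", "drift", "benthic")


@dataclass
class ClassifierThresholds:
    fii_threshold: float = 35.0          # dimensionless, strict >
    drift_peak_height: float = 1.0       # density s/m, strict >
    benthic_speed_window: float = 0.08   # m/s, inclusive window around 0
    benthic_peak_height: float = 1.5     # density s/m, strict >
    corner_distance_max: float = 15.0    # m, strict <
    bathy_diff_max: float = 100.0        # m, strict <
    min_kde_samples: int = 10
    bandwidth_floor: float = 1e-3        # m/s, guards degenerate samples

    def __post_init__(self) -> None:
        for name in ("fii_threshold", "drift_peak_height", "benthic_speed_window",
                     "benthic_peak_height", "corner_distance_max", "bathy_diff_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class KDEPeak:
    location: float  # m/s
    height: float    # density, s/m


@dataclass
class ClassificationDetail:
    """Diagnostics recorded alongside the label."""

    fii: float = 0.0
    drift_rate: Optional[float] = None
    drift_peak_height: Optional[float] = None
    bottom_peak_location: Optional[float] = None
    bottom_peak_height: Optional[float] = None
    corner_offset_m: Optional[float] = None
    bathy_diff_m: Optional[float] = None
    flags: list[str] = field(default_factory=list)


def foraging_intensity_index(m: DiveMetrics) -> float:
    """FII = W*V/R + W*V/R * V/T; 0 when there are no qualifying wiggles."""
    if m.W == 0 or m.R == 0:
        return 0.0
    if m.T <= 0:
        return 0.0
    base = m.W * m.V / m.R
    return base + base * (m.V / m.T)


def silverman_bandwidth(x: np.ndarray, floor: float = 1e-3) -> float:
    """Silverman's rule of thumb: 0.9 * min(sd, IQR/1.34) * n^(-1/5).

    The robust spread term keeps the bandwidth sensible for heavy-tailed
    speed samples; the floor guards near-degenerate (constant) samples.
    """
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(s for s in (sd, iqr / 1.34) if s > 0) if (sd > 0 or iqr > 0) else 0.0
    return max(0.9 * spread * n ** (-0.2), floor)


def vertical_speed_kde(
    speeds: Sequence[float],
    min_samples: int = 10,
    bandwidth: Optional[float] = None,
    bandwidth_floor: float = 1e-3,
    grid_size: int = 1024,
) -> Optional[KDEPeak]:
    """Gaussian-kernel density of a vertical-speed sample; returns the global
    maximum (location, height) or None for samples too small to estimate.

    The density integrates to 1, so the height carries units of s/m.
    """
    x = np.asarray(speeds, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < min_samples:
        return None
    h = bandwidth if bandwidth is not None else silverman_bandwidth(x, bandwidth_floor)
    grid = np.linspace(x.min() - 6 * h, x.max() + 6 * h, grid_size)
    sd = float(np.std(x, ddof=1))
    if sd > 1e-9 * max(1.0, float(np.abs(x).max())):
        kde = gaussian_kde(x, bw_method=h / sd)
        dens = kde(grid)
    else:  # constant sample: delta-like peak at the common value
        dens = np.exp(-0.5 * ((grid - x[0]) / h) ** 2) / (h * np.sqrt(2 * np.pi))
    i = int(np.argmax(dens))
    return KDEPeak(location=float(grid[i]), height=float(dens[i]))


def evaluate_kde(speeds: Sequence[float], grid: np.ndarray,
                 bandwidth: Optional[float] = None) -> np.ndarray:
    """Density values on an explicit grid (used by normalization checks)."""
    x = np.asarray(speeds, dtype=float)
    h = bandwidth if bandwidth is not None else silverman_bandwidth(x)
    sd = float(np.std(x, ddof=1))
    if sd > 1e-9 * max(1.0, float(np.abs(x).max())):
        return gaussian_kde(x, bw_method=h / sd)(grid)
    return np.exp(-0.5 * ((grid - x[0]) / h) ** 2) / (h * np.sqrt(2 * np.pi))


def _speeds(depths: np.ndarray, interval: float) -> np.ndarray:
    """Vertical speed (m/s, positive down) by first differences."""
    return np.diff(depths) / interval


def is_drift(dive: Dive, depths: np.ndarray, interval: float,
             thresholds: ClassifierThresholds) -> tuple[bool, Optional[KDEPeak]]:
    """Drift iff the whole-dive vertical-speed KDE peak height exceeds 1."""
    peak = vertical_speed_kde(
        _speeds(depths, interval),
        min_samples=thresholds.min_kde_samples,
        bandwidth_floor=thresholds.bandwidth_floor,
    )
    if peak is None:
        return False, None
    return peak.height > thresholds.drift_peak_height, peak


def corner_offset(dive: Dive, depths: np.ndarray, interval: float) -> Optional[float]:
    """Vertical distance (m) between the descent/bottom fitted-line
    intersection and the observed depth profile at the intersection time.

    Small offsets mean a sharp descent-to-bottom corner. None when either
    phase is too short to fit a line or the lines are parallel.
    """
    d_end, b_end = dive.descent_end_idx, dive.bottom_end_idx
    t = np.arange(len(depths)) * interval
    if d_end < 2 or (b_end - d_end) < 1:
        return None
    m1, c1 = np.polyfit(t[:d_end], depths[:d_end], 1)
    m2, c2 = np.polyfit(t[d_end:b_end + 1], depths[d_end:b_end + 1], 1)
    if abs(m1 - m2) < 1e-12:
        return None
    t_star = (c2 - c1) / (m1 - m2)
    depth_line = m1 * t_star + c1
    depth_obs = float(np.interp(t_star, t, depths))
    return abs(depth_obs - depth_line)


def is_benthic(
    dive: Dive,
    depths: np.ndarray,
    interval: float,
    bathymetry: Optional[float],
    thresholds: ClassifierThresholds,
) -> tuple[bool, ClassificationDetail]:
    """Benthic test (applied after foraging and drift have failed)."""
    det = ClassificationDetail()
    if bathymetry is None:
        det.flags.append("no-bathy")
        return False, det
    det.bathy_diff_m = abs(dive.max_depth - bathymetry)
    if not det.bathy_diff_m < thresholds.bathy_diff_max:
        return False, det
    bottom = depths[dive.descent_end_idx:dive.bottom_end_idx + 1]
    peak = vertical_speed_kde(
        _speeds(bottom, interval),
        min_samples=thresholds.min_kde_samples,
        bandwidth_floor=thresholds.bandwidth_floor,
    )
    if peak is None:
        det.flags.append("short-bottom")
        return False, det
    det.bottom_peak_location = peak.location
    det.bottom_peak_height = peak.height
    if not (abs(peak.location) <= thresholds.benthic_speed_window
            and peak.height > thresholds.benthic_peak_height):
        return False, det
    off = corner_offset(dive, depths, interval)
    det.corner_offset_m = off
    if off is None or not off < thresholds.corner_distance_max:
        return False, det
    return True, det


def classify_dive(
    dive: Dive,
    depths: np.ndarray,
    interval: float,
    bathymetry: Optional[float] = None,
    thresholds: Optional[ClassifierThresholds] = None,
) -> tuple[str, ClassificationDetail]:
    """Assign one of the four labels, testing foraging, drift, then benthic;
    dives meeting no criterion are putative transit dives."""
    thr = thresholds or ClassifierThresholds()
    fii = foraging_intensity_index(dive.metrics)
    if fii > thr.fii_threshold:
        det = ClassificationDetail(fii=fii)
        dive.type = "foraging"
        return "foraging", det
    drift, peak = is_drift(dive, depths, interval, thr)
    if drift:
        det = ClassificationDetail(fii=fii, drift_rate=peak.location,
                                   drift_peak_height=peak.height)
        dive.type = "drift"
        return "drift", det
    benthic, det = is_benthic(dive, depths, interval, bathymetry, thr)
    det.fii = fii
    if peak is not None:
        det.drift_rate = peak.location
        det.drift_peak_height = peak.height
    dive.type = "benthic" if benthic else "transit"
    return dive.type, det


def classify_dives(
    dives: list[Dive],
    series,
    thresholds: Optional[ClassifierThresholds] = None,
) -> list[ClassificationDetail]:
    """Classify every dive in place using its assigned bathymetry."""
    details = []
    for d in dives:
        _, det = classify_dive(d, d.slice(series), series.interval,
                               bathymetry=d.bathymetry, thresholds=thresholds)
        details.append(det)
    return details
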