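"""Pipeline configuration: every analysis threshold in one declarative
object, serializable to/from YAML, with defaults equal to the published
study constants so a bare run reproduces the documented behaviour on
synthetic data."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .geo import COLONY_LONLAT


@dataclass
class PipelineConfig:
    # dive detection
    min_depth: float = 25.0          # m
    min_duration: float = 32.0       # s
    resample: float = 8.0            # s
    zoc_window_min: float = 30.0     # minutes, zero-offset rolling window
    wiggle_threshold: float = 5.0    # m
    # classification
    fii_threshold: float = 35.0
    drift_peak_height: float = 1.0   # density s/m
    benthic_speed_window: float = 0.08  # m/s
    benthic_peak_height: float = 1.5
    corner_distance_max: float = 15.0   # m
    bathy_diff_max: float = 100.0       # m
    # shelf analysis
    shelf_depth: float = 140.0       # m, shelf-break isobath
    min_run: int = 5                 # consecutive dives in a qualifying block
    window_h: float = 72.0           # departure/arrival window
    # spatial summaries
    bathy_bin_m: float = 200.0
    dist_bin_km: float = 300.0
    colony_lon: float = COLONY_LONLAT[0]
    colony_lat: float = COLONY_LONLAT[1]
    colony_utc_offset_h: float = -7.0
    # track interpolation
    vmax: float = 3.0                # m/s speed filter
    step_h: float = 3.0              # track step
    # simulation / reproducibility
    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        """Stable digest of the full configuration, for provenance headers."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
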