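"""Pipeline configuration: defaults, TOML loading, validation, echo.

All thresholds default to the analysis' canonical values (50 km/day
stopover rule over > 3 days, 100 km great-circle sampling, 925 hPa
winds, +-50 km/day drift threshold, 30/40 deg N band edges, 3500 m
barrier contour, 700 km barrier distance).  A TOML file with per-stage
sections overrides any subset; the validated config is echoed into
every output directory so a run can be reproduced from its outputs
alone.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .energetics import DEFAULT_CONSTANTS, HARRIER, FlightConstants, Morphometrics
from .errors import ValidationError


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    # tracks
    stopover_threshold_kmday: float = 50.0
    stopover_min_days: int = 3
    gcr_spacing_km: float = 100.0
    daytime_window: tuple[int, int] = (0, 14)
    lc0_cross_track_km: float = 100.0
    # wind
    pressure_level_hpa: float = 925.0
    drift_threshold_kmday: float = 50.0
    band_edges: tuple[float, float] = (30.0, 40.0)
    # terrain
    elevation_threshold_m: float = 3500.0
    # energetics
    yb_km: float = 700.0
    morphometrics: Morphometrics = HARRIER
    flight_constants: FlightConstants = DEFAULT_CONSTANTS
    # synthetic cohort size for self-contained runs
    n_tracks: int = 6

    def __post_init__(self):
        positives = (self.stopover_threshold_kmday, self.gcr_spacing_km,
                     self.pressure_level_hpa, self.drift_threshold_kmday,
                     self.elevation_threshold_m, self.yb_km)
        if any(v <= 0 for v in positives):
            raise ValidationError("all thresholds must be positive")
        if self.stopover_min_days < 0:
            raise ValidationError("stopover_min_days must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["daytime_window"] = list(self.daytime_window)
        d["band_edges"] = list(self.band_edges)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "morphometrics" in d and isinstance(d["morphometrics"], dict):
            d["morphometrics"] = Morphometrics(**d["morphometrics"])
        if "flight_constants" in d and isinstance(d["flight_constants"], dict):
            fc = dict(d["flight_constants"])
            if "speed_bracket_ms" in fc:
                fc["speed_bracket_ms"] = tuple(fc["speed_bracket_ms"])
            d["flight_constants"] = FlightConstants(**fc)
        for key in ("daytime_window", "band_edges"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, dict) and key not in (
                    "morphometrics", "flight_constants"):
                flat.update(val)   # per-stage sections flatten
            else:
                flat[key] = val
        return cls.from_dict(flat)

    def echo(self, outdir) -> Path:
        """Write the validated config as JSON next to the outputs."""
        path = Path(outdir) / "config_echo.json"
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path
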