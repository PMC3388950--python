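"""Configuration objects for the accessibility pipeline.

All spatial quantities are planar metres (a British-National-Grid-like
projected CRS); speeds are km/h; clock times are minutes since midnight.
Defaults reproduce the study constants: 5 km/h walking, 14 km/h cycling,
free-flow car speeds by road class, at most two bus transfers, 30-minute
access/egress walks, 5-minute waits, a 10:00-16:00 weekday inter-peak
service window, and 20/30-minute accessibility thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

ROAD_CLASSES = ("motorway", "A", "B", "minor", "local")

#: Default uncongested speeds per road class, km/h. The road-class hierarchy
#: (motorway, A road, B road, minor road, local street) is fixed; the speeds
#: themselves are configurable placeholders.
DEFAULT_FREEFLOW_KMH = {
    "motorway": 112.0,
    "A": 80.0,
    "B": 64.0,
    "minor": 48.0,
    "local": 32.0,
}

#: Default junction turn penalties in seconds (configurable placeholders).
DEFAULT_TURN_PENALTIES_S = {"left": 6.0, "right": 9.0}


def parse_clock(value) -> float:
    """Parse ``HH:MM`` / ``HH:MM:SS`` (or a number of minutes) to minutes."""
    if isinstance(value, (int, float)):
        return float(value)
    parts = str(value).split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"not a clock time: {value!r}")
    h, m = int(parts[0]), int(parts[1])
    s = int(parts[2]) if len(parts) == 3 else 0
    return 60.0 * h + m + s / 60.0


def format_clock(minutes: float) -> str:
    """Render minutes since midnight as ``HH:MM:SS``."""
    total = int(round(minutes * 60))
    h, rem = divmod(total, 3600)
    m, s = divmod(rem, 60)
    return f"{h:02d}:{m:02d}:{s:02d}"


@dataclass
class RegionConfig:
    """Parameters of the synthetic study region.

    The stated world mirrors the Scottish small-area structure at desk
    scale: zones of 500-1000 residents nested in local authorities, a
    roughly 70/13/17 urban / small-town / rural split, income-deprivation
    quintiles with positive spatial autocorrelation, and facilities placed
    with a known deprivation gradient (``facility_rate_ratios``, quintile
    Q1 = most affluent is the baseline).
    """

    seed: int = 0
    n_zones: int = 100
    n_local_authorities: int = 4
    urban_fraction: float = 0.70
    smalltown_fraction: float = 0.13
    rural_fraction: float = 0.17
    grid_extent_m: float = 12_000.0
    facility_rate_ratios: Mapping[int, float] = field(
        default_factory=lambda: {1: 1.0, 2: 1.2, 3: 1.4, 4: 1.6, 5: 1.8}
    )
    mean_population: float = 750.0
    facilities_per_zone: float = 1.5
    bus_routes: int = 5
    service_window: tuple[float, float] = (600.0, 960.0)  # 10:00-16:00
    headway_min: float = 30.0

    def __post_init__(self):
        fr = (self.urban_fraction, self.smalltown_fraction, self.rural_fraction)
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("strata fractions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("strata fractions must sum to 1")
        if not (self.n_zones >= self.n_local_authorities >= 1):
            raise ValueError("need n_zones >= n_local_authorities >= 1")
        self.facility_rate_ratios = {int(q): float(r) for q, r in self.facility_rate_ratios.items()}
        if sorted(self.facility_rate_ratios) != [1, 2, 3, 4, 5]:
            raise ValueError("facility_rate_ratios must be keyed by quintiles 1..5")
        if any(r <= 0 for r in self.facility_rate_ratios.values()):
            raise ValueError("facility rate ratios must be positive")
        w = (parse_clock(self.service_window[0]), parse_clock(self.service_window[1]))
        if not w[0] < w[1]:
            raise ValueError("service window start must precede end")
        self.service_window = w


@dataclass
class ModeConfig:
    """Per-mode travel parameters.

    walk/cycle traverse links at a constant speed; car uses per-class
    free-flow speeds plus junction turn penalties; bus reuses the walk
    parameters for access, egress and interchange stages.
    """

    mode: str = "walk"
    walk_speed_kmh: float = 5.0
    cycle_speed_kmh: float = 14.0
    freeflow_kmh: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FREEFLOW_KMH))
    turn_penalties_s: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TURN_PENALTIES_S)
    )
    straight_threshold_deg: float = 30.0

    def __post_init__(self):
        if self.mode not in ("walk", "cycle", "car", "bus"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.walk_speed_kmh <= 0 or self.cycle_speed_kmh <= 0:
            raise ValueError("speeds must be positive")
        if any(v <= 0 for v in self.freeflow_kmh.values()):
            raise ValueError("free-flow speeds must be positive")
        if any(v < 0 for v in self.turn_penalties_s.values()):
            raise ValueError("turn penalties must be non-negative")

    @property
    def speed_kmh(self) -> float:
        if self.mode == "cycle":
            return self.cycle_speed_kmh
        return self.walk_speed_kmh


@dataclass
class BusConfig:
    """Constraints on timetable-based bus journeys."""

    max_transfers: int = 2
    max_access_egress_walk_min: float = 30.0
    max_wait_min: float = 5.0
    service_window: tuple[float, float] = (600.0, 960.0)

    def __post_init__(self):
        if self.max_transfers < 0:
            raise ValueError("max_transfers must be non-negative")
        if self.max_access_egress_walk_min < 0 or self.max_wait_min < 0:
            raise ValueError("walk and wait limits must be non-negative")
        w = (parse_clock(self.service_window[0]), parse_clock(self.service_window[1]))
        if not w[0] < w[1]:
            raise ValueError("service window start must precede end")
        self.service_window = w


@dataclass
class AnalysisConfig:
    """Accessibility-count settings: thresholds, intensities, per-capita base."""

    thresholds_min: tuple[float, ...] = (20.0, 30.0)
    intensities: tuple[str, ...] = ("moderate", "vigorous")
    per_capita_base: float = 1000.0
    include_light: bool = False

    def __post_init__(self):
        t = tuple(float(x) for x in self.thresholds_min)
        if any(x <= 0 for x in t) or any(b <= a for a, b in zip(t, t[1:])) is True:
            raise ValueError("thresholds must be positive and strictly increasing")
        if not all(b > a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        self.thresholds_min = t
        if self.per_capita_base <= 0:
            raise ValueError("per_capita_base must be positive")


@dataclass
class ModelOptions:
    """Count-model settings: 99% Wald intervals, Q1 baseline, LA random intercept."""

    conf_level: float = 0.99
    n_permutations: int = 999
    quad_points: int = 10
    modes: tuple[str, ...] = ("walk", "cycle", "car", "bus")

    def __post_init__(self):
        if not 0 < self.conf_level < 1:
            raise ValueError("conf_level must be in (0, 1)")


@dataclass
class PipelineConfig:
    """Everything needed for an end-to-end run."""

    region: RegionConfig = field(default_factory=RegionConfig)
    bus: BusConfig = field(default_factory=BusConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    model: ModelOptions = field(default_factory=ModelOptions)
    walk: ModeConfig = field(default_factory=lambda: ModeConfig(mode="walk"))
    cycle: ModeConfig = field(default_factory=lambda: ModeConfig(mode="cycle"))
    car: ModeConfig = field(default_factory=lambda: ModeConfig(mode="car"))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, typ in (
            ("region", RegionConfig),
            ("bus", BusConfig),
            ("analysis", AnalysisConfig),
            ("model", ModelOptions),
        ):
            if key in raw:
                kwargs[key] = typ(**raw[key])
        for key in ("walk", "cycle", "car"):
            if key in raw:
                kwargs[key] = ModeConfig(mode=key, **raw[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)
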