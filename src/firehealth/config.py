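"""Configuration for the analysis pipeline.

A single :class:`PipelineConfig` (YAML/JSON serialisable) carries one
section per pipeline stage.  The synthetic-data section fixes the study
conditions the generator emulates: a premonsoon (Jan-May) fire season
peaking in March superimposed on a smooth polluted background over a
Southeast-Asia-like domain, a clustered population, GBD-style baseline
health rates, and an infant-mortality-rate surface whose association with
fire-derived PM is set by a single coupling coefficient.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from .exceptions import ConfigurationError

__all__ = [
    "FirePlume",
    "PopulationCenter",
    "SyntheticConfig",
    "HealthConfig",
    "EvaluationConfig",
    "EquityConfig",
    "RegionRule",
    "ReportingConfig",
    "PipelineConfig",
    "demo_config",
]


@dataclass
class FirePlume:
    """One fire source: Gaussian in space, triangular in time over the season."""

    lat: float
    lon: float
    amplitude: float  # peak-month PM2.5 enhancement at the centre, ug m-3
    decay_km: float  # Gaussian spatial scale


@dataclass
class PopulationCenter:
    lat: float
    lon: float
    weight: float  # relative share of the clustered population
    scale_km: float


@dataclass
class SyntheticConfig:
    # domain & grid
    lat_min: float = 10.0
    lat_max: float = 20.0
    lon_min: float = 95.0
    lon_max: float = 105.0
    resolution: float = 0.25  # degrees
    n_months: int = 12
    n_days: int = 365

    # fire signal: premonsoon season, March peak
    fire_season: tuple[int, ...] = (1, 2, 3, 4, 5)
    peak_month: int = 3
    plumes: tuple[FirePlume, ...] = (
        FirePlume(lat=18.0, lon=97.5, amplitude=55.0, decay_km=220.0),
        FirePlume(lat=16.5, lon=99.5, amplitude=40.0, decay_km=180.0),
        FirePlume(lat=14.0, lon=96.5, amplitude=30.0, decay_km=160.0),
    )

    # background (nonfire) PM2.5: mean plus linear gradient toward the
    # urbanised south-east corner, so nonfire pollution anti-correlates
    # with the remote fire-prone uplands
    background_pm25_mean: float = 16.0
    background_pm25_grad_lat: float = -0.6  # ug m-3 per degree northwards
    background_pm25_grad_lon: float = 0.8  # ug m-3 per degree eastwards

    # PM10 scaling: background coarse fraction, fine-dominated fire smoke
    pm10_background_ratio: float = 1.7
    pm10_fire_ratio: float = 1.15

    # ozone (daily max 8-h values, ppbv)
    o3_background: float = 35.0
    o3_seasonal_amplitude: float = 6.0
    o3_fire_enhancement: float = 6.0  # ppbv at plume centre, peak season
    o3_daily_noise_sd: float = 0.05  # lognormal sigma on daily values

    # population
    population_total: float = 8.0e7
    population_centers: tuple[PopulationCenter, ...] = (
        PopulationCenter(lat=12.0, lon=103.5, weight=0.35, scale_km=120.0),
        PopulationCenter(lat=14.5, lon=101.5, weight=0.25, scale_km=150.0),
        PopulationCenter(lat=17.5, lon=98.5, weight=0.15, scale_km=130.0),
    )
    population_rural_fraction: float = 0.25

    # infant mortality rate (poverty proxy)
    imr_base: float = 35.0
    imr_coupling: float = 3.0  # IMR units per ug m-3 of fire-derived PM2.5
    imr_noise_sd: float = 12.0

    # noise
    concentration_noise_sd: float = 0.08  # lognormal sigma on monthly fields

    # station observations
    station_bias: float = 1.25  # observed = bias * truth (model underestimates)
    station_noise_sd: float = 3.0  # additive Gaussian sd on observed series, ug m-3

    seed: int = 42

    def __post_init__(self):
        if isinstance(self.plumes, list):
            self.plumes = tuple(
                FirePlume(**p) if isinstance(p, dict) else p for p in self.plumes
            )
        if isinstance(self.population_centers, list):
            self.population_centers = tuple(
                PopulationCenter(**p) if isinstance(p, dict) else p
                for p in self.population_centers
            )
        self.fire_season = tuple(self.fire_season)
        self.validate()

    def validate(self) -> None:
        if not (self.lat_max > self.lat_min and self.lon_max > self.lon_min):
            raise ConfigurationError("domain bounds must satisfy min < max")
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be positive")
        for extent, name in (
            (self.lat_max - self.lat_min, "lat"),
            (self.lon_max - self.lon_min, "lon"),
        ):
            n = extent / self.resolution
            if abs(n - round(n)) > 1e-9:
                raise ConfigurationError(
                    f"resolution {self.resolution} does not divide the {name} extent {extent}"
                )
        if not all(1 <= m <= 12 for m in self.fire_season):
            raise ConfigurationError("fire_season months must lie in 1..12")
        if self.peak_month not in self.fire_season:
            raise ConfigurationError("peak_month must be one of the fire_season months")
        nonneg = {
            "background_pm25_mean": self.background_pm25_mean,
            "o3_background": self.o3_background,
            "o3_fire_enhancement": self.o3_fire_enhancement,
            "population_total": self.population_total,
            "imr_noise_sd": self.imr_noise_sd,
            "concentration_noise_sd": self.concentration_noise_sd,
            "station_noise_sd": self.station_noise_sd,
            "o3_daily_noise_sd": self.o3_daily_noise_sd,
        }
        for k, v in nonneg.items():
            if v < 0:
                raise ConfigurationError(f"{k} must be nonnegative, got {v}")
        for p in self.plumes:
            if p.amplitude < 0 or p.decay_km <= 0:
                raise ConfigurationError("plume amplitudes must be >= 0 and decay lengths > 0")

    # grid cell centres
    @property
    def lat(self):
        import numpy as np

        n = round((self.lat_max - self.lat_min) / self.resolution)
        return self.lat_min + self.resolution * (np.arange(n) + 0.5)

    @property
    def lon(self):
        import numpy as np

        n = round((self.lon_max - self.lon_min) / self.resolution)
        return self.lon_min + self.resolution * (np.arange(n) + 0.5)


@dataclass
class HealthConfig:
    gemm_variant: str = "ncd_lri"  # "ncd_lri" aggregate or "five_cause"
    counterfactual: float = 2.4  # ug m-3, GEMM low-concentration cutoff
    ozone_rr_per_10ppb: float = 1.12
    ozone_rr_ci: tuple[float, float] = (1.08, 1.16)
    ozone_tmrel: float = 26.7  # ppbv
    n_draws: int = 1000

    def __post_init__(self):
        self.ozone_rr_ci = tuple(self.ozone_rr_ci)
        if self.ozone_rr_per_10ppb <= 0:
            raise ConfigurationError("ozone_rr_per_10ppb must be > 0")
        if self.ozone_tmrel < 0:
            raise ConfigurationError("ozone_tmrel must be >= 0")
        if self.counterfactual < 0:
            raise ConfigurationError("counterfactual must be >= 0")


@dataclass
class EvaluationConfig:
    n_stations: int = 12
    fire_influence_threshold: float = 0.20
    sampling: str = "nearest"  # or "bilinear"


@dataclass
class EquityConfig:
    imr_bin_width: float = 10.0
    low_cut: float = 20.0
    high_cut: float = 60.0
    confidence: float = 0.99
    imr_class_edges: tuple[float, ...] = (0.0, 20.0, 60.0, 100.0)
    pm_class_edges: tuple[float, ...] = (0.0, 5.0, 15.0, 30.0)
    poverty_cutpoints: tuple[float, ...] = (15.0, 32.0, 65.0, 100.0)
    poverty_labels: tuple[str, ...] = ("not poor", "moderately poor", "poor", "very poor")

    def __post_init__(self):
        self.imr_class_edges = tuple(self.imr_class_edges)
        self.pm_class_edges = tuple(self.pm_class_edges)
        self.poverty_cutpoints = tuple(self.poverty_cutpoints)
        self.poverty_labels = tuple(self.poverty_labels)


@dataclass
class RegionRule:
    """Declarative lat/lon box rule defining one region mask."""

    name: str
    lat_min: float = -90.0
    lat_max: float = 90.0
    lon_min: float = -360.0
    lon_max: float = 360.0


@dataclass
class ReportingConfig:
    who_guideline: float = 10.0  # ug m-3 annual-mean PM2.5
    who_interim_target2: float = 25.0
    groupings: dict = field(default_factory=dict)  # group name -> member regions


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    health: HealthConfig = field(default_factory=HealthConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    equity: EquityConfig = field(default_factory=EquityConfig)
    reporting: ReportingConfig = field(default_factory=ReportingConfig)
    regions: tuple[RegionRule, ...] = ()
    seed: int = 42

    def __post_init__(self):
        for name, cls in (
            ("synthetic", SyntheticConfig),
            ("health", HealthConfig),
            ("evaluation", EvaluationConfig),
            ("equity", EquityConfig),
            ("reporting", ReportingConfig),
        ):
            v = getattr(self, name)
            if isinstance(v, dict):
                setattr(self, name, cls(**v))
        self.regions = tuple(
            RegionRule(**r) if isinstance(r, dict) else r for r in self.regions
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, synthetic=replace(self.synthetic, seed=seed), seed=seed)


def _plain(obj):
    """Recursively convert tuples to lists for clean YAML output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def demo_config(seed: int = 42) -> PipelineConfig:
    """The packaged demo: 40x40 grid at 0.25 deg, 12 months, 12 stations,
    four quadrant regions plus a whole-domain grouping."""
    regions = (
        RegionRule("northwest", lat_min=15.0, lat_max=20.0, lon_min=95.0, lon_max=100.0),
        RegionRule("northeast", lat_min=15.0, lat_max=20.0, lon_min=100.0, lon_max=105.0),
        RegionRule("southwest", lat_min=10.0, lat_max=15.0, lon_min=95.0, lon_max=100.0),
        RegionRule("southeast", lat_min=10.0, lat_max=15.0, lon_min=100.0, lon_max=105.0),
    )
    groupings = {"domain_total": ["northwest", "northeast", "southwest", "southeast"]}
    cfg = PipelineConfig(
        synthetic=SyntheticConfig(seed=seed),
        reporting=ReportingConfig(groupings=groupings),
        regions=regions,
        seed=seed,
    )
    return cfg
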