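"""Synthetic inputs with known ground truth.

Generates every input the pipeline needs — matched all-sources/fires-off
concentration fields, gridded population, baseline health rates, an
infant-mortality-rate (IMR) surface, and station observations — so each
downstream stage is testable without external model output or monitoring
archives.

The fire signal is Gaussian in space around configured plume centres and
triangular in time across the fire-season months, peaking at the
configured peak month (a premonsoon March peak by default).  The
all-sources field is constructed as the fires-off field plus a
nonnegative fire contribution, so scenario consistency (all >= nofire,
zero fire signal outside the season) holds by construction.

Randomness: one independent stream per generated product, derived from
the master seed through fixed offsets, so adding or re-ordering products
never perturbs the others.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .config import SyntheticConfig
from .evaluation import StationSeries
from .exceptions import ConfigurationError, GridAlignmentError, StationPlacementError
from .grids import ScenarioPair, check_aligned, make_field

__all__ = [
    "generate_scenario_pair",
    "generate_population",
    "generate_imr_grid",
    "generate_station_series",
    "generate_hourly_o3",
    "generate_baseline_health",
    "seasonal_weights",
]

# fixed per-product stream offsets (see module docstring)
_STREAM = {
    "pm25": 11,
    "pm10": 12,
    "o3": 13,
    "population": 21,
    "imr": 31,
    "stations": 41,
    "hourly_o3": 51,
}

_EARTH_RADIUS_KM = 6371.0


def _rng(config: SyntheticConfig, product: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[product], int(config.seed)])


def _distance_km(lat_grid, lon_grid, lat0, lon0):
    """Great-circle distance from (lat0, lon0) to each cell centre."""
    la1, lo1, la2, lo2 = map(np.radians, (lat_grid, lon_grid, lat0, lon0))
    dlat, dlon = la2 - la1, lo2 - lo1
    a = np.sin(dlat / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _plume_field(config: SyntheticConfig) -> np.ndarray:
    """Peak-month fire PM2.5 enhancement (ug m-3) on the grid."""
    lat2d, lon2d = np.meshgrid(config.lat, config.lon, indexing="ij")
    out = np.zeros_like(lat2d)
    for p in config.plumes:
        d = _distance_km(lat2d, lon2d, p.lat, p.lon)
        out += p.amplitude * np.exp(-0.5 * (d / p.decay_km) ** 2)
    return out


def seasonal_weights(config: SyntheticConfig) -> np.ndarray:
    """Triangular fire-season weights per month (1..n_months), peak = 1."""
    months = np.arange(1, config.n_months + 1)
    season = sorted(config.fire_season)
    first, last, peak = season[0], season[-1], config.peak_month
    w = np.zeros(config.n_months)
    for i, m in enumerate(months):
        if m not in config.fire_season:
            continue
        if m <= peak:
            w[i] = (m - (first - 1)) / (peak - (first - 1))
        else:
            w[i] = ((last + 1) - m) / ((last + 1) - peak)
    return w


def _lognormal_noise(rng, sigma, shape):
    """Mean-one multiplicative lognormal noise; exactly 1 when sigma == 0."""
    if sigma == 0:
        return np.ones(shape)
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=shape))


def generate_scenario_pair(config: SyntheticConfig) -> ScenarioPair:
    """Matched all-sources and fires-off fields on the analysis grid.

    Returns monthly PM2.5 and PM10 plus daily-maximum-8-h ozone for both
    scenarios.  Annual means are derived from the monthlies, so the
    "annual = mean of months" invariant is exact.
    """
    lat, lon = config.lat, config.lon
    nlat, nlon, nm = lat.size, lon.size, config.n_months
    lat2d = np.meshgrid(lat, lon, indexing="ij")[0]
    lon2d = np.meshgrid(lat, lon, indexing="ij")[1]

    background = (
        config.background_pm25_mean
        + config.background_pm25_grad_lat * (lat2d - lat2d.mean())
        + config.background_pm25_grad_lon * (lon2d - lon2d.mean())
    )
    background = np.clip(background, 0.5, None)
    plume = _plume_field(config)
    w = seasonal_weights(config)

    months = np.arange(1, nm + 1)
    sigma = config.concentration_noise_sd

    def _monthly_pair(rng, bg2d, fire2d):
        bg_noise = _lognormal_noise(rng, sigma, (nm, nlat, nlon))
        fire_noise = _lognormal_noise(rng, sigma, (nm, nlat, nlon))
        nofire = bg2d[None, :, :] * bg_noise
        fire = fire2d[None, :, :] * w[:, None, None] * fire_noise
        return nofire + fire, nofire

    rng25 = _rng(config, "pm25")
    pm25_all, pm25_nofire = _monthly_pair(rng25, background, plume)
    rng10 = _rng(config, "pm10")
    pm10_all, pm10_nofire = _monthly_pair(
        rng10,
        background * config.pm10_background_ratio,
        plume * config.pm10_fire_ratio,
    )

    # ozone: smooth seasonal background plus a fire enhancement that follows
    # the plume spatial pattern and the triangular season, on daily steps
    rng_o3 = _rng(config, "o3")
    nd = config.n_days
    days = np.arange(nd)
    peak_day = (config.peak_month - 0.5) / 12.0 * nd
    seasonal = config.o3_background + config.o3_seasonal_amplitude * np.cos(
        2 * np.pi * (days - peak_day) / nd
    )
    # daily fire weight: interpolate the monthly triangular weights
    day_w = np.interp(days, (months - 0.5) / nm * nd, w)
    shape = plume / plume.max() if plume.max() > 0 else np.zeros_like(plume)
    o3_sigma = config.o3_daily_noise_sd
    o3_bg_noise = _lognormal_noise(rng_o3, o3_sigma, (nd, nlat, nlon))
    o3_fire_noise = _lognormal_noise(rng_o3, o3_sigma, (nd, nlat, nlon))
    o3_nofire = seasonal[:, None, None] * o3_bg_noise
    o3_fire = config.o3_fire_enhancement * shape[None, :, :] * day_w[:, None, None]
    o3_all = o3_nofire + o3_fire * o3_fire_noise

    def f(values, species, scenario, temporal, time):
        return make_field(
            values, lat, lon, species=species, scenario=scenario, temporal=temporal, time=time
        )

    return ScenarioPair(
        pm25_monthly_all=f(pm25_all, "PM2.5", "all", "monthly", months),
        pm25_monthly_nofire=f(pm25_nofire, "PM2.5", "nofire", "monthly", months),
        pm10_monthly_all=f(pm10_all, "PM10", "all", "monthly", months),
        pm10_monthly_nofire=f(pm10_nofire, "PM10", "nofire", "monthly", months),
        o3_dm8h_all=f(o3_all, "O3", "all", "daily", days),
        o3_dm8h_nofire=f(o3_nofire, "O3", "nofire", "daily", days),
    )


def generate_population(config: SyntheticConfig) -> xr.DataArray:
    """Clustered population counts; sums exactly to the configured total."""
    lat, lon = config.lat, config.lon
    lat2d, lon2d = np.meshgrid(lat, lon, indexing="ij")
    rng = _rng(config, "population")
    if config.population_total == 0:
        return make_field(np.zeros(lat2d.shape), lat, lon, units="persons", name="population")
    clustered = np.zeros_like(lat2d)
    total_weight = sum(c.weight for c in config.population_centers)
    for c in config.population_centers:
        d = _distance_km(lat2d, lon2d, c.lat, c.lon)
        clustered += c.weight * np.exp(-0.5 * (d / c.scale_km) ** 2)
    if total_weight > 0:
        clustered /= clustered.sum()
    rural = np.ones_like(lat2d)
    rural *= _lognormal_noise(rng, 0.3, lat2d.shape)
    rural /= rural.sum()
    density = (
        (1 - config.population_rural_fraction) * clustered
        + config.population_rural_fraction * rural
    )
    counts = config.population_total * density / density.sum()
    return make_field(counts, lat, lon, units="persons", name="population")


def generate_imr_grid(config: SyntheticConfig, fire_pm: xr.DataArray) -> xr.DataArray:
    """IMR surface (deaths per 1,000 live births) coupled to fire-derived PM.

    IMR = base + coupling * fire_pm + Gaussian noise, clipped to [0, 100].
    With coupling 0 and noise 0 the field is constant at the base rate.
    """
    lat, lon = config.lat, config.lon
    if fire_pm.sizes["lat"] != lat.size or fire_pm.sizes["lon"] != lon.size:
        raise GridAlignmentError("fire_pm is not on the configured analysis grid")
    check_aligned(fire_pm, make_field(np.zeros((lat.size, lon.size)), lat, lon))
    rng = _rng(config, "imr")
    noise = (
        rng.normal(0.0, config.imr_noise_sd, size=fire_pm.shape)
        if config.imr_noise_sd > 0
        else 0.0
    )
    values = config.imr_base + config.imr_coupling * fire_pm.values + noise
    values = np.clip(values, 0.0, 100.0)
    out = make_field(values, lat, lon, units="deaths per 1000 live births", name="imr")
    out.attrs["provenance"] = "synthetic IMR poverty proxy"
    return out


def generate_station_series(
    config: SyntheticConfig,
    pair: ScenarioPair,
    n_stations: int = 12,
    year: int = 2014,
) -> list[StationSeries]:
    """Monthly PM10 monitoring series at stations inside the domain.

    Observed = multiplicative bias x sampled all-sources series + additive
    Gaussian noise (clipped at zero).  Station placement favours
    fire-influenced cells so that the 20%-fire-influence selection has
    candidates; the true fire fraction at each station is recorded.
    """
    if n_stations < 1:
        raise ConfigurationError("n_stations must be >= 1")
    rng = _rng(config, "stations")
    ann_all = pair.annual("PM10", "all").values
    ann_nofire = pair.annual("PM10", "nofire").values
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(ann_all > 0, (ann_all - ann_nofire) / ann_all, 0.0)
    weights = (frac + 0.05).ravel()
    weights /= weights.sum()
    n_cells = weights.size
    idx = rng.choice(n_cells, size=min(n_stations, n_cells), replace=False, p=weights)
    lat, lon = config.lat, config.lon
    times = pd.period_range(start=f"{year}-01", periods=config.n_months, freq="M").to_timestamp(
        how="end"
    )
    out = []
    for k, flat in enumerate(sorted(int(i) for i in idx)):
        i, j = np.unravel_index(flat, (lat.size, lon.size))
        model_all = pair.pm10_monthly_all.values[:, i, j].copy()
        model_nofire = pair.pm10_monthly_nofire.values[:, i, j].copy()
        noise = (
            rng.normal(0.0, config.station_noise_sd, size=model_all.size)
            if config.station_noise_sd > 0
            else 0.0
        )
        observed = np.clip(config.station_bias * model_all + noise, 0.0, None)
        out.append(
            StationSeries(
                station_id=f"ST{k:03d}",
                lat=float(lat[i]),
                lon=float(lon[j]),
                time=times,
                observed=observed,
                model={"all": model_all, "nofire": model_nofire},
                species="PM10",
                meta={"true_fire_fraction": float(frac[i, j]), "bias": config.station_bias},
            )
        )
    for s in out:
        if not (config.lat_min <= s.lat <= config.lat_max and config.lon_min <= s.lon <= config.lon_max):
            raise StationPlacementError(f"station {s.station_id} outside domain")
    return out


def generate_hourly_o3(
    config: SyntheticConfig, n_days: int = 10
) -> tuple[xr.DataArray, xr.DataArray]:
    """Hourly ozone plus its daily-maximum-8-h product, for window testing.

    The daily-max-8-h values returned here are computed by an explicit
    scan over all 17 within-day 8-hour windows, independent of the
    exposure module's implementation.
    """
    lat, lon = config.lat, config.lon
    nlat, nlon = lat.size, lon.size
    rng = _rng(config, "hourly_o3")
    hours = np.arange(24)
    # afternoon-peaking diurnal cycle
    diurnal = 1.0 + 0.35 * np.sin(np.pi * np.clip((hours - 6) / 14.0, 0, 1))
    base = config.o3_background * np.ones((n_days, 24, nlat, nlon))
    base *= diurnal[None, :, None, None]
    base *= _lognormal_noise(rng, config.o3_daily_noise_sd, base.shape)
    hourly = base.reshape(n_days * 24, nlat, nlon)
    # brute-force daily max over all complete 8-h windows
    dm8h = np.empty((n_days, nlat, nlon))
    daily = hourly.reshape(n_days, 24, nlat, nlon)
    for d in range(n_days):
        wins = [daily[d, s : s + 8].mean(axis=0) for s in range(17)]
        dm8h[d] = np.max(wins, axis=0)
    t_h = np.arange(n_days * 24)
    hourly_da = make_field(hourly, lat, lon, species="O3", temporal="hourly", time=t_h)
    dm8h_da = make_field(dm8h, lat, lon, species="O3", temporal="daily", time=np.arange(n_days))
    return hourly_da, dm8h_da


# --- baseline health data -------------------------------------------------

# GEMM-style exposure-response coefficients are configuration inputs
# (health.py carries the packaged defaults).  Baseline rates below are
# GBD-style magnitudes: NCD+LRI mortality ~600 per 100k, DALY rates
# ~25,000 per 100k, adult (25+) population fraction ~0.6; respiratory
# mortality (the ozone-affected cause) ~90 per 100k.

_BASE_ROWS = {
    "ncd_lri": [
        # cause, age_group, mort (lo, hi), daly (lo, hi), fraction (lo, hi)
        ("ncd_lri", "25+", 0.0060, 0.0055, 0.0065, 0.25, 0.22, 0.28, 0.60, 0.58, 0.62),
    ],
    "five_cause": [
        ("ihd", "25+", 0.0016, 0.0014, 0.0018, 0.060, 0.052, 0.068, 0.60, 0.58, 0.62),
        ("stroke", "25+", 0.0014, 0.0012, 0.0016, 0.055, 0.047, 0.063, 0.60, 0.58, 0.62),
        ("copd", "25+", 0.0005, 0.0004, 0.0006, 0.022, 0.018, 0.026, 0.60, 0.58, 0.62),
        ("lung_cancer", "25+", 0.0003, 0.00025, 0.00035, 0.012, 0.010, 0.014, 0.60, 0.58, 0.62),
        ("lri", "all", 0.0004, 0.0003, 0.0005, 0.020, 0.015, 0.025, 1.00, 1.00, 1.00),
    ],
}
_OZONE_ROW = ("resp", "25+", 0.0009, 0.0008, 0.0010, 0.030, 0.025, 0.035, 0.60, 0.58, 0.62)

# fixed regional multipliers emulate between-country rate differences
_REGION_MULT = (1.05, 0.92, 1.00, 1.08, 0.97, 1.02)


def generate_baseline_health(
    regions: list[str], variant: str = "ncd_lri"
) -> pd.DataFrame:
    """Cause/age-specific baseline rates with 95% uncertainty intervals.

    One row per (region, cause, age group); columns: mortality rate,
    DALY rate (both per person per year) and adult population fraction,
    each with 95UI bounds.  Includes the ozone-affected respiratory cause
    alongside the PM causes of the requested GEMM variant.
    """
    if variant not in _BASE_ROWS:
        raise ConfigurationError(f"unknown GEMM variant '{variant}'")
    rows = []
    for ridx, region in enumerate(regions):
        m = _REGION_MULT[ridx % len(_REGION_MULT)]
        for row in _BASE_ROWS[variant] + [_OZONE_ROW]:
            cause, age, mr, mrl, mrh, dr, drl, drh, fr, frl, frh = row
            rows.append(
                {
                    "region": region,
                    "cause": cause,
                    "age_group": age,
                    "mort_rate": mr * m,
                    "mort_lo": mrl * m,
                    "mort_hi": mrh * m,
                    "daly_rate": dr * m,
                    "daly_lo": drl * m,
                    "daly_hi": drh * m,
                    "age_fraction": fr,
                    "frac_lo": frl,
                    "frac_hi": frh,
                }
            )
    return pd.DataFrame(rows)
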