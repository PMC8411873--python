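"""Model-measurement comparison machinery.

Implements the evaluation toolkit used for fire-influenced monitoring
sites: selection of stations where fires contribute at least a threshold
fraction of simulated annual-mean PM, isolation of the fire-derived PM
signal by subtracting each calendar year's minimum monthly mean,
the normalized mean bias factor (NMBF) of Yu et al., Pearson
correlation, and the normalized standard deviation (NSD).

NMBF conventions: a positive NMBF means the model overestimates the
observations by a factor NMBF + 1; a negative NMBF means the model
underestimates them by a factor 1 - NMBF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .exceptions import StationPlacementError, UndefinedValueError

__all__ = [
    "StationSeries",
    "EvaluationMetrics",
    "select_fire_influenced",
    "fire_derived_series",
    "nmbf",
    "pearson_and_nsd",
    "composite_series",
    "evaluate_stations",
]


@dataclass
class StationSeries:
    """Observed and model-sampled time series at one monitoring site."""

    station_id: str
    lat: float
    lon: float
    time: pd.DatetimeIndex
    observed: np.ndarray
    model: dict  # scenario -> np.ndarray sampled at the station cell
    species: str = "PM10"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        self.time = pd.DatetimeIndex(self.time)
        if not self.time.is_monotonic_increasing or self.time.has_duplicates:
            raise ValueError(f"{self.station_id}: timestamps must be strictly increasing")
        for scen, arr in self.model.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.observed.shape:
                raise ValueError(f"{self.station_id}: model '{scen}' length mismatch")
            self.model[scen] = arr

    def observed_series(self) -> pd.Series:
        return pd.Series(self.observed, index=self.time)

    def model_series(self, scenario: str = "all") -> pd.Series:
        return pd.Series(self.model[scenario], index=self.time)


@dataclass
class EvaluationMetrics:
    nmbf: float
    pearson_r: float
    r_squared: float
    nsd: float
    n_pairs: int


def _cell_index(coord: np.ndarray, x: float) -> int:
    """Index of the grid cell whose centre is nearest to x (containment on
    a regular grid), or -1 if x lies outside the grid's outer edges."""
    coord = np.asarray(coord, float)
    step = coord[1] - coord[0]
    if x < coord[0] - step / 2 or x > coord[-1] + step / 2:
        return -1
    return int(np.argmin(np.abs(coord - x)))


def sample_field_at(field: xr.DataArray, lat: float, lon: float, method: str = "nearest") -> float:
    """Value of a 2-D field at a station location (containing cell by
    default; bilinear available)."""
    if method == "bilinear":
        return float(field.interp(lat=lat, lon=lon).values)
    i = _cell_index(field.coords["lat"].values, lat)
    j = _cell_index(field.coords["lon"].values, lon)
    if i < 0 or j < 0:
        raise StationPlacementError(f"location ({lat}, {lon}) outside grid")
    return float(field.values[i, j])


def select_fire_influenced(
    all_field: xr.DataArray,
    nofire_field: xr.DataArray,
    stations: list[StationSeries],
    threshold_fraction: float = 0.20,
    sampling: str = "nearest",
) -> list[StationSeries]:
    """Stations whose grid cell has a simulated annual-mean fire
    contribution (all - nofire)/all at or above the threshold."""
    if not 0 <= threshold_fraction <= 1:
        raise ValueError("threshold_fraction must lie in [0, 1]")
    outside = [
        s.station_id
        for s in stations
        if _cell_index(all_field.coords["lat"].values, s.lat) < 0
        or _cell_index(all_field.coords["lon"].values, s.lon) < 0
    ]
    if outside:
        raise StationPlacementError(f"stations outside grid: {outside}")
    selected = []
    for s in stations:
        a = sample_field_at(all_field, s.lat, s.lon, sampling)
        n = sample_field_at(nofire_field, s.lat, s.lon, sampling)
        frac = (a - n) / a if a > 0 else 0.0
        if frac >= threshold_fraction:
            selected.append(s)
    return selected


def fire_derived_series(series: pd.Series) -> pd.Series:
    """Fire-derived enhancement: monthly value minus that calendar year's
    minimum monthly mean, each year treated independently.

    Years with fewer than 2 non-missing months are returned as missing.
    Idempotent: the minimum month maps to zero, so reapplying changes
    nothing.
    """
    s = series.astype(float)
    out = pd.Series(np.nan, index=s.index)
    for year, grp in s.groupby(s.index.year):
        valid = grp.dropna()
        if len(valid) < 2:
            continue
        out.loc[grp.index] = grp - valid.min()
    return out


def nmbf(model, observed) -> float:
    """Normalized mean bias factor (Yu et al.).

    NMBF = sum(M)/sum(O) - 1 when mean(M) >= mean(O), else
    NMBF = 1 - sum(O)/sum(M).  Pairs with a missing member are dropped.
    """
    m = np.asarray(model, dtype=float)
    o = np.asarray(observed, dtype=float)
    if m.shape != o.shape:
        raise ValueError("model and observed must be paired (equal length)")
    ok = np.isfinite(m) & np.isfinite(o)
    m, o = m[ok], o[ok]
    sm, so = m.sum(), o.sum()
    if sm <= 0 or so <= 0:
        raise UndefinedValueError("NMBF undefined for non-positive series sums")
    if m.mean() >= o.mean():
        return float(sm / so - 1.0)
    return float(1.0 - so / sm)


def pearson_and_nsd(model, observed) -> EvaluationMetrics:
    """Pearson r, r^2 and normalized standard deviation on paired values."""
    m = np.asarray(model, dtype=float)
    o = np.asarray(observed, dtype=float)
    ok = np.isfinite(m) & np.isfinite(o)
    m, o = m[ok], o[ok]
    if m.size < 2:
        raise UndefinedValueError("need >= 2 paired values")
    sd_o = o.std(ddof=1)
    sd_m = m.std(ddof=1)
    if sd_o == 0:
        raise UndefinedValueError("NSD undefined: zero observed variance")
    if sd_m == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(m, o).statistic)
    try:
        bias = nmbf(m, o)
    except UndefinedValueError:
        bias = np.nan  # e.g. negative-sum series; bias factor has no meaning
    return EvaluationMetrics(
        nmbf=bias,
        pearson_r=r,
        r_squared=r**2 if np.isfinite(r) else np.nan,
        nsd=float(sd_m / sd_o),
        n_pairs=int(m.size),
    )


def composite_series(stations: list[StationSeries], scenario: str = "all"):
    """Regional-average (unweighted mean across stations per timestamp)
    observed and model series, as used for multi-station composites."""
    obs = pd.concat([s.observed_series() for s in stations], axis=1).mean(axis=1)
    mod = pd.concat([s.model_series(scenario) for s in stations], axis=1).mean(axis=1)
    return mod, obs


def evaluate_stations(
    stations: list[StationSeries],
    scenario: str = "all",
    fire_derived: bool = True,
    composite: bool = True,
) -> pd.DataFrame:
    """Scorecard: one row per station plus (optionally) the composite.

    With ``fire_derived`` the per-year minimum-month subtraction is
    applied to both model and observed series before computing metrics.
    """

    def _metrics(mod: pd.Series, obs: pd.Series) -> EvaluationMetrics:
        if fire_derived:
            mod, obs = fire_derived_series(mod), fire_derived_series(obs)
        return pearson_and_nsd(mod.values, obs.values)

    rows = []
    for s in stations:
        met = _metrics(s.model_series(scenario), s.observed_series())
        rows.append({"station_id": s.station_id, **met.__dict__})
    if composite and stations:
        mod, obs = composite_series(stations, scenario)
        met = _metrics(mod, obs)
        rows.append({"station_id": "composite", **met.__dict__})
    return pd.DataFrame(rows)
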