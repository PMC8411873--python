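"""Exposure metrics on gridded concentration fields.

Covers the standard quantities of a fire-impact air-quality assessment:
bilinear regridding, block-mean aggregation to a coarser grid,
population-weighted regional means, annual average daily-maximum-8-h
ozone (ADM8h), percentage changes between scenario pairs, and the
population living above a concentration threshold (WHO guideline or
interim targets).

Missing values (NaN) are ignored by masked metrics; the missing fraction
can be queried separately.  Threshold comparisons are strict (">").
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .exceptions import ExtrapolationError, GridAlignmentError, UndefinedValueError
from .grids import RegionMask, check_aligned, check_regular, make_field

__all__ = [
    "regrid_linear",
    "aggregate_mean_to_grid",
    "population_weighted_mean",
    "area_weighted_mean",
    "adm8h",
    "daily_max_8h",
    "percent_change",
    "population_above_threshold",
]


def regrid_linear(field: xr.DataArray, target_lat, target_lon) -> xr.DataArray:
    """Bilinear interpolation onto target cell centres.

    The target grid must lie inside the source extent (no extrapolation);
    a constant field maps to itself and a (bi)linear field is reproduced
    exactly.
    """
    target_lat = np.asarray(target_lat, float)
    target_lon = np.asarray(target_lon, float)
    check_regular(target_lat, "target lat")
    check_regular(target_lon, "target lon")
    src_lat = field.coords["lat"].values
    src_lon = field.coords["lon"].values
    if (
        target_lat[0] < src_lat[0]
        or target_lat[-1] > src_lat[-1]
        or target_lon[0] < src_lon[0]
        or target_lon[-1] > src_lon[-1]
    ):
        raise ExtrapolationError("target grid extends outside the source grid")
    out = field.interp(lat=target_lat, lon=target_lon, method="linear")
    out.attrs = dict(field.attrs)
    return out


def aggregate_mean_to_grid(fine: xr.DataArray, target_lat, target_lon) -> xr.DataArray:
    """Mean of fine cells falling in each target cell (NaNs skipped).

    Fine cells are assigned to the target cell containing their centre;
    target cells with no finite fine values come out missing.  This is the
    operation used to bring a fine poverty-proxy raster onto the analysis
    grid.
    """
    target_lat = np.asarray(target_lat, float)
    target_lon = np.asarray(target_lon, float)
    check_regular(target_lat, "target lat")
    check_regular(target_lon, "target lon")
    dlat = target_lat[1] - target_lat[0]
    dlon = target_lon[1] - target_lon[0]
    lat_edges = np.concatenate([target_lat - dlat / 2, [target_lat[-1] + dlat / 2]])
    lon_edges = np.concatenate([target_lon - dlon / 2, [target_lon[-1] + dlon / 2]])
    fl = fine.coords["lat"].values
    fo = fine.coords["lon"].values
    li = np.digitize(fl, lat_edges) - 1
    lj = np.digitize(fo, lon_edges) - 1
    vals = fine.values
    nlat, nlon = target_lat.size, target_lon.size
    acc = np.zeros((nlat, nlon))
    cnt = np.zeros((nlat, nlon))
    for i, ti in enumerate(li):
        if not 0 <= ti < nlat:
            continue
        for j, tj in enumerate(lj):
            if not 0 <= tj < nlon:
                continue
            v = vals[i, j]
            if np.isfinite(v):
                acc[ti, tj] += v
                cnt[ti, tj] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return make_field(out, target_lat, target_lon, units=fine.attrs.get("units"))


def _mask_values(field: xr.DataArray, mask: RegionMask | None):
    if mask is None:
        return field.values
    check_aligned(field, mask.mask)
    return np.where(mask.mask.values, field.values, np.nan)


def population_weighted_mean(
    field: xr.DataArray, pop: xr.DataArray, mask: RegionMask | None = None
) -> float:
    """Sum(C * P) / Sum(P) over (unmasked, non-missing) cells."""
    check_aligned(field, pop)
    c = _mask_values(field, mask)
    p = np.where(np.isfinite(c), pop.values, 0.0)
    tot = p.sum()
    if tot <= 0:
        raise UndefinedValueError("zero population under the mask")
    return float(np.nansum(c * p) / tot)


def area_weighted_mean(field: xr.DataArray, mask: RegionMask | None = None) -> float:
    """cos(latitude)-weighted regional mean (for non-population metrics)."""
    c = _mask_values(field, mask)
    w = np.cos(np.radians(field.coords["lat"].values))[:, None] * np.ones_like(c)
    w = np.where(np.isfinite(c), w, 0.0)
    if w.sum() <= 0:
        raise UndefinedValueError("no finite cells under the mask")
    return float(np.nansum(c * w) / w.sum())


def missing_fraction(field: xr.DataArray, mask: RegionMask | None = None) -> float:
    c = _mask_values(field, mask)
    n = c.size if mask is None else int(mask.mask.sum())
    return float(np.sum(~np.isfinite(c)) / n) if n else 0.0


def daily_max_8h(hourly: np.ndarray, cross_day: bool = False) -> np.ndarray:
    """Daily maximum of running 8-h means from an (n_days*24, ...) array.

    Windows are confined within calendar days by default (17 windows per
    day, starts at hours 0..16); ``cross_day`` allows windows spanning
    midnight (window labelled by its start day).  Days with fewer than 8
    valid hours give NaN.
    """
    hourly = np.asarray(hourly, dtype=float)
    n = hourly.shape[0]
    if n % 24 != 0:
        raise ValueError("hourly input length must be a multiple of 24")
    n_days = n // 24
    out_shape = (n_days,) + hourly.shape[1:]
    out = np.full(out_shape, np.nan)
    starts_per_day = 24 if cross_day else 17
    for d in range(n_days):
        best = np.full(hourly.shape[1:], -np.inf)
        any_valid = np.zeros(hourly.shape[1:], dtype=bool)
        for s in range(starts_per_day):
            lo = d * 24 + s
            hi = lo + 8
            if hi > n:
                break
            win = hourly[lo:hi]
            valid = np.all(np.isfinite(win), axis=0)
            m = win.mean(axis=0)
            best = np.where(valid & (m > best), m, best)
            any_valid |= valid
        out[d] = np.where(any_valid, best, np.nan)
    return out


def adm8h(o3: xr.DataArray, cross_day: bool = False) -> xr.DataArray:
    """Annual average daily-maximum-8-h ozone.

    Accepts hourly input (``temporal == "hourly"``, time length a
    multiple of 24) or an already-daily max-8-h product; the annual value
    is the mean over days with valid maxima.  Cells with no valid day
    come out missing.
    """
    temporal = o3.attrs.get("temporal", "daily")
    if temporal == "hourly":
        dm = daily_max_8h(o3.values, cross_day=cross_day)
    else:
        dm = o3.values
    with np.errstate(invalid="ignore"):
        ann = np.nanmean(dm, axis=0)
    out = make_field(
        ann,
        o3.coords["lat"].values,
        o3.coords["lon"].values,
        species="O3",
        temporal="annual",
    )
    out.attrs["metric"] = "ADM8h"
    if "scenario" in o3.attrs:
        out.attrs["scenario"] = o3.attrs["scenario"]
    return out


def percent_change(with_fire, without_fire):
    """Percentage reduction when fires are excluded: 100 (with - without)/with.

    Works on aligned DataArrays (cell-wise map) or scalars; cells with a
    non-positive all-sources value come out missing.
    """
    if isinstance(with_fire, xr.DataArray):
        check_aligned(with_fire, without_fire)
        w = with_fire.values
        wo = without_fire.values
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(w > 0, 100.0 * (w - wo) / np.where(w > 0, w, 1.0), np.nan)
        res = make_field(out, with_fire.coords["lat"].values, with_fire.coords["lon"].values,
                         units="%")
        return res
    if with_fire <= 0:
        return float("nan")
    return 100.0 * (with_fire - without_fire) / with_fire


def population_above_threshold(
    field: xr.DataArray,
    pop: xr.DataArray,
    threshold: float,
    mask: RegionMask | None = None,
) -> float:
    """Population in cells with concentration strictly above the threshold."""
    check_aligned(field, pop)
    c = _mask_values(field, mask)
    over = np.isfinite(c) & (c > threshold)
    return float(pop.values[over].sum())
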