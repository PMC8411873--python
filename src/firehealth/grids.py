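"""Gridded containers: concentration fields, population, IMR, region masks.

All gridded products are :class:`xarray.DataArray` objects on a regular
lat/lon grid (cell-centre coordinates, strictly increasing, constant
spacing), dims ``("lat", "lon")`` for static fields and
``("time", "lat", "lon")`` for monthly/daily fields.  Metadata travels in
``attrs``: ``species`` (PM2.5 | PM10 | O3), ``scenario`` (all | nofire),
``temporal`` (hourly | daily | monthly | annual) and ``units``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import xarray as xr
from shapely.geometry import Point, shape
from shapely.prepared import prep

from .exceptions import ConfigurationError, GridAlignmentError

__all__ = [
    "make_field",
    "check_regular",
    "check_aligned",
    "fire_contribution",
    "RegionMask",
    "ScenarioPair",
    "write_netcdf",
    "read_netcdf",
]

_SPECIES_UNITS = {"PM2.5": "ug m-3", "PM10": "ug m-3", "O3": "ppbv"}


def check_regular(coord: np.ndarray, name: str = "coord") -> None:
    """Require strictly increasing, constant-spacing coordinates."""
    coord = np.asarray(coord, dtype=float)
    if coord.ndim != 1 or coord.size < 2:
        raise ConfigurationError(f"{name}: need a 1-D coordinate with >= 2 points")
    d = np.diff(coord)
    if np.any(d <= 0):
        raise ConfigurationError(f"{name}: coordinates must be strictly increasing")
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        raise ConfigurationError(f"{name}: coordinate spacing must be constant")


def make_field(
    values: np.ndarray,
    lat: np.ndarray,
    lon: np.ndarray,
    *,
    species: str | None = None,
    scenario: str | None = None,
    temporal: str | None = None,
    time=None,
    units: str | None = None,
    name: str | None = None,
) -> xr.DataArray:
    """Build a validated DataArray on a regular lat/lon grid."""
    check_regular(lat, "lat")
    check_regular(lon, "lon")
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        dims = ("lat", "lon")
        coords = {"lat": np.asarray(lat, float), "lon": np.asarray(lon, float)}
    elif values.ndim == 3:
        dims = ("time", "lat", "lon")
        if time is None:
            time = np.arange(values.shape[0])
        coords = {
            "time": np.asarray(time),
            "lat": np.asarray(lat, float),
            "lon": np.asarray(lon, float),
        }
    else:
        raise ConfigurationError("field must be 2-D (lat, lon) or 3-D (time, lat, lon)")
    if values.shape[-2:] != (len(lat), len(lon)):
        raise ConfigurationError(
            f"field shape {values.shape} does not match grid ({len(lat)}, {len(lon)})"
        )
    attrs = {}
    if species is not None:
        attrs["species"] = species
        attrs["units"] = units or _SPECIES_UNITS.get(species, "")
    elif units is not None:
        attrs["units"] = units
    if scenario is not None:
        attrs["scenario"] = scenario
    if temporal is not None:
        attrs["temporal"] = temporal
    return xr.DataArray(values, dims=dims, coords=coords, attrs=attrs, name=name)


def check_aligned(*fields: xr.DataArray) -> None:
    """Require all fields to share identical lat/lon coordinates."""
    ref = fields[0]
    for f in fields[1:]:
        for c in ("lat", "lon"):
            if ref.sizes.get(c) != f.sizes.get(c) or not np.allclose(
                ref.coords[c].values, f.coords[c].values, rtol=0, atol=1e-9
            ):
                raise GridAlignmentError(
                    f"grids not aligned on '{c}': {ref.sizes.get(c)} vs {f.sizes.get(c)} cells"
                )


def fire_contribution(all_field: xr.DataArray, nofire_field: xr.DataArray) -> xr.DataArray:
    """Fire-derived part of a scenario pair: all-sources minus fires-off."""
    check_aligned(all_field, nofire_field)
    out = all_field - nofire_field
    out.attrs = dict(all_field.attrs)
    out.attrs["scenario"] = "fire"
    return out


@dataclass
class RegionMask:
    """Named boolean cell-membership mask on the analysis grid.

    Masks can be built from declarative lat/lon box rules (the convention
    used for e.g. "SE China: south of 30N, east of 98E") or from polygons
    (GeoJSON), and combined into partitions for regional aggregation.
    """

    name: str
    mask: xr.DataArray  # boolean, dims (lat, lon)
    rule: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        if not bool(self.mask.any()):
            raise ConfigurationError(f"region '{self.name}' has no member cells")

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def from_box(
        cls,
        name: str,
        lat: np.ndarray,
        lon: np.ndarray,
        lat_min: float = -90.0,
        lat_max: float = 90.0,
        lon_min: float = -360.0,
        lon_max: float = 360.0,
    ) -> "RegionMask":
        """Mask of cells whose centres fall in [lat_min, lat_max) x [lon_min, lon_max)."""
        lat = np.asarray(lat, float)
        lon = np.asarray(lon, float)
        mlat = (lat >= lat_min) & (lat < lat_max)
        mlon = (lon >= lon_min) & (lon < lon_max)
        m = np.outer(mlat, mlon)
        da = xr.DataArray(m, dims=("lat", "lon"), coords={"lat": lat, "lon": lon})
        rule = {
            "type": "box",
            "lat_min": lat_min,
            "lat_max": lat_max,
            "lon_min": lon_min,
            "lon_max": lon_max,
        }
        return cls(name=name, mask=da, rule=rule)

    @classmethod
    def from_polygon(cls, name: str, lat: np.ndarray, lon: np.ndarray, polygon) -> "RegionMask":
        """Mask of cells whose centres fall inside a shapely polygon."""
        lat = np.asarray(lat, float)
        lon = np.asarray(lon, float)
        prepared = prep(polygon)
        m = np.zeros((lat.size, lon.size), dtype=bool)
        for i, la in enumerate(lat):
            for j, lo in enumerate(lon):
                m[i, j] = prepared.contains(Point(lo, la))
        da = xr.DataArray(m, dims=("lat", "lon"), coords={"lat": lat, "lon": lon})
        return cls(name=name, mask=da, rule={"type": "polygon"})

    @classmethod
    def from_geojson(cls, name: str, lat, lon, geojson: str | dict) -> "RegionMask":
        if isinstance(geojson, str):
            geojson = json.loads(geojson)
        geom = geojson.get("geometry", geojson)
        return cls.from_polygon(name, lat, lon, shape(geom))


def check_partition(masks: list[RegionMask]) -> None:
    """Require masks of a partition to be pairwise disjoint."""
    total = None
    for m in masks:
        arr = m.mask.values
        if total is None:
            total = arr.astype(int).copy()
        else:
            total += arr.astype(int)
    if total is not None and (total > 1).any():
        raise ConfigurationError("region masks of a partition overlap")


@dataclass
class ScenarioPair:
    """Matched all-sources / fires-off concentration fields on one grid.

    ``pm25_monthly``, ``pm10_monthly`` have dims (time, lat, lon) with 12
    monthly steps; ``o3_dm8h`` holds daily-maximum-8-h ozone with one step
    per day.  Annual means are derived, never stored, so the invariant
    "annual = mean of the monthlies" holds by construction.
    """

    pm25_monthly_all: xr.DataArray
    pm25_monthly_nofire: xr.DataArray
    pm10_monthly_all: xr.DataArray
    pm10_monthly_nofire: xr.DataArray
    o3_dm8h_all: xr.DataArray
    o3_dm8h_nofire: xr.DataArray

    def __post_init__(self):
        check_aligned(
            self.pm25_monthly_all,
            self.pm25_monthly_nofire,
            self.pm10_monthly_all,
            self.pm10_monthly_nofire,
            self.o3_dm8h_all,
            self.o3_dm8h_nofire,
        )

    @property
    def lat(self) -> np.ndarray:
        return self.pm25_monthly_all.coords["lat"].values

    @property
    def lon(self) -> np.ndarray:
        return self.pm25_monthly_all.coords["lon"].values

    def annual(self, species: str, scenario: str) -> xr.DataArray:
        """Annual mean field (mean over the time axis) for one species/scenario."""
        da = self.monthly(species, scenario) if species != "O3" else self.o3(scenario)
        out = da.mean("time")
        out.attrs = dict(da.attrs)
        out.attrs["temporal"] = "annual"
        return out

    def monthly(self, species: str, scenario: str) -> xr.DataArray:
        key = {"PM2.5": "pm25", "PM10": "pm10"}[species]
        return getattr(self, f"{key}_monthly_{scenario}")

    def o3(self, scenario: str) -> xr.DataArray:
        return getattr(self, f"o3_dm8h_{scenario}")

    def fire_pm25_annual(self) -> xr.DataArray:
        return fire_contribution(self.annual("PM2.5", "all"), self.annual("PM2.5", "nofire"))

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "pm25_monthly_all": self.pm25_monthly_all.rename({"time": "month"}),
                "pm25_monthly_nofire": self.pm25_monthly_nofire.rename({"time": "month"}),
                "pm10_monthly_all": self.pm10_monthly_all.rename({"time": "month"}),
                "pm10_monthly_nofire": self.pm10_monthly_nofire.rename({"time": "month"}),
                "o3_dm8h_all": self.o3_dm8h_all.rename({"time": "day"}),
                "o3_dm8h_nofire": self.o3_dm8h_nofire.rename({"time": "day"}),
            }
        )


def write_netcdf(obj: xr.Dataset | xr.DataArray, path) -> None:
    """Write a CF-style NetCDF file (NetCDF3 via the scipy backend)."""
    if isinstance(obj, xr.DataArray):
        obj = obj.to_dataset(name=obj.name or "field")
    obj.to_netcdf(path, engine="scipy")


def read_netcdf(path) -> xr.Dataset:
    return xr.load_dataset(path, engine="scipy")
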