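"""Gridded climatologies, bathymetry, ecological zone masks and light weighting.

Conventions (applied package-wide):

* latitudes are cell-center degrees, ascending; longitudes are cell-center
  degrees in [-180, 180); both axes regularly spaced;
* a climatology is exactly 12 monthly layers of one variable plus a single
  2-D validity mask (a cell is either valid in all months or in none);
* depth is meters, positive downward; the neritic/oceanic boundary is 200 m
  and the shelf-edge/deep boundary 2,000 m, ties going to the shallower band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

from .exceptions import (
    ConfigurationError,
    DegenerateInputError,
    GridFormatError,
)
from .geometry import cell_area_grid

DEPTH_NERITIC_M = 200.0
DEPTH_SHELF_EDGE_M = 2_000.0

ZONE_IDS = (
    "land",
    "surface_all",
    "surface_neritic",
    "surface_oceanic",
    "benthic_all",
    "benthic_neritic",
    "benthic_shelf_edge",
    "benthic_deep",
)


def _check_regular(axis: np.ndarray, name: str) -> float:
    if axis.ndim != 1 or axis.size < 1:
        raise GridFormatError(f"{name} axis must be 1-D and non-empty")
    if axis.size == 1:
        return np.nan
    steps = np.diff(axis)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise GridFormatError(f"{name} axis is not regularly spaced")
    if steps[0] <= 0:
        raise GridFormatError(f"{name} axis must be ascending")
    return float(steps[0])


@dataclass
class ClimatologyGrid:
    """Twelve monthly layers of one climatic variable on a regular grid."""

    name: str
    units: str
    lat: np.ndarray
    lon: np.ndarray
    data: np.ndarray  # (12, nlat, nlon)
    mask: np.ndarray  # (nlat, nlon) bool, True where valid

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != (12, self.lat.size, self.lon.size):
            raise GridFormatError(
                f"climatology '{self.name}' must have shape (12, nlat, nlon); "
                f"got {self.data.shape}"
            )
        _check_regular(self.lat, "lat")
        _check_regular(self.lon, "lon")
        if self.mask.shape != (self.lat.size, self.lon.size):
            raise GridFormatError("mask shape must be (nlat, nlon)")

    @property
    def resolution(self) -> float:
        return float(self.lat[1] - self.lat[0]) if self.lat.size > 1 else np.nan

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    def annual_mean(self) -> np.ndarray:
        """Per-cell mean over the 12 months (NaN outside the valid mask)."""
        out = self.data.mean(axis=0)
        out = np.where(self.mask, out, np.nan)
        return out

    def same_geometry(self, other: "ClimatologyGrid | BathymetryGrid") -> bool:
        return (
            self.lat.size == other.lat.size
            and self.lon.size == other.lon.size
            and np.allclose(self.lat, other.lat)
            and np.allclose(self.lon, other.lon)
        )

    # ----- I/O -------------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {
                self.name: (("month", "lat", "lon"), self.data),
                "valid": (("lat", "lon"), self.mask.astype(np.int8)),
            },
            coords={
                "month": np.arange(1, 13),
                "lat": self.lat,
                "lon": self.lon,
            },
        )
        ds[self.name].attrs["units"] = self.units
        return ds

    def write_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    def write_csv(self, path) -> None:
        months, lats, lons = np.meshgrid(
            np.arange(1, 13), self.lat, self.lon, indexing="ij"
        )
        df = pd.DataFrame(
            {
                "month": months.ravel(),
                "lat": lats.ravel(),
                "lon": lons.ravel(),
                "value": self.data.ravel(),
                "valid": np.broadcast_to(self.mask, self.data.shape).astype(int).ravel(),
            }
        )
        df.to_csv(path, index=False)


def read_climatology(path, dialect: str | None = None, name: str | None = None,
                     units: str = "") -> ClimatologyGrid:
    """Read a climatology from NetCDF or long-format CSV.

    ``dialect`` is 'netcdf' or 'csv'; inferred from the file suffix when
    omitted.  The file must declare exactly 12 monthly layers.
    """
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "netcdf"
    if dialect == "netcdf":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        data_vars = [v for v in ds.data_vars if v != "valid"]
        if name is None:
            if len(data_vars) != 1:
                raise GridFormatError(
                    f"expected one data variable, found {data_vars}; pass name="
                )
            name = data_vars[0]
        da = ds[name]
        if "month" not in da.dims or da.sizes["month"] != 12:
            raise GridFormatError(
                f"variable '{name}' must have 12 monthly layers"
            )
        lat = ds["lat"].values
        lon = ds["lon"].values
        data = da.transpose("month", "lat", "lon").values
        if "valid" in ds:
            mask = ds["valid"].values.astype(bool)
        else:
            mask = ~np.isnan(data).any(axis=0)
        return ClimatologyGrid(
            name=name,
            units=str(da.attrs.get("units", units)),
            lat=lat,
            lon=lon,
            data=data,
            mask=mask,
        )
    if dialect == "csv":
        df = pd.read_csv(path)
        months = np.sort(df["month"].unique())
        if months.size != 12 or not np.array_equal(months, np.arange(1, 13)):
            raise GridFormatError(
                f"CSV climatology must contain months 1..12, found {months.size} layers"
            )
        lat = np.sort(df["lat"].unique())
        lon = np.sort(df["lon"].unique())
        data = np.empty((12, lat.size, lon.size))
        valid = np.ones((lat.size, lon.size), dtype=bool)
        lat_idx = {v: i for i, v in enumerate(lat)}
        lon_idx = {v: i for i, v in enumerate(lon)}
        for row in df.itertuples(index=False):
            data[int(row.month) - 1, lat_idx[row.lat], lon_idx[row.lon]] = row.value
            if hasattr(row, "valid"):
                valid[lat_idx[row.lat], lon_idx[row.lon]] &= bool(row.valid)
        return ClimatologyGrid(
            name=name or "variable", units=units, lat=lat, lon=lon,
            data=data, mask=valid,
        )
    raise GridFormatError(f"unknown dialect '{dialect}'")


@dataclass
class BathymetryGrid:
    """Seafloor depth (m, positive downward) plus a land flag per cell."""

    lat: np.ndarray
    lon: np.ndarray
    depth: np.ndarray  # (nlat, nlon), NaN over land
    land_mask: np.ndarray  # (nlat, nlon) bool, True on land

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        _check_regular(self.lat, "lat")
        _check_regular(self.lon, "lon")
        ocean = ~self.land_mask
        if np.any(self.depth[ocean] < 0):
            raise GridFormatError("ocean depth must be >= 0 (positive downward)")

    @property
    def resolution(self) -> float:
        return float(self.lat[1] - self.lat[0]) if self.lat.size > 1 else np.nan

    def write_csv(self, path) -> None:
        lats, lons = np.meshgrid(self.lat, self.lon, indexing="ij")
        pd.DataFrame(
            {
                "lat": lats.ravel(),
                "lon": lons.ravel(),
                "depth": self.depth.ravel(),
                "land": self.land_mask.astype(int).ravel(),
            }
        ).to_csv(path, index=False)


def read_bathymetry_csv(path) -> BathymetryGrid:
    df = pd.read_csv(path)
    lat = np.sort(df["lat"].unique())
    lon = np.sort(df["lon"].unique())
    depth = np.full((lat.size, lon.size), np.nan)
    land = np.zeros((lat.size, lon.size), dtype=bool)
    lat_idx = {v: i for i, v in enumerate(lat)}
    lon_idx = {v: i for i, v in enumerate(lon)}
    for row in df.itertuples(index=False):
        depth[lat_idx[row.lat], lon_idx[row.lon]] = row.depth
        land[lat_idx[row.lat], lon_idx[row.lon]] = bool(row.land)
    return BathymetryGrid(lat=lat, lon=lon, depth=depth, land_mask=land)


@dataclass
class ZoneMask:
    """Membership mask of one ecological zone plus its total area."""

    zone_id: str
    member: np.ndarray  # (nlat, nlon) bool
    area_km2: float
    lat: np.ndarray = field(repr=False, default=None)
    lon: np.ndarray = field(repr=False, default=None)


def make_zone_masks(bathy: BathymetryGrid,
                    land_mask: np.ndarray | None = None) -> dict[str, ZoneMask]:
    """Build the land / pelagic / benthic zone masks from bathymetry.

    Depth thresholds are 200 m (neritic vs. oceanic / shelf vs. shelf-edge)
    and 2,000 m (shelf-edge vs. deep); a cell whose depth equals a threshold
    belongs to the shallower band.  The three benthic bands partition the
    ocean, as do the two surface bands.
    """
    land = bathy.land_mask if land_mask is None else np.asarray(land_mask, bool)
    ocean = ~land & np.isfinite(bathy.depth)
    if not ocean.any():
        warnings.warn("all-land grid: marine zone masks are empty", stacklevel=2)
    depth = bathy.depth
    neritic = ocean & (depth <= DEPTH_NERITIC_M)
    oceanic = ocean & (depth > DEPTH_NERITIC_M)
    shelf_edge = ocean & (depth > DEPTH_NERITIC_M) & (depth <= DEPTH_SHELF_EDGE_M)
    deep = ocean & (depth > DEPTH_SHELF_EDGE_M)

    res = bathy.resolution
    row_areas = cell_area_grid(bathy.lat, res)
    areas_2d = np.broadcast_to(row_areas[:, None], depth.shape)

    def _mk(zone_id: str, member: np.ndarray) -> ZoneMask:
        return ZoneMask(
            zone_id=zone_id,
            member=member,
            area_km2=float(areas_2d[member].sum()),
            lat=bathy.lat,
            lon=bathy.lon,
        )

    return {
        "land": _mk("land", land),
        "surface_all": _mk("surface_all", ocean),
        "surface_neritic": _mk("surface_neritic", neritic),
        "surface_oceanic": _mk("surface_oceanic", oceanic),
        "benthic_all": _mk("benthic_all", ocean),
        "benthic_neritic": _mk("benthic_neritic", neritic),
        "benthic_shelf_edge": _mk("benthic_shelf_edge", shelf_edge),
        "benthic_deep": _mk("benthic_deep", deep),
    }


@dataclass(frozen=True)
class LightWeightParams:
    """Parameters of the beta-shaped light response (E m^-2 yr^-1)."""

    v: float = 1.0
    e_max: float = 70.0
    e_opt: float = 20.0
    e_min: float = 0.0

    def __post_init__(self) -> None:
        if not (self.e_min < self.e_opt < self.e_max):
            raise ConfigurationError(
                "light params must satisfy e_min < e_opt < e_max"
            )
        if self.v <= 0:
            raise ConfigurationError("light params must have v > 0")


def light_weight(e, params: LightWeightParams = LightWeightParams()):
    """Beta-distribution weight w(e) in [0, v] for seabed irradiance e.

    w = v * ((e_max - e)/(e_max - e_opt))
          * ((e - e_min)/(e_opt - e_min)) ** ((e_opt - e_min)/(e_max - e_opt))

    Unimodal on [e_min, e_max] with w(e_opt) = v and w = 0 at both ends;
    inputs outside the interval are clipped to it.
    """
    e = np.clip(np.asarray(e, dtype=float), params.e_min, params.e_max)
    left = (params.e_max - e) / (params.e_max - params.e_opt)
    base = (e - params.e_min) / (params.e_opt - params.e_min)
    exponent = (params.e_opt - params.e_min) / (params.e_max - params.e_opt)
    w = params.v * left * np.power(base, exponent)
    return w if w.ndim else float(w)


def regrid_linear(grid: ClimatologyGrid, target_resolution: float) -> ClimatologyGrid:
    """Bilinear regrid to a new resolution over the same domain bounds.

    Target cells whose interpolation stencil touches an invalid source cell
    (or falls outside the source cell-center hull in latitude) come out
    invalid.  Longitude is treated as periodic.
    """
    if not grid.mask.any():
        raise DegenerateInputError("cannot regrid a grid with no valid cells")
    res = grid.resolution
    lat_lo = grid.lat[0] - res / 2.0
    lat_hi = grid.lat[-1] + res / 2.0
    n_lat = int(round((lat_hi - lat_lo) / target_resolution))
    lon_res = float(grid.lon[1] - grid.lon[0]) if grid.lon.size > 1 else res
    lon_lo = grid.lon[0] - lon_res / 2.0
    lon_span = grid.lon.size * lon_res
    n_lon = int(round(lon_span / target_resolution))
    new_lat = lat_lo + target_resolution * (np.arange(n_lat) + 0.5)
    new_lon = lon_lo + target_resolution * (np.arange(n_lon) + 0.5)

    # pad longitude once on each side so interpolation wraps the seam
    src_lon = np.concatenate(
        ([grid.lon[0] - lon_res], grid.lon, [grid.lon[-1] + lon_res])
    )
    masked = np.where(grid.mask, 1.0, np.nan)
    new_data = np.empty((12, n_lat, n_lon))
    pts_lat, pts_lon = np.meshgrid(new_lat, new_lon, indexing="ij")
    pts = np.column_stack([pts_lat.ravel(), pts_lon.ravel()])
    for m in range(12):
        layer = grid.data[m] * masked
        padded = np.concatenate([layer[:, -1:], layer, layer[:, :1]], axis=1)
        interp = RegularGridInterpolator(
            (grid.lat, src_lon), padded, method="linear",
            bounds_error=False, fill_value=np.nan,
        )
        new_data[m] = interp(pts).reshape(n_lat, n_lon)
    new_mask = ~np.isnan(new_data).any(axis=0)
    if not new_mask.any():
        raise DegenerateInputError("regridded field has no valid cells")
    new_data = np.where(new_mask[None, :, :], new_data, np.nan)
    return ClimatologyGrid(
        name=grid.name, units=grid.units, lat=new_lat, lon=new_lon,
        data=new_data, mask=new_mask,
    )
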