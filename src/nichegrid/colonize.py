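"""Monthly colonization of climatologies by a niche pool.

A pool member is present in a cell in a given month iff the cell's value on
every climatic axis that month lies inside the member's closed interval on
that axis.  From the 12 monthly presence sets we derive:

* phi_m  -- monthly richness (number of members present in month m),
* D      -- annual richness, the mean of the 12 monthly counts,
* Phi    -- union richness, members present in at least one month,
* psi10  -- monthly stability, sum(phi_m) / (12 * Phi).

Two residency policies are supported.  ``per_month`` (default) counts a
member in every month it tolerates individually; ``all_months`` requires
tolerance of all 12 months, in which case phi_m, D and Phi coincide.

Counting is exact but never loops over (member, cell, month) triples:
single-axis monthly counts use sorted-endpoint binary search, full two-axis
pools use the per-axis product identity, and explicit member samples are
evaluated in vectorized chunks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .exceptions import ConfigurationError, DimensionError
from .grids import ClimatologyGrid, LightWeightParams, ZoneMask, light_weight
from .niches import NichePool

PresencePolicy = Literal["per_month", "all_months"]

#: Above this full-product pool size the union count is skipped under
#: compute_union='auto' (the pairwise enumeration would not fit a desk run).
UNION_AUTO_LIMIT = 2_000_000


@dataclass
class RichnessField:
    """Per-cell monthly, annual-mean and union pseudo-species richness."""

    lat: np.ndarray
    lon: np.ndarray
    monthly: np.ndarray  # (12, nlat, nlon), NaN outside the zone
    annual_mean: np.ndarray  # (nlat, nlon)
    union_total: np.ndarray | None  # (nlat, nlon) or None if not computed
    zone_id: str
    policy: str
    pool_size: int
    phi: float

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.annual_mean)

    def to_dataset(self):
        import xarray as xr

        data = {
            "monthly_richness": (("month", "lat", "lon"), self.monthly),
            "annual_mean_richness": (("lat", "lon"), self.annual_mean),
        }
        if self.union_total is not None:
            data["union_richness"] = (("lat", "lon"), self.union_total)
        ds = xr.Dataset(
            data,
            coords={"month": np.arange(1, 13), "lat": self.lat, "lon": self.lon},
        )
        ds.attrs.update(zone_id=self.zone_id, policy=self.policy,
                        pool_size=self.pool_size, phi=self.phi)
        return ds

    def write_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")


def _cell_values(climates: Sequence[ClimatologyGrid], zone: ZoneMask):
    """Jointly valid cells of a zone and their per-axis monthly values."""
    base = climates[0]
    for c in climates[1:]:
        if not base.same_geometry(c):
            raise ConfigurationError("climate grids must share one geometry")
    if zone.member.shape != base.mask.shape:
        raise ConfigurationError("zone mask does not match the climate geometry")
    valid = zone.member.copy()
    for c in climates:
        valid &= c.mask
    values = [c.data[:, valid] for c in climates]  # each (12, ncells)
    return valid, values


def _monthly_counts_sorted(x: np.ndarray, y: np.ndarray, v: np.ndarray) -> np.ndarray:
    """#intervals with x <= v <= y, for every entry of v, via binary search."""
    xs = np.sort(x)
    ys = np.sort(y)
    return (
        np.searchsorted(xs, v, side="right") - np.searchsorted(ys, v, side="left")
    )


def _axis_member_intervals(pool: NichePool, d: int) -> tuple[np.ndarray, np.ndarray]:
    a = pool.axes[d]
    if pool.is_full:
        return a.x, a.y
    idx = pool.member_index[:, d]
    return a.x[idx], a.y[idx]


def _coverage_counts(x, y, lo, hi, chunk=4096) -> np.ndarray:
    """#intervals with x <= lo and y >= hi (lo, hi arrays over cells)."""
    out = np.zeros(lo.shape, dtype=np.int64)
    for start in range(0, x.size, chunk):
        xs = x[start : start + chunk, None]
        ys = y[start : start + chunk, None]
        out += ((xs <= lo[None, :]) & (ys >= hi[None, :])).sum(axis=0)
    return out


def richness_field(
    pool: NichePool,
    climates: Sequence[ClimatologyGrid] | ClimatologyGrid,
    zone: ZoneMask,
    policy: PresencePolicy = "per_month",
    compute_union: bool | str = "auto",
    chunk_size: int = 256,
) -> RichnessField:
    """Colonize a zone's climatology with a niche pool and count richness.

    ``climates`` supplies one grid per pool axis, in axis order (e.g. SST for
    a thermal pool; land temperature then precipitation for a two-axis pool).
    """
    if isinstance(climates, ClimatologyGrid):
        climates = [climates]
    if len(climates) != pool.n_axes:
        raise ConfigurationError(
            f"pool has {pool.n_axes} axes but {len(climates)} climate grids given"
        )
    if policy not in ("per_month", "all_months"):
        raise ConfigurationError(f"unknown presence policy '{policy}'")
    valid, values = _cell_values(climates, zone)
    ncells = int(valid.sum())
    nlat, nlon = valid.shape
    shape2 = (nlat, nlon)

    if policy == "all_months":
        # tolerance of all 12 months factorizes across axes:
        # x <= min_m v_m and y >= max_m v_m on every axis
        count = np.ones(ncells, dtype=np.int64)
        for d in range(pool.n_axes):
            x, y = _axis_member_intervals(pool, d)
            lo = values[d].min(axis=0)
            hi = values[d].max(axis=0)
            if pool.is_full:
                count_d = _coverage_counts(x, y, lo, hi)
                if d == 0:
                    count = count_d
                else:
                    count = count * count_d
            else:
                if d == 0:
                    member_ok = (x[:, None] <= lo[None, :]) & (y[:, None] >= hi[None, :])
                else:
                    member_ok &= (x[:, None] <= lo[None, :]) & (y[:, None] >= hi[None, :])
        if not pool.is_full:
            count = member_ok.sum(axis=0)
        monthly_cells = np.broadcast_to(count, (12, ncells)).astype(float)
        union_cells = count.astype(float)
    else:
        per_axis_monthly = []
        separable = pool.is_full or pool.n_axes == 1
        if separable:
            for d in range(pool.n_axes):
                x, y = _axis_member_intervals(pool, d)
                per_axis_monthly.append(_monthly_counts_sorted(x, y, values[d]))
            monthly_cells = per_axis_monthly[0].astype(float)
            for counts in per_axis_monthly[1:]:
                monthly_cells = monthly_cells * counts
        else:
            monthly_cells = None  # filled by the chunked pass below

        want_union = compute_union is True or (
            compute_union == "auto"
            and not (pool.is_full and pool.n_axes == 2 and pool.R_full > UNION_AUTO_LIMIT)
        )
        union_cells = None
        if want_union or monthly_cells is None:
            if pool.is_full and pool.n_axes == 2 and pool.R_full > UNION_AUTO_LIMIT:
                warnings.warn(
                    f"union richness over a full product pool of {pool.R_full} "
                    "members is expensive; consider compute_union=False",
                    stacklevel=2,
                )
            union_acc = np.zeros(ncells, dtype=np.int64)
            monthly_acc = np.zeros((12, ncells), dtype=np.int64)
            for _, per_axis in pool.iter_member_chunks(chunk_size):
                x0, y0 = per_axis[0]
                present = (x0[:, None, None] <= values[0][None]) & (
                    values[0][None] <= y0[:, None, None]
                )
                for d in range(1, pool.n_axes):
                    xd, yd = per_axis[d]
                    present &= (xd[:, None, None] <= values[d][None]) & (
                        values[d][None] <= yd[:, None, None]
                    )
                union_acc += present.any(axis=1).sum(axis=0)
                if monthly_cells is None:
                    monthly_acc += present.sum(axis=0)
            union_cells = union_acc.astype(float)
            if monthly_cells is None:
                monthly_cells = monthly_acc.astype(float)

    monthly = np.full((12, nlat, nlon), np.nan)
    monthly[:, valid] = monthly_cells
    annual = np.full(shape2, np.nan)
    annual[valid] = monthly_cells.mean(axis=0)
    union = None
    if union_cells is not None:
        union = np.full(shape2, np.nan)
        union[valid] = union_cells

    return RichnessField(
        lat=climates[0].lat,
        lon=climates[0].lon,
        monthly=monthly,
        annual_mean=annual,
        union_total=union,
        zone_id=zone.zone_id,
        policy=policy,
        pool_size=len(pool),
        phi=pool.phi,
    )


def stability_index(field: RichnessField) -> np.ndarray:
    """Cellwise monthly-stability index psi10 = sum_m(phi_m) / (12 * Phi).

    In (0, 1]; 1 means the same richness every month.  NaN where the union
    richness Phi is zero or the cell is outside the zone.
    """
    if field.union_total is None:
        raise ConfigurationError(
            "stability index requires the union richness; recompute the field "
            "with compute_union=True"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        psi10 = field.monthly.sum(axis=0) / (12.0 * field.union_total)
    psi10[~np.isfinite(psi10)] = np.nan
    psi10[field.union_total == 0] = np.nan
    return psi10


def weighted_richness(
    field: RichnessField,
    light: ClimatologyGrid,
    params: LightWeightParams = LightWeightParams(),
) -> np.ndarray:
    """Light-weighted annual richness D* = w(light) * D.

    ``light`` is the seabed-irradiance climatology; its annual mean drives
    the beta-shaped weight.  Used for the with-light benthic-neritic run.
    """
    if light.annual_mean().shape != field.annual_mean.shape:
        raise DimensionError("light grid does not match the richness geometry")
    w = light_weight(light.annual_mean(), params)
    return w * field.annual_mean
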