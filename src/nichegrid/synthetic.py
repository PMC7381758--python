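"""Seeded synthetic planet: climatologies, bathymetry and pseudo-observations.

The generator emulates the statistical structure the analysis relies on,
not real geography:

* sea-surface and land temperature follow a smooth equator-to-pole gradient
  with a seasonal cycle whose amplitude vanishes at the equator, grows
  toward the poles, and is antiphased between hemispheres;
* monthly precipitation has an equatorial maximum (a rain belt whose center
  migrates seasonally between hemispheres), subtropical dry belts, and a
  secondary midlatitude wet band;
* a meridional supercontinent (a longitude band spanning all latitudes)
  separates land from ocean, so the terrestrial gradient is defined at
  every latitude;
* bathymetry deepens monotonically away from the coast through shelf
  (< 200 m), shelf-edge (200-2,000 m) and deep (> 2,000 m) zones;
* seabed temperature relaxes toward a cold stable deep value with depth,
  and seabed light decays exponentially with depth (clipped to the observed
  0-33.43 E m^-2 yr^-1 range, zero below the photic cutoff).

Noise is a per-variable seeded Gaussian *spatial* field added identically
to all 12 months, so a configuration without seasonal forcing yields
exactly month-constant fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ConfigurationError, DimensionError
from .colonize import RichnessField
from .grids import BathymetryGrid, ClimatologyGrid, ZoneMask, make_zone_masks

#: Maximum seabed irradiance (E m^-2 yr^-1) retained after depth attenuation.
SEABED_LIGHT_MAX = 33.43

DEFAULT_NOISE_SD = {
    "sst": 0.3,
    "land_temp": 0.5,
    "precip": 8.0,
    "seabed_temp": 0.05,
    "seabed_light": 0.3,
}


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the synthetic planet (degrees, degC, mm, meters)."""

    n_lat: int = 90
    n_lon: int = 180
    lat_range: tuple[float, float] = (-90.0, 90.0)
    resolution: float = 2.0
    seed: int = 0
    sst_eq: float = 28.0          # equatorial annual-mean SST (degC)
    sst_pole: float = -1.8        # polar annual-mean SST (degC)
    seasonal_amp_pole: float = 8.0  # seasonal half-amplitude at the poles (degC)
    precip_eq: float = 280.0      # equatorial monthly precipitation peak (mm)
    precip_subtrop: float = 20.0  # subtropical monthly minimum scale (mm)
    dry_belt_lat: float = 25.0    # center of the subtropical dry belts (deg)
    land_fraction: float = 0.3    # fraction of longitudes in the continent
    shelf_width_cells: int = 2
    noise_sd: dict | float = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    itcz_shift_deg: float = 8.0   # seasonal migration of the rain-belt center
    continentality: float = 2.0   # land/sea seasonal-amplitude ratio
    photic_cutoff_m: float = 200.0
    light_attenuation_per_m: float = 0.025
    light_surface_eq: float = 36.0  # surface irradiance at the equator
    deep_sea_temp: float = 2.0

    def __post_init__(self) -> None:
        if self.n_lat <= 0 or self.n_lon <= 0 or self.resolution <= 0:
            raise ConfigurationError("grid sizes and resolution must be positive")
        lo, hi = self.lat_range
        if abs(self.resolution * self.n_lat - (hi - lo)) > 1e-9:
            raise ConfigurationError(
                "resolution * n_lat must span lat_range exactly"
            )
        if self.precip_eq <= self.precip_subtrop:
            raise ConfigurationError("precip_eq must exceed precip_subtrop")
        if not 0.0 <= self.land_fraction <= 1.0:
            raise ConfigurationError("land_fraction must lie in [0, 1]")

    def without_seasonality(self) -> "WorldConfig":
        """Copy with every source of monthly variation switched off."""
        return replace(self, seasonal_amp_pole=0.0, itcz_shift_deg=0.0)

    def noise_for(self, variable: str) -> float:
        if isinstance(self.noise_sd, dict):
            return float(self.noise_sd.get(variable, 0.0))
        return float(self.noise_sd)

    # ----- config file round trip -----------------------------------------
    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "lat_range" in data:
            data["lat_range"] = tuple(data["lat_range"])
        return cls(**data)


@dataclass
class SyntheticWorld:
    """All fields of one synthetic planet on a shared geometry."""

    config: WorldConfig
    sst: ClimatologyGrid
    land_temp: ClimatologyGrid
    precip: ClimatologyGrid
    seabed_temp: ClimatologyGrid
    seabed_light: ClimatologyGrid
    bathymetry: BathymetryGrid
    land_mask: np.ndarray

    @property
    def lat(self) -> np.ndarray:
        return self.sst.lat

    @property
    def lon(self) -> np.ndarray:
        return self.sst.lon

    def zone_masks(self) -> dict[str, ZoneMask]:
        return make_zone_masks(self.bathymetry, land_mask=self.land_mask)

    def to_netcdf(self, path) -> None:
        import xarray as xr

        ds = xr.merge(
            [
                g.to_dataset().rename({"valid": f"{g.name}_valid"})
                for g in (self.sst, self.land_temp, self.precip,
                          self.seabed_temp, self.seabed_light)
            ]
        )
        ds["depth"] = (("lat", "lon"), self.bathymetry.depth)
        ds["land"] = (("lat", "lon"), self.land_mask.astype(np.int8))
        ds.to_netcdf(path, engine="scipy")


def _monthly_phase(months: np.ndarray) -> np.ndarray:
    """Seasonal phase factor peaking in July (month 7)."""
    return np.cos(2.0 * np.pi * (months - 7.0) / 12.0)


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Deterministically generate a synthetic planet from its configuration."""
    lo, hi = config.lat_range
    lat = lo + config.resolution * (np.arange(config.n_lat) + 0.5)
    lon_res = 360.0 / config.n_lon
    lon = -180.0 + lon_res * (np.arange(config.n_lon) + 0.5)
    rad = np.radians(lat)
    months = np.arange(1, 13, dtype=float)
    phase = _monthly_phase(months)  # (12,)
    hemi = np.where(lat >= 0.0, 1.0, -1.0)

    # --- land mask: meridional supercontinent centered on lon 0 ------------
    n_land = int(round(config.land_fraction * config.n_lon))
    land_cols = np.zeros(config.n_lon, dtype=bool)
    if n_land > 0:
        j0 = config.n_lon // 2 - n_land // 2
        land_cols[j0 : j0 + n_land] = True
    land_mask = np.broadcast_to(land_cols, (config.n_lat, config.n_lon)).copy()

    def _noise(variable: str, idx: int) -> np.ndarray:
        sd = config.noise_for(variable)
        if sd == 0.0:
            return np.zeros((config.n_lat, config.n_lon))
        rng = np.random.default_rng([config.seed, idx])
        return rng.normal(0.0, sd, size=(config.n_lat, config.n_lon))

    # --- temperatures -------------------------------------------------------
    annual_sst = config.sst_pole + (config.sst_eq - config.sst_pole) * np.cos(rad) ** 2
    amp = config.seasonal_amp_pole * np.abs(np.sin(rad))
    seasonal = amp[None, :] * hemi[None, :] * phase[:, None]  # (12, nlat)
    sst3 = annual_sst[None, :, None] + seasonal[:, :, None] + _noise("sst", 1)[None]
    sst3 = np.maximum(sst3, -1.8)  # sea water freezes

    land3 = (
        annual_sst[None, :, None]
        + config.continentality * seasonal[:, :, None]
        + _noise("land_temp", 2)[None]
    )

    # --- precipitation ------------------------------------------------------
    sigma_itcz = 9.0
    belt_center = config.itcz_shift_deg * phase  # (12,)
    rain_belt = config.precip_eq * np.exp(
        -(((lat[None, :] - belt_center[:, None]) / sigma_itcz) ** 2)
    )
    midlat_band = 60.0 * np.exp(
        -(((np.abs(lat) - 2.0 * config.dry_belt_lat) / 15.0) ** 2)
    )
    precip2 = rain_belt + midlat_band[None, :] + config.precip_subtrop * 0.25
    precip3 = precip2[:, :, None] + _noise("precip", 3)[None]
    precip3 = np.maximum(precip3, 0.0)

    # --- bathymetry ---------------------------------------------------------
    depth = np.full((config.n_lat, config.n_lon), np.nan)
    ocean_cols = ~land_cols
    if ocean_cols.any():
        if land_cols.any():
            land_idx = np.flatnonzero(land_cols)
            col_idx = np.arange(config.n_lon)
            diff = np.abs(col_idx[:, None] - land_idx[None, :])
            dist_cols = np.minimum(diff, config.n_lon - diff).min(axis=1)
        else:
            dist_cols = np.full(config.n_lon, 10)
        shelf_w = max(config.shelf_width_cells, 1)
        slope_w = 3
        prof = np.empty(config.n_lon)
        for j in np.flatnonzero(ocean_cols):
            d = dist_cols[j]
            if d <= shelf_w:
                prof[j] = 180.0 * d / shelf_w  # shelf: 0..180 m
            elif d <= shelf_w + slope_w:
                prof[j] = 200.0 + 1_800.0 * (d - shelf_w) / slope_w  # slope to 2,000
            else:
                prof[j] = min(2_500.0 + 400.0 * (d - shelf_w - slope_w), 4_500.0)
        depth[:, ocean_cols] = prof[ocean_cols][None, :]

    bathy = BathymetryGrid(lat=lat, lon=lon, depth=depth, land_mask=land_mask)

    # --- seabed temperature and light ---------------------------------------
    depth_safe = np.where(np.isfinite(depth), depth, 0.0)
    mixing = np.exp(-depth_safe / 300.0)  # surface influence fades with depth
    seabed3 = mixing[None] * sst3 + (1.0 - mixing[None]) * config.deep_sea_temp
    seabed3 = seabed3 + _noise("seabed_temp", 4)[None]

    surface_light = config.light_surface_eq * np.cos(rad)
    light2 = surface_light[:, None] * np.exp(
        -config.light_attenuation_per_m * depth_safe
    )
    light2 = light2 + _noise("seabed_light", 5)
    light2 = np.clip(light2, 0.0, SEABED_LIGHT_MAX)
    light2[depth_safe > config.photic_cutoff_m] = 0.0
    light3 = np.broadcast_to(light2, (12, config.n_lat, config.n_lon)).copy()

    ocean_mask = ~land_mask

    def _grid(name, units, data, mask):
        return ClimatologyGrid(
            name=name, units=units, lat=lat, lon=lon,
            data=np.where(mask[None], data, np.nan), mask=mask,
        )

    return SyntheticWorld(
        config=config,
        sst=_grid("sst", "degC", sst3, ocean_mask),
        land_temp=_grid("land_temp", "degC", land3, land_mask),
        precip=_grid("precip", "mm", precip3, land_mask),
        seabed_temp=_grid("seabed_temp", "degC", seabed3, ocean_mask),
        seabed_light=_grid("seabed_light", "E m-2 yr-1", light3, ocean_mask),
        bathymetry=bathy,
        land_mask=land_mask,
    )


def generate_observed_richness(
    world: SyntheticWorld,
    model_richness: RichnessField,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Pseudo-observed richness: model annual richness plus seeded Gaussian
    noise, truncated at zero.  Ground truth for validating the correlation
    machinery."""
    if model_richness.annual_mean.shape != (world.lat.size, world.lon.size):
        raise DimensionError("richness field does not match the world geometry")
    base = model_richness.annual_mean
    if noise_sd == 0.0:
        return base.copy()
    rng = np.random.default_rng(seed)
    noisy = base + rng.normal(0.0, noise_sd, size=base.shape)
    return np.where(np.isfinite(base), np.maximum(noisy, 0.0), np.nan)
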