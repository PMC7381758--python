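import numpy as np
import pytest

from nichegrid import (
    BathymetryGrid,
    ClimatologyGrid,
    LightWeightParams,
    THERMAL_SPEC,
    build_pool,
    light_weight,
    make_zone_masks,
    read_climatology,
    regrid_linear,
    richness_field,
    sample_pool,
)
from nichegrid.exceptions import ConfigurationError, DegenerateInputError, GridFormatError
from nichegrid.patterns import correlate_maps


def small_grid(nlat=4, nlon=6, fill=10.0):
    lat = np.linspace(-45, 45, nlat)
    lon = np.linspace(-150, 150, nlon)
    data = np.full((12, nlat, nlon), fill)
    return ClimatologyGrid("sst", "degC", lat, lon, data, np.ones((nlat, nlon), bool))


class TestClimatologyIO:
    def test_netcdf_round_trip(self, tmp_path, world_coarse):
        path = tmp_path / "sst.nc"
        world_coarse.sst.write_netcdf(path)
        back = read_climatology(path)
        assert np.allclose(back.lat, world_coarse.sst.lat)
        assert np.array_equal(back.mask, world_coarse.sst.mask)
        valid = back.mask
        assert np.allclose(back.data[:, valid], world_coarse.sst.data[:, valid])

    def test_csv_round_trip_small_fixture(self, tmp_path):
        grid = small_grid(3, 3)
        grid.data[:] = np.arange(12 * 9).reshape(12, 3, 3)
        path = tmp_path / "grid.csv"
        grid.write_csv(path)
        back = read_climatology(path, dialect="csv")
        assert np.allclose(back.data, grid.data)
        assert np.allclose(back.lat, grid.lat)

    def test_eleven_layers_rejected(self):
        with pytest.raises(GridFormatError):
            ClimatologyGrid(
                "sst", "degC", np.linspace(-10, 10, 3), np.linspace(-10, 10, 3),
                np.zeros((11, 3, 3)), np.ones((3, 3), bool),
            )

    def test_irregular_axis_rejected(self):
        with pytest.raises(GridFormatError):
            ClimatologyGrid(
                "sst", "degC", np.array([0.0, 1.0, 3.0]), np.linspace(-10, 10, 3),
                np.zeros((12, 3, 3)), np.ones((3, 3), bool),
            )


class TestZoneMasks:
    def _bathy(self, depths):
        n = len(depths)
        return BathymetryGrid(
            lat=np.linspace(-10, 10, 2),
            lon=np.linspace(-100, 100, n),
            depth=np.tile(depths, (2, 1)).astype(float),
            land_mask=np.zeros((2, n), bool),
        )

    def test_depth_band_conventions(self):
        zones = make_zone_masks(self._bathy([150, 200, 2000, 2500]))
        # 150 m and the 200 m tie belong to the shallow bands
        assert zones["benthic_neritic"].member[0, 0]
        assert zones["surface_neritic"].member[0, 1]
        assert zones["benthic_neritic"].member[0, 1]
        # 2,000 m tie stays shelf-edge; 2,500 m is deep and oceanic
        assert zones["benthic_shelf_edge"].member[0, 2]
        assert zones["benthic_deep"].member[0, 3]
        assert zones["surface_oceanic"].member[0, 3]

    def test_benthic_bands_partition_ocean(self, world_coarse):
        zones = world_coarse.zone_masks()
        stack = (
            zones["benthic_neritic"].member.astype(int)
            + zones["benthic_shelf_edge"].member.astype(int)
            + zones["benthic_deep"].member.astype(int)
        )
        assert np.array_equal(stack, zones["benthic_all"].member.astype(int))
        surf = (
            zones["surface_neritic"].member.astype(int)
            + zones["surface_oceanic"].member.astype(int)
        )
        assert np.array_equal(surf, zones["surface_all"].member.astype(int))

    def test_all_land_warns_with_empty_ocean(self):
        bathy = BathymetryGrid(
            lat=np.linspace(-10, 10, 2), lon=np.linspace(-100, 100, 2),
            depth=np.full((2, 2), np.nan), land_mask=np.ones((2, 2), bool),
        )
        with pytest.warns(UserWarning):
            zones = make_zone_masks(bathy)
        assert not zones["surface_all"].member.any()


class TestLightWeight:
    def test_optimum_gives_unit_weight(self):
        assert light_weight(20.0) == pytest.approx(1.0)

    def test_boundaries_are_zero(self):
        assert light_weight(0.0) == 0.0
        assert light_weight(70.0) == 0.0

    def test_observed_maximum_irradiance(self):
        assert light_weight(33.43) == pytest.approx(0.898, abs=5e-4)

    def test_out_of_range_clipped(self):
        assert light_weight(-5.0) == light_weight(0.0)
        assert light_weight(95.0) == light_weight(70.0)

    def test_unimodal_with_max_at_e_opt(self):
        e = np.linspace(0, 70, 1401)
        w = light_weight(e)
        peak = e[np.argmax(w)]
        assert peak == pytest.approx(20.0, abs=0.06)
        rising = w[e <= 20.0]
        falling = w[e >= 20.0]
        assert np.all(np.diff(rising) >= -1e-12)
        assert np.all(np.diff(falling) <= 1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            LightWeightParams(e_min=5, e_opt=5, e_max=70)


class TestRegrid:
    def test_constant_field_preserved(self):
        grid = small_grid(fill=7.5)
        out = regrid_linear(grid, grid.resolution / 2)
        assert np.allclose(out.data[:, out.mask], 7.5)

    def test_linear_in_latitude_exact(self):
        nlat, nlon = 6, 4
        lat = np.linspace(-75, 75, nlat)
        lon = np.linspace(-135, 135, nlon)
        data = np.broadcast_to(2.0 * lat[:, None], (12, nlat, nlon)).copy()
        grid = ClimatologyGrid("t", "degC", lat, lon, data, np.ones((nlat, nlon), bool))
        out = regrid_linear(grid, grid.resolution / 3)
        inner = (out.lat >= lat[0]) & (out.lat <= lat[-1])
        expected = 2.0 * out.lat[inner]
        got = out.data[0][inner][out.mask[inner]]
        assert np.allclose(got.reshape(inner.sum(), -1), expected[:, None])

    def test_invalid_stencil_propagates(self):
        grid = small_grid()
        grid.mask[1, 1] = False
        grid.data[:, 1, 1] = np.nan
        out = regrid_linear(grid, grid.resolution / 2)
        assert not out.mask.all()

    def test_empty_grid_rejected(self):
        grid = small_grid()
        grid.mask[:] = False
        with pytest.raises(DegenerateInputError):
            regrid_linear(grid, 1.0)

    def test_richness_resolution_insensitivity(self, world_coarse, zones_coarse):
        """Coarse- and fine-grid richness maps are nearly perfectly correlated."""
        pool = sample_pool(build_pool(THERMAL_SPEC), 0.05, seed=2)
        coarse = richness_field(
            pool, world_coarse.sst, zones_coarse["surface_all"], compute_union=False
        )
        fine_sst = regrid_linear(world_coarse.sst, 2.0)
        from nichegrid import ZoneMask

        fine_zone = ZoneMask(
            "surface_all", fine_sst.mask, 1.0, fine_sst.lat, fine_sst.lon
        )
        fine = richness_field(pool, fine_sst, fine_zone, compute_union=False)
        back = regrid_linear(fine_sst, 6.0)  # sanity: geometry machinery closes
        assert back.lat.size == world_coarse.sst.lat.size
        coarse_prof = np.nanmedian(coarse.annual_mean, axis=1)
        fine_prof = np.nanmedian(fine.annual_mean, axis=1)
        fine_on_coarse = fine_prof.reshape(coarse_prof.size, -1).mean(axis=1)
        rep = correlate_maps(coarse_prof, fine_on_coarse)
        assert rep.r >= 0.95
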