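import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nichegrid import (
    ClimatologyGrid,
    LightWeightParams,
    NicheAxisSpec,
    NichePool,
    build_pool,
    richness_field,
    sample_pool,
    stability_index,
    weighted_richness,
)
from nichegrid.exceptions import ConfigurationError
from conftest import full_zone, naive_richness


def climate_from_values(values, name="sst"):
    """(12, nlat, nlon) array -> ClimatologyGrid with everything valid."""
    values = np.asarray(values, dtype=float)
    _, nlat, nlon = values.shape
    lat = 2.0 * (np.arange(nlat) - (nlat - 1) / 2)
    lon = 2.0 * (np.arange(nlon) - (nlon - 1) / 2)
    return ClimatologyGrid(name, "", lat, lon, values, np.ones((nlat, nlon), bool))


class TestToyExamples:
    def test_constant_cell_value_six(self, toy_pool):
        clim = climate_from_values(np.full((12, 1, 1), 6.0))
        field = richness_field(toy_pool, clim, full_zone(1, 1))
        assert np.all(field.monthly[:, 0, 0] == 5)
        assert field.annual_mean[0, 0] == 5
        assert field.union_total[0, 0] == 5

    def test_empty_pool_all_zero(self, toy_spec):
        empty = NichePool(
            axes=build_pool(toy_spec).axes,
            member_index=np.empty((0, 1), dtype=int),
            sampled_fraction=1.0,
        )
        clim = climate_from_values(np.full((12, 2, 2), 6.0))
        field = richness_field(empty, clim, full_zone(2, 2))
        assert np.all(field.annual_mean == 0)
        assert np.all(field.union_total == 0)

    def test_alternating_months_union_and_mean(self, toy_pool):
        # months alternate 1 (3 niches: [0,2],[0,6],[0,10]) and 6 (5 niches);
        # the union is the 6 distinct intervals
        # [0,2],[0,6],[0,10],[5,7],[5,11],[5,15]
        vals = np.where(np.arange(12) % 2 == 0, 1.0, 6.0).reshape(12, 1, 1)
        field = richness_field(toy_pool, climate_from_values(vals), full_zone(1, 1))
        assert field.union_total[0, 0] == 6
        assert field.annual_mean[0, 0] == pytest.approx((6 * 3 + 6 * 5) / 12)  # = 4

    def test_axis_count_mismatch_rejected(self, toy_pool):
        clim = climate_from_values(np.zeros((12, 1, 1)))
        with pytest.raises(ConfigurationError):
            richness_field(toy_pool, [clim, clim], full_zone(1, 1))


class TestOracleEquivalence:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        policy=st.sampled_from(["per_month", "all_months"]),
        fraction=st.sampled_from([1.0, 0.5]),
    )
    def test_matches_triple_loop(self, seed, policy, fraction):
        """Vectorized counting equals the naive (niche x cell x month) loop."""
        rng = np.random.default_rng(seed)
        spec = NicheAxisSpec(0, int(rng.integers(6, 14)), 1, int(rng.integers(1, 4)),
                             int(rng.integers(1, 4)))
        pool = sample_pool(build_pool(spec), fraction, seed=seed)
        vals = rng.uniform(-2, spec.rho_max + 2, size=(12, 3, 4))
        clim = climate_from_values(vals)
        zone = full_zone(3, 4)
        field = richness_field(pool, clim, zone, policy=policy, compute_union=True)
        if policy == "per_month":
            monthly, union = naive_richness(pool, [vals], zone.member)
            assert np.array_equal(field.monthly, monthly)
            assert np.array_equal(field.union_total, union)
        else:
            expected = np.zeros((3, 4))
            for k in range(len(pool)):
                n = pool.get_niche(k)
                (x, y), = n.intervals
                expected += ((vals.min(0) >= x) & (vals.max(0) <= y))
            assert np.array_equal(field.annual_mean, expected)

    def test_two_axis_sampled_pairs_match_oracle(self):
        rng = np.random.default_rng(7)
        spec_t = NicheAxisSpec(0, 8, 2, 2, 3)
        spec_p = NicheAxisSpec(0, 12, 4, 4, 6, "precipitation")
        from nichegrid import build_product_pool

        pool = sample_pool(build_product_pool(spec_t, spec_p), 0.5, seed=1)
        vt = rng.uniform(0, 8, size=(12, 2, 3))
        vp = rng.uniform(0, 12, size=(12, 2, 3))
        zone = full_zone(2, 3)
        field = richness_field(
            pool, [climate_from_values(vt), climate_from_values(vp, "precip")], zone
        )
        monthly, union = naive_richness(pool, [vt, vp], zone.member)
        assert np.array_equal(field.monthly, monthly)
        assert np.array_equal(field.union_total, union)

    def test_full_product_pool_matches_oracle(self):
        rng = np.random.default_rng(3)
        spec_t = NicheAxisSpec(0, 6, 2, 2, 3)
        spec_p = NicheAxisSpec(0, 10, 5, 5, 5, "precipitation")
        from nichegrid import build_product_pool

        pool = build_product_pool(spec_t, spec_p)
        vt = rng.uniform(0, 6, size=(12, 2, 2))
        vp = rng.uniform(0, 10, size=(12, 2, 2))
        zone = full_zone(2, 2)
        field = richness_field(
            pool, [climate_from_values(vt), climate_from_values(vp, "precip")],
            zone, compute_union=True,
        )
        monthly, union = naive_richness(pool, [vt, vp], zone.member)
        assert np.array_equal(field.monthly, monthly)
        assert np.array_equal(field.union_total, union)


class TestStructuralProperties:
    def test_adding_niches_never_decreases_richness(self, toy_pool):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 12, size=(12, 3, 3))
        clim = climate_from_values(vals)
        zone = full_zone(3, 3)
        sub = sample_pool(toy_pool, 0.5, seed=4)
        f_sub = richness_field(sub, clim, zone)
        f_all = richness_field(toy_pool, clim, zone)
        assert np.all(f_all.monthly >= f_sub.monthly)
        assert np.all(f_all.union_total >= f_sub.union_total)

    def test_all_months_at_most_per_month(self, toy_pool):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 12, size=(12, 3, 3))
        clim = climate_from_values(vals)
        zone = full_zone(3, 3)
        strict = richness_field(toy_pool, clim, zone, policy="all_months")
        loose = richness_field(toy_pool, clim, zone, policy="per_month")
        assert np.all(strict.union_total <= loose.union_total)

    def test_mid_domain_at_field_level(self):
        """With SST linear in latitude, richness peaks where SST crosses the
        niche-domain midpoint."""
        spec = NicheAxisSpec(0, 20, 1, 1, 1)
        pool = build_pool(spec)
        nlat = 21
        sst = np.broadcast_to(
            np.linspace(0, 20, nlat)[None, :, None], (12, nlat, 1)
        ).copy()
        field = richness_field(pool, climate_from_values(sst), full_zone(nlat, 1))
        assert np.nanargmax(field.annual_mean[:, 0]) == nlat // 2  # SST = 10


class TestStability:
    def test_constant_climate_gives_one(self, toy_pool):
        clim = climate_from_values(np.full((12, 2, 2), 6.0))
        field = richness_field(toy_pool, clim, full_zone(2, 2))
        assert np.all(stability_index(field) == 1.0)

    def test_single_month_presence_gives_one_twelfth(self, toy_pool):
        # one month inside the domain, the rest far outside every niche
        vals = np.full((12, 1, 1), 1e6)
        vals[0] = 6.0
        field = richness_field(toy_pool, climate_from_values(vals), full_zone(1, 1))
        assert stability_index(field)[0, 0] == pytest.approx(1 / 12)

    def test_requires_union(self, toy_pool):
        clim = climate_from_values(np.full((12, 1, 1), 6.0))
        field = richness_field(toy_pool, clim, full_zone(1, 1), compute_union=False)
        with pytest.raises(ConfigurationError):
            stability_index(field)


class TestWeightedRichness:
    def _field(self, toy_pool, nlat=1, nlon=1, value=6.0):
        clim = climate_from_values(np.full((12, nlat, nlon), value))
        return richness_field(toy_pool, clim, full_zone(nlat, nlon))

    def test_optimal_light_is_identity(self, toy_pool):
        field = self._field(toy_pool)
        light = climate_from_values(np.full((12, 1, 1), 20.0), "light")
        assert weighted_richness(field, light)[0, 0] == field.annual_mean[0, 0]

    def test_zero_light_kills_richness(self, toy_pool):
        field = self._field(toy_pool)
        light = climate_from_values(np.zeros((12, 1, 1)), "light")
        assert weighted_richness(field, light)[0, 0] == 0.0

    def test_observed_maximum_light(self, toy_pool):
        field = self._field(toy_pool)  # D = 5
        light = climate_from_values(np.full((12, 1, 1), 33.43), "light")
        expected = 5 * 0.898250584287436
        assert weighted_richness(field, light)[0, 0] == pytest.approx(expected)
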