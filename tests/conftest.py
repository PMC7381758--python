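import numpy as np
import pytest

from nichegrid import (
    NicheAxisSpec,
    WorldConfig,
    ZoneMask,
    build_pool,
    generate_world,
    niche_contains,
)

#: toy axis: intervals [0,2],[5,7],[10,12],[0,6],[5,11],[0,10],[5,15]
TOY_SPEC = NicheAxisSpec(0, 10, 2, 4, 5, axis_id="temperature")


@pytest.fixture
def toy_spec():
    return TOY_SPEC


@pytest.fixture
def toy_pool():
    return build_pool(TOY_SPEC)


@pytest.fixture(scope="session")
def world_2deg():
    """The default synthetic planet at 2-degree resolution."""
    return generate_world(WorldConfig(seed=11))


@pytest.fixture(scope="session")
def zones_2deg(world_2deg):
    return world_2deg.zone_masks()


@pytest.fixture(scope="session")
def world_coarse():
    """A small 6-degree planet for fast end-to-end tests."""
    return generate_world(WorldConfig(n_lat=30, n_lon=60, resolution=6.0, seed=5))


@pytest.fixture(scope="session")
def zones_coarse(world_coarse):
    return world_coarse.zone_masks()


def full_zone(nlat, nlon, resolution=1.0, zone_id="test"):
    """An all-member zone mask on a synthetic geometry (area unused)."""
    # cell centers near the equator at 2-degree spacing so per-cell areas
    # are always well defined
    return ZoneMask(
        zone_id=zone_id,
        member=np.ones((nlat, nlon), dtype=bool),
        area_km2=1.0,
        lat=2.0 * (np.arange(nlat) - (nlat - 1) / 2),
        lon=2.0 * (np.arange(nlon) - (nlon - 1) / 2),
    )


def naive_richness(pool, climate_stacks, valid):
    """Triple-loop (niche x cell x month) oracle for richness counting.

    ``climate_stacks`` is a list of (12, nlat, nlon) arrays, one per axis.
    Returns (monthly, union) count arrays over all cells (NaN where invalid).
    """
    nlat, nlon = valid.shape
    monthly = np.full((12, nlat, nlon), np.nan)
    union = np.full((nlat, nlon), np.nan)
    for i in range(nlat):
        for j in range(nlon):
            if not valid[i, j]:
                continue
            per_month = np.zeros(12, dtype=int)
            union_count = 0
            for k in range(len(pool)):
                niche = pool.get_niche(k)
                months_ok = [
                    niche_contains(niche, [stack[m, i, j] for stack in climate_stacks])
                    for m in range(12)
                ]
                per_month += np.asarray(months_ok, dtype=int)
                union_count += int(any(months_ok))
            monthly[:, i, j] = per_month
            union[i, j] = union_count
    return monthly, union


def flood_fill_components(mask, connectivity=4, wrap=False):
    """Independent stack-based flood-fill labeling oracle."""
    nlat, nlon = mask.shape
    labels = np.zeros((nlat, nlon), dtype=int)
    current = 0
    for si in range(nlat):
        for sj in range(nlon):
            if not mask[si, sj] or labels[si, sj]:
                continue
            current += 1
            stack = [(si, sj)]
            labels[si, sj] = current
            while stack:
                i, j = stack.pop()
                if connectivity == 4:
                    deltas = [(-1, 0), (1, 0), (0, -1), (0, 1)]
                else:
                    deltas = [
                        (di, dj)
                        for di in (-1, 0, 1)
                        for dj in (-1, 0, 1)
                        if (di, dj) != (0, 0)
                    ]
                for di, dj in deltas:
                    ni, nj = i + di, j + dj
                    if ni < 0 or ni >= nlat:
                        continue
                    if wrap:
                        nj %= nlon
                    elif nj < 0 or nj >= nlon:
                        continue
                    if mask[ni, nj] and not labels[ni, nj]:
                        labels[ni, nj] = current
                        stack.append((ni, nj))
    return labels, current
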