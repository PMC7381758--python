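"""Allopatric pseudo-species: splitting a niche's range into disjoint patches.

Even with identical climatic tolerances, populations separated by at least
one unsuitable grid cell cannot mix, so each spatially connected component
of a niche's suitable range counts as one pseudo-species (Buffon's Law).
The labeling runs on the coarse grid (2 degrees by default): connectivity is
rook (4-neighbour) unless configured otherwise, longitude wraps around the
date line by default, and there is no adjacency across the poles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ConfigurationError
from .colonize import PresencePolicy, _cell_values
from .geometry import cell_area_grid
from .grids import ClimatologyGrid, ZoneMask
from .niches import Niche, NichePool


@dataclass
class RangeLabeling:
    """Connected-component labels of one niche's suitable range."""

    niche_id: int
    component_labels: np.ndarray  # (nlat, nlon) int, 0 = unsuitable
    n_components: int


def suitability_mask(
    niche: Niche,
    climates: Sequence[ClimatologyGrid] | ClimatologyGrid,
    zone: ZoneMask,
    policy: PresencePolicy = "per_month",
) -> np.ndarray:
    """Boolean suitability of every zone cell for one niche.

    Under ``per_month`` a cell is suitable if the niche tolerates it in at
    least one month (every axis in that same month); under ``all_months``
    all 12 months must be tolerated.
    """
    if isinstance(climates, ClimatologyGrid):
        climates = [climates]
    if len(climates) != len(niche.intervals):
        raise ConfigurationError("one climate grid per niche axis is required")
    valid, values = _cell_values(climates, zone)
    present = np.ones((12, int(valid.sum())), dtype=bool)
    for (x, y), v in zip(niche.intervals, values):
        present &= (x <= v) & (v <= y)
    cells = present.all(axis=0) if policy == "all_months" else present.any(axis=0)
    mask = np.zeros(valid.shape, dtype=bool)
    mask[valid] = cells
    return mask


def label_components(
    mask: np.ndarray,
    connectivity: int = 4,
    wrap_longitude: bool = True,
    niche_id: int = -1,
) -> RangeLabeling:
    """Label spatially connected patches of a suitability mask.

    ``connectivity`` is 4 (rook; diagonal contact does not connect) or 8.
    With ``wrap_longitude`` the first and last columns are adjacent.  Labels
    are contiguous positive integers; 0 marks unsuitable cells.
    """
    if connectivity not in (4, 8):
        raise ConfigurationError("connectivity must be 4 or 8")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labels, n = ndimage.label(mask, structure=structure)
    if wrap_longitude and mask.shape[1] > 1 and n > 1:
        # union labels that touch across the seam, then compact the numbering
        parent = np.arange(n + 1)

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        left, right = labels[:, 0], labels[:, -1]
        if connectivity == 4:
            pairs = zip(left, right)
        else:
            shifted_up = np.concatenate([right[1:], [0]])
            shifted_down = np.concatenate([[0], right[:-1]])
            pairs = list(zip(left, right)) + list(zip(left, shifted_up)) + list(
                zip(left, shifted_down)
            )
        for a, b in pairs:
            if a and b:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
        roots = np.array([find(a) for a in range(n + 1)])
        uniq = np.unique(roots[1:])
        remap = np.zeros(n + 1, dtype=labels.dtype)
        remap[uniq] = np.arange(1, uniq.size + 1)
        labels = remap[roots][labels]
        n = uniq.size
    return RangeLabeling(niche_id=niche_id, component_labels=labels, n_components=int(n))


def enumerate_pseudo_species(
    pool: NichePool,
    climates: Sequence[ClimatologyGrid] | ClimatologyGrid,
    zone: ZoneMask,
    policy: PresencePolicy = "per_month",
    connectivity: int = 4,
    wrap_longitude: bool = True,
) -> pd.DataFrame:
    """One record per (niche, connected range component) over a whole pool.

    Returns a DataFrame with columns ``species_id``, ``niche_id``,
    ``component_id``, ``cell_count`` and ``area_km2`` (sum of member cell
    areas).  Niches with empty suitable ranges contribute no record.  The
    per-niche record counts feed the mean-species-per-niche metric.
    """
    if isinstance(climates, ClimatologyGrid):
        climates = [climates]
    if len(climates) != pool.n_axes:
        raise ConfigurationError("one climate grid per pool axis is required")
    valid, values = _cell_values(climates, zone)
    nlat, nlon = valid.shape
    res = float(climates[0].lat[1] - climates[0].lat[0]) if nlat > 1 else 1.0
    row_areas = cell_area_grid(climates[0].lat, res)
    area_2d = np.broadcast_to(row_areas[:, None], (nlat, nlon))

    records: list[tuple[int, int, int, int, float]] = []
    species_id = 0
    mask = np.zeros((nlat, nlon), dtype=bool)
    for ids, per_axis in pool.iter_member_chunks(chunk_size=256):
        x0, y0 = per_axis[0]
        present = (x0[:, None, None] <= values[0][None]) & (
            values[0][None] <= y0[:, None, None]
        )
        for d in range(1, pool.n_axes):
            xd, yd = per_axis[d]
            present &= (xd[:, None, None] <= values[d][None]) & (
                values[d][None] <= yd[:, None, None]
            )
        suitable = (
            present.all(axis=1) if policy == "all_months" else present.any(axis=1)
        )
        for k, niche_id in enumerate(ids):
            cells = suitable[k]
            if not cells.any():
                continue
            mask[:] = False
            mask[valid] = cells
            labeling = label_components(
                mask, connectivity=connectivity, wrap_longitude=wrap_longitude,
                niche_id=int(niche_id),
            )
            flat = labeling.component_labels.ravel()
            counts = np.bincount(flat, minlength=labeling.n_components + 1)
            areas = np.bincount(
                flat, weights=area_2d.ravel(), minlength=labeling.n_components + 1
            )
            for comp in range(1, labeling.n_components + 1):
                records.append(
                    (species_id, int(niche_id), comp, int(counts[comp]), float(areas[comp]))
                )
                species_id += 1
    return pd.DataFrame(
        records,
        columns=["species_id", "niche_id", "component_id", "cell_count", "area_km2"],
    )
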