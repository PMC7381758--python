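"""Spherical geometry on a regular latitude/longitude grid.

Distances use a spherical Earth of radius 6,377.221 km (the Clarke-ellipsoid
equatorial value used throughout the biodiversity literature this package
follows), so all areas and distances are mutually consistent.
"""

from __future__ import annotations

import numpy as np

#: Earth radius (km) used for every distance/area in the package.
EARTH_RADIUS_KM = 6_377.221


def great_circle_distance(p1, p2) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees.

    d = R * arccos(sin(g1) sin(g2) + cos(g1) cos(g2) cos(dlon)), with the
    arccos argument clamped to [-1, 1] for numerical safety.  Symmetric,
    and zero for identical points.
    """
    lat1, lon1 = np.radians(np.asarray(p1, dtype=float))
    lat2, lon2 = np.radians(np.asarray(p2, dtype=float))
    cos_h = (
        np.sin(lat1) * np.sin(lat2)
        + np.cos(lat1) * np.cos(lat2) * np.cos(lon1 - lon2)
    )
    h = np.arccos(np.clip(cos_h, -1.0, 1.0))
    return float(EARTH_RADIUS_KM * h)


def cell_area(lat_center: float, resolution: float) -> float:
    """Area (km^2) of a regular grid cell centered at ``lat_center``.

    Computed as zonal span x meridional span, each span being the
    great-circle distance between the midpoints of opposite cell edges.
    Strictly decreasing with |lat| at fixed resolution.
    """
    half = resolution / 2.0
    if abs(lat_center) + half > 90.0 + 1e-9:
        raise ValueError(
            f"cell at lat={lat_center} with resolution={resolution} exceeds the pole"
        )
    zonal = great_circle_distance((lat_center, -half), (lat_center, half))
    meridional = great_circle_distance((lat_center - half, 0.0), (lat_center + half, 0.0))
    return zonal * meridional


def cell_area_grid(lat_centers: np.ndarray, resolution: float) -> np.ndarray:
    """Per-latitude-row cell areas (km^2) for a regular grid (1-D array)."""
    return np.array([cell_area(float(lat), resolution) for lat in lat_centers])
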