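"""Per-zone diversity summaries (psi1-psi10) and realm scaling.

For one domain or ecological zone the summary records:

* psi1 -- niches simulated (the sampled pool size),
* psi2 -- niches realized by at least one pseudo-species,
* psi3 -- 100 * psi2 / psi1 (%),
* psi4 -- mean pseudo-species (range components) per realized niche,
* psi5 -- total pseudo-species, psi2 * psi4 * phi, where phi corrects for
  simulating only a fraction 1/phi of the pool,
* psi6/psi7/psi8 -- median and quartiles of per-species range area (km^2),
* psi9 -- 100 * psi6 / zone area (%),
* psi10 -- zone-mean monthly stability of richness, in (0, 1].

Note on psi5: it multiplies the *realized* niche count psi2 (the published
per-zone tables are arithmetically consistent only with psi2, not with the
full pool size psi1; see docs/methods.md).

Scaling divides summed pseudo-species totals (terrestrial theta_T plus the
five marine zones, theta_M) by a reference species count so that the scaled
realm totals sum exactly to the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .colonize import RichnessField, stability_index
from .grids import ZoneMask
from .niches import NichePool

# Catalogued and estimated eukaryotic species counts used for realm scaling.
CATALOGUED_TERRESTRIAL = 1_233_500
CATALOGUED_MARINE = 193_756
CATALOGUED_TOTAL = CATALOGUED_TERRESTRIAL + CATALOGUED_MARINE  # 1,427,256
ESTIMATED_TERRESTRIAL = 8_740_000
ESTIMATED_MARINE = 2_210_000
ESTIMATED_TOTAL = ESTIMATED_TERRESTRIAL + ESTIMATED_MARINE  # 10,950,000


def total_pseudo_species(psi2: float, psi4: float, phi: float) -> float:
    """Total pseudo-species for a zone: realized niches x mean species per
    niche x sampling correction."""
    return psi2 * psi4 * phi


def area_share(psi6: float, zone_area_km2: float) -> float:
    """psi9: the median species range as a percentage of the zone area."""
    return 100.0 * psi6 / zone_area_km2


@dataclass
class DiversitySummary:
    zone_id: str
    psi1: int
    psi2: int
    psi3: float
    psi4: float
    psi5: float
    psi6: float
    psi7: float
    psi8: float
    psi9: float
    psi10: float
    phi: float
    zone_area_km2: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "zone": self.zone_id,
                "psi1": self.psi1,
                "psi2": self.psi2,
                "psi3": self.psi3,
                "psi4": self.psi4,
                "psi5": self.psi5,
                "psi6": self.psi6,
                "psi7": self.psi7,
                "psi8": self.psi8,
                "psi9": self.psi9,
                "psi10": self.psi10,
                "phi": self.phi,
                "area_km2": self.zone_area_km2,
            }
        )


def summarize_zone(
    pool: NichePool,
    species_records: pd.DataFrame,
    richness: RichnessField,
    zone: ZoneMask,
    area_weighted_stability: bool = False,
) -> DiversitySummary:
    """Compute the psi1-psi10 summary for one zone.

    ``species_records`` is the output of ``enumerate_pseudo_species`` for the
    same pool and zone.  Quartiles of the species-area distribution use
    linear interpolation between order statistics.
    """
    psi1 = len(pool)
    if len(species_records):
        psi2 = int(species_records["niche_id"].nunique())
        n_species = len(species_records)
        psi4 = n_species / psi2
        areas = species_records["area_km2"].to_numpy()
        psi7, psi6, psi8 = np.percentile(areas, [25, 50, 75])
    else:
        warnings.warn(f"zone '{zone.zone_id}': no species records", stacklevel=2)
        psi2, psi4 = 0, np.nan
        psi6 = psi7 = psi8 = np.nan
    psi3 = 100.0 * psi2 / psi1 if psi1 else np.nan
    psi5 = total_pseudo_species(psi2, psi4, pool.phi) if psi2 else 0.0
    psi9 = area_share(psi6, zone.area_km2) if zone.area_km2 else np.nan

    stab = stability_index(richness)
    cells = zone.member & np.isfinite(stab)
    if cells.any():
        if area_weighted_stability:
            from .geometry import cell_area_grid

            res = float(richness.lat[1] - richness.lat[0])
            w = np.broadcast_to(
                cell_area_grid(richness.lat, res)[:, None], stab.shape
            )
            psi10 = float((stab[cells] * w[cells]).sum() / w[cells].sum())
        else:
            psi10 = float(stab[cells].mean())
    else:
        psi10 = np.nan

    return DiversitySummary(
        zone_id=zone.zone_id,
        psi1=psi1,
        psi2=psi2,
        psi3=psi3,
        psi4=psi4,
        psi5=psi5,
        psi6=float(psi6),
        psi7=float(psi7),
        psi8=float(psi8),
        psi9=float(psi9),
        psi10=psi10,
        phi=pool.phi,
        zone_area_km2=zone.area_km2,
    )


@dataclass
class ScalingResult:
    theta_T: float
    theta_M: float
    n_reference: float
    scale_factor: float
    scaled_terrestrial: float
    scaled_marine: float

    @property
    def theta(self) -> float:
        return self.theta_T + self.theta_M


def scale_to_reference(
    terrestrial_total: float,
    marine_totals,
    n_reference: float,
) -> ScalingResult:
    """Scale planetary pseudo-biodiversity to a reference species count.

    ``marine_totals`` is a scalar or an iterable of per-zone totals (the
    marine realm total is their sum).  The scaled terrestrial and marine
    counts sum exactly to ``n_reference`` by construction.
    """
    if n_reference <= 0:
        raise ConfigurationError("reference species count must be positive")
    theta_M = float(np.sum(np.atleast_1d(np.asarray(marine_totals, dtype=float))))
    theta_T = float(terrestrial_total)
    theta = theta_T + theta_M
    if theta <= 0:
        raise ConfigurationError("total pseudo-biodiversity must be positive")
    k = theta / n_reference
    ref = float(n_reference)
    scaled_T = theta_T / k
    # complement then re-complement: the pair then sums to ref exactly in
    # floating point (Fast2Sum-style stabilization)
    scaled_M = ref - scaled_T
    scaled_T = ref - scaled_M
    return ScalingResult(
        theta_T=theta_T,
        theta_M=theta_M,
        n_reference=ref,
        scale_factor=k,
        scaled_terrestrial=scaled_T,
        scaled_marine=scaled_M,
    )


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Stack DiversitySummary objects into a table with one row per zone."""
    return pd.DataFrame([s.to_series() for s in summaries])
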