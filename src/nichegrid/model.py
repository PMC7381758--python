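"""Model/Results interface tying the pipeline stages together.

``NicheColonizationModel`` couples a niche pool to the climatology of one
domain or ecological zone; ``fit()`` runs the colonization (and optionally
the allopatric range-splitting) and returns a ``NicheColonizationResults``
carrying the richness fields, stability, species table, per-zone diversity
summary, gradient extractors and validation diagnostics.

    >>> world = generate_world(WorldConfig(seed=1))
    >>> model = NicheColonizationModel.from_world(world, "surface_all",
    ...                                           fraction=0.25, seed=1)
    >>> res = model.fit()
    >>> res.lbg_profile().peak_latitude()
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .colonize import (
    PresencePolicy,
    RichnessField,
    richness_field,
    stability_index,
    weighted_richness,
)
from .grids import ClimatologyGrid, LightWeightParams, ZoneMask
from .metrics import DiversitySummary, summarize_zone
from .niches import (
    NicheAxisSpec,
    NichePool,
    PRECIP_SPEC_COARSE,
    PRECIP_SPEC_FINE,
    THERMAL_SPEC,
    build_pool,
    build_product_pool,
    sample_pool,
)
from .patterns import (
    CorrelationReport,
    LBGMatrix,
    LBGProfile,
    correlate_maps,
    lbg_longitude_matrix,
    lbg_median,
)
from .speciate import enumerate_pseudo_species

#: climate sources per zone family on a synthetic world
_ZONE_CLIMATE = {
    "land": ("land_temp", "precip"),
    "surface": ("sst",),
    "benthic": ("seabed_temp",),
}


class NicheColonizationModel:
    """Climate-envelope colonization of one zone by a niche pool."""

    def __init__(
        self,
        pool: NichePool,
        climates: Sequence[ClimatologyGrid] | ClimatologyGrid,
        zone: ZoneMask,
        policy: PresencePolicy = "per_month",
        connectivity: int = 4,
        wrap_longitude: bool = True,
    ) -> None:
        if isinstance(climates, ClimatologyGrid):
            climates = [climates]
        if len(climates) != pool.n_axes:
            raise ConfigurationError(
                "one climate grid per niche axis is required"
            )
        self.pool = pool
        self.climates = list(climates)
        self.zone = zone
        self.policy = policy
        self.connectivity = connectivity
        self.wrap_longitude = wrap_longitude

    @classmethod
    def from_world(
        cls,
        world,
        zone_id: str,
        specs: Sequence[NicheAxisSpec] | None = None,
        fraction: float = 1.0,
        seed: int | None = None,
        coarse_precip: bool = False,
        **kwargs,
    ) -> "NicheColonizationModel":
        """Build the model for one zone of a synthetic (or loaded) world.

        Land zones use temperature and precipitation jointly; pelagic zones
        use SST; benthic zones use seabed temperature.  Default axis specs
        are the standard thermal and precipitation settings; ``fraction``
        subsamples the pool (recording phi = 1/fraction).
        """
        family = "land" if zone_id == "land" else zone_id.split("_")[0]
        if family not in _ZONE_CLIMATE:
            raise ConfigurationError(f"unknown zone '{zone_id}'")
        climate_names = _ZONE_CLIMATE[family]
        climates = [getattr(world, n) for n in climate_names]
        if specs is None:
            precip_spec = PRECIP_SPEC_COARSE if coarse_precip else PRECIP_SPEC_FINE
            specs = (
                (THERMAL_SPEC, precip_spec) if family == "land" else (THERMAL_SPEC,)
            )
        if len(specs) != len(climates):
            raise ConfigurationError(
                f"zone '{zone_id}' needs {len(climates)} axis spec(s)"
            )
        pool = (
            build_product_pool(*specs) if len(specs) == 2 else build_pool(specs[0])
        )
        pool = sample_pool(pool, fraction, seed=seed)
        zone = world.zone_masks()[zone_id]
        return cls(pool, climates, zone, **kwargs)

    def fit(
        self,
        speciation: bool = False,
        compute_union: bool | str = "auto",
    ) -> "NicheColonizationResults":
        """Run the colonization; optionally split ranges into pseudo-species.

        Range splitting is meaningful at coarse resolution (2 degrees); it
        is refused on sub-degree grids where it was never calibrated.
        """
        field = richness_field(
            self.pool, self.climates, self.zone,
            policy=self.policy, compute_union=compute_union,
        )
        species = None
        summary = None
        if speciation:
            res = self.climates[0].resolution
            if res < 1.0:
                raise ConfigurationError(
                    "range splitting runs on the coarse grid (>= 1 degree); "
                    f"got resolution {res}"
                )
            species = enumerate_pseudo_species(
                self.pool, self.climates, self.zone,
                policy=self.policy, connectivity=self.connectivity,
                wrap_longitude=self.wrap_longitude,
            )
            if field.union_total is not None:
                summary = summarize_zone(self.pool, species, field, self.zone)
        return NicheColonizationResults(self, field, species, summary)


@dataclass
class NicheColonizationResults:
    """Fitted richness fields plus derived diagnostics for one zone."""

    model: NicheColonizationModel
    richness: RichnessField
    species: pd.DataFrame | None = None
    zone_summary: DiversitySummary | None = None

    # ----- derived fields --------------------------------------------------
    def stability(self) -> np.ndarray:
        return stability_index(self.richness)

    def light_weighted_richness(
        self, light: ClimatologyGrid, params: LightWeightParams = LightWeightParams()
    ) -> np.ndarray:
        return weighted_richness(self.richness, light, params)

    # ----- gradients -------------------------------------------------------
    def lbg_profile(self, min_longitudes: int = 5) -> LBGProfile:
        return lbg_median(
            self.richness.annual_mean, self.richness.lat, min_longitudes
        )

    def lbg_matrix(self, bin_width: float = 0.05) -> LBGMatrix:
        return lbg_longitude_matrix(
            self.richness.annual_mean, self.richness.lat, bin_width
        )

    # ----- validation ------------------------------------------------------
    def correlate(self, observed: np.ndarray) -> CorrelationReport:
        """Pearson r (with minimum significant n*) against an observed map."""
        return correlate_maps(self.richness.annual_mean, observed)

    # ----- presentation ----------------------------------------------------
    def summary(self) -> str:
        f = self.richness
        lines = [
            "Niche colonization results",
            "=" * 44,
            f"{'zone':<24}{f.zone_id}",
            f"{'presence policy':<24}{f.policy}",
            f"{'pool size (psi1)':<24}{f.pool_size}",
            f"{'sampling phi':<24}{f.phi:g}",
            f"{'valid cells':<24}{int(f.valid.sum())}",
            f"{'mean annual richness':<24}{np.nanmean(f.annual_mean):.2f}",
            f"{'max annual richness':<24}{np.nanmax(f.annual_mean):.2f}",
        ]
        prof = self.lbg_profile()
        lines.append(f"{'LBG peak latitude':<24}{prof.peak_latitude():.1f}")
        if self.zone_summary is not None:
            s = self.zone_summary
            lines += [
                "-" * 44,
                f"{'occupied niches (psi2)':<24}{s.psi2}",
                f"{'occupied share (psi3)':<24}{s.psi3:.2f} %",
                f"{'species/niche (psi4)':<24}{s.psi4:.2f}",
                f"{'total species (psi5)':<24}{s.psi5:,.0f}",
                f"{'median area (psi6)':<24}{s.psi6:,.0f} km2",
                f"{'area share (psi9)':<24}{s.psi9:.2f} %",
                f"{'stability (psi10)':<24}{s.psi10:.3f}",
            ]
        lines.append("=" * 44)
        return "\n".join(lines)

    def plot_lbg(self, ax=None, **kwargs):
        """Plot median richness against latitude (matplotlib axis returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        prof = self.lbg_profile()
        ax.plot(prof.median_richness, prof.latitudes, **kwargs)
        ax.set_xlabel("median pseudo-species richness")
        ax.set_ylabel("latitude (deg)")
        ax.set_title(f"LBG - {self.richness.zone_id}")
        return ax
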