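# Methods

`nichegrid` implements a deterministic null model of global biodiversity:
species are reduced to rectangular climatic tolerance intervals ("niches"),
a combinatorial pool of all such niches is built, and each niche colonizes
every grid cell of a monthly climatology that it tolerates.  Local richness
is then simply the number of tolerant niches, and large-scale biodiversity
patterns — in particular the contrasting latitudinal biodiversity gradients
(LBGs) of land and ocean — emerge from the interaction between the niche
pool and the climate field, without dispersal limits, biotic interactions
or evolutionary dynamics.

## The niche pool

One axis spans `[rho_min, rho_max]` (thermal default −1.8 … 44 °C;
precipitation 0 … 3,000 mm per month).  Amplitudes grow arithmetically from
`alpha_1` in steps of `mu` up to `alpha_max = rho_max − rho_min`; for each
amplitude `alpha_i` the interval start steps from `rho_min` in increments of
the overlap `s`, with

    q_i = floor((alpha_max + s − alpha_i) / s + 1)

starts, the end being `x + alpha_i`.  The axis count is `r = Σ q_i`; a
two-axis (temperature × precipitation) pool is the full cross product
`R = r_t · r_p`.  Interval ends may exceed `rho_max`; they are kept, because
the construction (and the published pool sizes 930 and 72 for the two
precipitation settings) requires them.  Every niche is unique within a pool
(competitive exclusion) and intervals are closed on both ends — boundary
inclusion is not dictated by the construction, so the inclusive convention
is applied uniformly.

All of this arithmetic runs on exact rationals (`fractions.Fraction`).  The
floors are step-sensitive at `mu = s = 0.1`, and accumulating
double-precision increments changes counts: the thermal axis has exactly
101,474 intervals under exact arithmetic, while naive floating-point
accumulation can lose a few dozen intervals.  The exact count is the one
this package reports and tests (against an independent rational
enumeration oracle).

A pool can be subsampled uniformly without replacement (seeded); the
sampling fraction `f` is recorded as the correction factor `phi = 1/f` used
by the total-pseudo-species estimate.  The standard design uses `f = 1` for
precipitation-only pools, 0.25 for thermal pools in range-splitting runs
(`phi = 4`) and 0.01 for two-axis pools (`phi = 100`).

A structural consequence worth naming: under a *constant* climate `c` the
number of niches containing `c` is maximal at the domain midpoint — a
mid-domain effect in niche space, not geographic space.  This is what makes
richness peak where the climate sits near the middle of the tolerated
range, and it is property-tested for every standard axis spec.

## Colonization and richness

A pool member is present in cell `c`, month `m` iff the cell's value on
every climatic axis in month `m` lies inside the member's interval on that
axis (both axes must be satisfied *in the same month* for land).  From the
12 monthly presence sets we compute monthly richness `phi_m`, annual
richness `D = mean_m(phi_m)`, union richness `Phi` (present in ≥ 1 month)
and the monthly stability index

    psi10 = Σ_m phi_m / (12 · Phi)  ∈ (0, 1].

Presence is evaluated per month by default ("per_month"); a strict
"all_months" residency policy (the member must tolerate all 12 months) is
available for sensitivity analysis.  Per-month is the default because a
strict residency rule forces `psi10 = 1` everywhere, which contradicts the
wide range of zone stabilities the model is meant to produce.  Note the
published per-zone tables print the stability on a ×100 scale; this package
keeps the (0, 1] fraction.

Counting is exact but never loops over (niche, cell, month) triples:

* single-axis monthly counts use sorted-endpoint binary search
  (`#[x ≤ v] − #[y < v]`), valid for arbitrary interval subsets;
* a full two-axis pool factorizes, `phi_m = count_t(m) · count_p(m)`, which
  is what makes the 94-million-niche land mapping run in milliseconds;
* explicit pair subsamples are evaluated in vectorized chunks;
* the strict all-months policy factorizes across axes because conjunction
  distributes over "for all months" (`x ≤ min_m v` and `y ≥ max_m v`).

The union count has no product shortcut for full two-axis pools, so it is
chunk-enumerated and skipped automatically (under `compute_union='auto'`)
when the product pool exceeds 2×10⁶ members; the mapping analyses only need
`D`.  A naive triple-loop oracle lives in the test suite and the vectorized
paths are required to match it exactly on hundreds of random small cases.

For the benthic zone that requires light, richness is weighted by a
beta-shaped response to seabed irradiance `e` (E m⁻² yr⁻¹):

    w = v · ((e_max − e)/(e_max − e_opt)) · ((e − e_min)/(e_opt − e_min))^((e_opt − e_min)/(e_max − e_opt))

with defaults `v = 1, e_max = 70, e_opt = 20, e_min = 0`; `w(e_opt) = 1`,
`w = 0` at both ends, inputs clipped to `[e_min, e_max]`.

## Allopatric pseudo-species

Identical climatic tolerances in disjoint regions are occupied by different
species (Buffon's Law).  Per niche, the suitability mask (≥ 1 tolerated
month by default) is split into connected components; each component is one
pseudo-species with its cell count and range area.  Defaults: rook
(4-neighbour) connectivity — "separated by at least one cell" reads as
excluding diagonal contact — longitude wrap across the date line (oceans
are zonally continuous), no adjacency across the poles.  Whether patches
connected in some months but not others are one species or two is genuinely
ambiguous; it is exposed as the same per_month/all_months policy switch
rather than guessed.  Range splitting is intended for the coarse (2°) grid;
the model layer refuses it below 1° where it was never calibrated and where
per-niche labeling cost would dominate.  Labeling is implemented with
`scipy.ndimage.label` plus a union-find merge across the longitude seam,
and is tested against an independent flood-fill oracle, including cyclic
shift invariance.

## Summary metrics and scaling

Per zone: `psi1` (sampled pool size), `psi2` (niches realized by ≥ 1
species), `psi3 = 100·psi2/psi1`, `psi4` (mean species per realized niche),
`psi5 = psi2·psi4·phi` (total pseudo-species), `psi6–psi8`
(median/quartiles of species range areas, linear interpolation between
order statistics), `psi9 = 100·psi6/zone_area`, and `psi10` (unweighted
zone mean of the cellwise stability; an area-weighted variant is a config
option).  `psi5` deliberately multiplies the *realized* niche count: the
published per-zone rows (e.g. 24,112 × 13.17 × 4 ≈ 1.27×10⁶) are consistent
only with `psi2`, so the variant that multiplies the full pool size is
treated as a misprint.

Range areas sum per-cell areas, each cell area being the product of the
great-circle spans between midpoints of opposite cell edges on a sphere of
radius 6,377.221 km (the same radius as the distance formula, so distances
and areas are mutually consistent; a 10°-resolution globe sums to the
sphere area within 2%).

Planetary scaling sums the terrestrial total and the five marine zone
totals (nerito-pelagic, holo-pelagic, nerito-benthic, shelf-edge, deep
seabed) and divides by a reference count — 1,427,256 catalogued
(1,233,500 terrestrial + 193,756 marine) or 10,950,000 estimated eukaryote
species.  The scaled realm totals sum to the reference *exactly* in
floating point: the marine share is the complement of the terrestrial one,
stabilized by a double subtraction.

## Gradients and validation

The LBG of a richness map is the per-latitude median over longitudes,
reported only where at least five longitudes contribute.  The longitude-
resolved view min-max standardizes richness globally (once, not per
latitude) and histograms each latitude into 0.05-wide bins on [0, 1],
with a closed top bin, rows expressed as percentages.

Validation uses the Pearson correlation over jointly valid cells.  Because
gridded richness is strongly spatially autocorrelated, we also report `n*`:
the smallest sample size (≥ 3) at which the observed `r` would remain
significant in a two-sided t test at p = .05, found by bisection on the
monotone `t − t_crit` margin.  This is a deterministic, documented
effective-sample-size diagnostic — a stand-in for dof-recalculation schemes
whose details vary across the literature — so published `n*` values from
other implementations are not reproduction targets.

## The synthetic world

The generator emulates only the structure the analysis needs:

* SST: annual mean `sst_pole + (sst_eq − sst_pole)·cos²(lat)` (defaults
  −1.8 and 28 °C), plus a seasonal term `seasonal_amp_pole·|sin(lat)|`
  (default 8 °C) antiphased between hemispheres and vanishing at the
  equator, floored at −1.8 °C (frozen seawater).  Land temperature uses the
  same profile with the seasonal term amplified by a continentality factor
  (default 2).
* Precipitation: a Gaussian equatorial rain belt (peak 280 mm/month,
  width 9°) whose center migrates ±8° seasonally, a midlatitude wet band,
  and dry belts emerging near ±25° — enough to give the terrestrial LBG its
  equatorial peak and the subtropical water limitation.
* A meridional supercontinent (default 30% of longitudes) so the
  terrestrial gradient exists at every latitude.  No realistic coastlines.
* Bathymetry deepening monotonically away from the coast: shelf
  (< 200 m, default 2 cells), slope to 2,000 m, abyss capped at 4,500 m.
* Seabed temperature relaxes to a stable 2 °C with an e-folding depth of
  300 m; seabed light decays as `exp(−0.025·depth)` from a
  `36·cos(lat)` surface value, clipped to the observed 0–33.43 E m⁻² yr⁻¹
  range and zeroed below the 200 m photic cutoff.
* Noise: per-variable seeded Gaussian *spatial* fields (defaults 0.3 °C
  SST, 0.5 °C land, 8 mm precipitation) added identically to all 12
  months, so switching seasonal forcing off (`without_seasonality()`)
  yields exactly month-constant fields and `psi10 = 1` bitwise.

Everything is reproducible bitwise for a fixed seed.  What the synthetic
world does *not* contain: real coastlines and ocean basins, zonal asymmetry
of climate, interannual variability, orography, and observational error
structure.  Tests passing on it therefore demonstrate the correctness and
the qualitative behaviour of the machinery (equatorial land peak,
subtropical marine peaks with an equatorial dip, richer land than sea when
the precipitation axis is added), not quantitative agreement with real
biodiversity maps, which requires the user to supply real gridded inputs.

## Numerical and design choices

* Niche arithmetic: exact rationals; enumeration order (amplitude
  ascending, start ascending) gives stable ids and reproducible sampling.
* Subsample size is `round(R·f)` with half-up rounding (25% of the thermal
  pool is 25,369 members).
* Depth-band ties go to the shallower band (a "0–200 m" band reads as an
  inclusive upper bound).
* Longitudes live in [−180, 180), cell-center registered; regridding is
  bilinear with NaN poisoning, so any target cell whose stencil touches an
  invalid source cell becomes invalid, and no imputation ever happens.
* Cells invalid in any participating grid are excluded from the whole
  simulation of that zone.
* Degenerate inputs raise typed errors (`ConfigurationError`,
  `DegenerateInputError`, `InsufficientDataError`, ...) rather than
  returning NaN silently; an all-land bathymetry yields empty marine masks
  with a warning.

## Problem sizes

The built-in analyses run at 2° resolution (90×180 cells) with the 25%
thermal sample, where the mapping stages complete in seconds thanks to the
binary-search/product counting, and at 6° for the end-to-end tests that
exercise range splitting; these sizes were chosen as the smallest at which
the qualitative gradient contrasts are stable.  Range splitting over very
large two-axis samples (the 1% sample of the 94-million pool is ~943,000
niches) is supported by the same code path but is a long batch computation
by nature; the packaged runs demonstrate it at reduced pool fractions.

## Known limitations

* The model is an equilibrium occupancy null model: no dispersal kinetics,
  no biotic interactions, no local stochastic absence, no paleoclimate.
* `n*` is not a semivariogram/Moran's-I autocorrelation correction and is
  not meant to reproduce published effective-dof values.
* GeoTIFF ingestion of real climatology layers is not implemented; NetCDF
  (classic format via the scipy backend) and CSV are the supported
  dialects.
* The per-species range area is a sum of member cell areas; convex-span
  alternatives would give larger values for fragmented ranges.
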