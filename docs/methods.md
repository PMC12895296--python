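# Methods

## Scope and model

swampflux estimates how the extent, water-table levels and greenhouse-gas
balance of permanently inundated tropical swamp forest change over a
multi-year satellite record. The underlying model is deliberately simple
and layered:

* **Inundation** is a binary per-pixel, per-year state inferred from
  dual-polarisation L-band backscatter. Flooded forest is brighter in HH
  than terra-firme forest because of double-bounce scattering off the water
  surface and trunks; the classifier additionally uses HV, the HV−HH dB
  difference and HAND (flooding potential).
* **Water-table level (WTL)** is reconstructed by inverting HAND: standing
  water depth is the gap between a pixel's HAND and a robust annual maximum
  flood level, and below-ground depth is the gap to a robust minimum over
  the non-flooded part of the maximum flood extent. This assumes a locally
  flat water surface and that HAND orders pixels hydrologically — no
  groundwater flow, soil physics or sub-annual dynamics.
* **Emissions** are area-weighted sums of per-WTL-class net flux densities.
  Fluxes are net (sinks negative); CO₂-equivalents are the weighted sums
  CO₂ + 34·CH₄ + 298·N₂O (100-yr horizon) and CO₂ + 82.5·CH₄ + 273·N₂O
  (20-yr). Plant-mediated transport, substrate supply and microbial
  dynamics are not modelled; they are assumed to be absorbed into the
  per-class flux intervals.
* **Trends** are ordinary least squares on annual series, with a continuous
  one-breakpoint alternative for records suspected of a regime shift.

## Key parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| calibration factor | −83.0 | dB | L-band PALSAR convention for DN → γ⁰; configurable |
| reference incidence angle | 38.7 | ° | mid-swath reference; first-power cosine-ratio model, exponent configurable |
| speckle kernel | 3×3 mean | — | standard window size; median available (`statistic="median"`) — the choice of statistic is left open by common usage, mean is the default |
| HAND flood-potential cutoff | 20 | m | pixels higher above drainage do not flood |
| train fraction / trees | 0.7 / 500 | — | standard split and forest size for this class of mapping problem |
| flood-depth reference | 90th pct of flooded HAND | — | robust maximum; damps isolated flood patches at high HAND |
| below-ground reference | 10th pct of non-flooded HAND | — | robust minimum within the maximum flood extent |
| below-ground clamp | −5 | cm | a classifier-dry pixel can never enter an inundated class |
| flood-depth clamp | 0 | cm | flooded pixels above the 90th-pct reference get zero depth, never negative |
| WTL classes | ≤−70, −70…−50, −50…−30, −30…−5, −5…40, >40 | cm | standard six-class aggregation for tropical-wetland flux synthesis |
| GWP weights | 34/298 (100 yr), 82.5/273 (20 yr) | — | IPCC-convention global warming potentials |
| flux density unit | t km⁻² yr⁻¹ | — | numerically equal to g m⁻² yr⁻¹; converter provided |

Percentiles use linear interpolation between order statistics. Binning is
lower-exclusive/upper-inclusive, so −70 cm falls in the deepest class and
+40 cm in the shallow inundated class; every domain pixel lands in exactly
one class.

## Numerical and design choices

* **Tie-breaking in classification.** The forest's swamp-vote fraction is
  thresholded strictly above 0.5; an exact tie goes to terra firme, which
  is conservative for mapped swamp area.
* **Split stratification.** The 70/30 split is stratified by class to
  avoid degenerate single-class training sets at small n.
* **Extent uncertainty.** Mapped areas are adjusted with the stratified
  (confusion-matrix) good-practice area estimator; the 95% interval comes
  from within-stratum binomial variances and collapses to zero width for a
  diagonal confusion matrix. The emissions intervals instead propagate only
  the flux-table bounds against point-estimate areas: compounding both
  sources would require a joint error model the inputs do not support, and
  the flux intervals dominate in practice.
* **Change map.** Period "presence" is a strict majority of that period's
  annual maps; the four classes (stable swamp, terra firme, loss, gain)
  partition the analysis domain.
* **Piecewise fits.** The two-segment model is continuous at the
  breakpoint (a linear hinge) with candidates restricted to interior
  observed years and ties resolved to the earliest year. Because the hinge
  nests the straight line for every candidate, its RSS never exceeds the
  single-line RSS. Gap years are simply absent from the design; no
  imputation.
* **Degenerate series.** Exactly-fitted series report a zero-width CI and
  limiting p-values (0 for nonzero slope, 1 for flat); a paired t-test on
  constant nonzero differences reports (±∞, 0).
* **Pixel-wise significance** uses raw p < 0.05 split by slope sign, the
  usual reporting convention for vegetation-index trend maps; an FDR
  adjustment would be a straightforward extension but is not applied by
  default.
* **Seeding.** One run seed fans out to per-stage child seeds via
  `numpy.random.SeedSequence.spawn`, so stages are individually
  reproducible and the whole run is bit-deterministic.

## The synthetic scene

The generator emulates the statistical structure the analysis relies on,
not the physics:

* **Terrain.** Drainage is one or more meandering connected channels; HAND
  is 0.25 m per 8-connected pixel step of channel distance plus smooth
  relief spanning strictly less than one step, making HAND provably
  monotone in channel distance (the property the inversion needs) while
  spreading values almost continuously. Forest covers ~90% of the grid in
  smooth patches.
* **Flood truth.** Bathtub filling: forest pixels with HAND below a
  piecewise-linear annual cutoff (default: drying at −0.04 m yr⁻¹ from
  1.6 m, reversing to +0.08 m yr⁻¹ at 2017, mirroring the
  drying-then-wetting shift seen in basin hydrological records). Label
  noise flips 5% of forest labels per year in spatially correlated patches
  (Gaussian-smoothed field thresholded at the matching quantile;
  σ = 0 recovers independent Bernoulli flips). The correlation matters:
  purely independent flips are erased by the 3×3 speckle filter, leaving
  truth a deterministic function of HAND — which the forest then learns
  outright, so every annual map collapses onto the training year and the
  record carries no inter-annual signal. Patchy variability is also what
  real scenes show.
* **Backscatter.** Class-conditional Gaussians in dB (HH −6/−9, HV
  −12/−13 flooded/dry, SD 1 dB): clearly bimodal, configurable; no
  physical scattering model.
* **EVI.** Stratum baselines 0.45 (swamp) / 0.50 (terra firme) — the
  ordering, not the magnitude, of the lower productivity of permanently
  inundated forest — with per-stratum linear trends (defaults +0.0006 and
  +0.0009 yr⁻¹), Gaussian noise and Bernoulli missingness re-expanded into
  April–June monthly observations for the compositing stage.
* **Flux table.** The real per-class tropical-wetland flux synthesis is an
  external input; the bundled default is synthetic, chosen once so CH₄
  rises and CO₂ falls monotonically with water table, CH₄ peaks above
  40 cm of standing water, and per-class 100-yr CO₂-eq densities decrease
  with wetness. Under these densities the wetting scenario's sign
  structure — CH₄ up, CO₂ and 100-yr CO₂-eq down, the 20-yr horizon
  amplifying methane's share — follows from the accounting.

Because the generator controls the truth, passing tests demonstrate the
correctness of the *machinery* (masking, inversion, binning, accounting,
inference) and the recoverability of imposed effects; they do not validate
radar scattering physics, HAND quality, or flux densities on real scenes.

## Problem sizes

Default runs use a 96×96 grid (≈9,200 pixels) over 14 observation years,
400–1087 ground-truth points, 500 simulation replicates for CI-coverage
checks and 200 for breakpoint recovery. These sizes give stable Monte-Carlo
estimates for every property tested while keeping a full run around a few
seconds; all are configurable upward for denser experiments.

## Known limitations

* Binary, annual inundation only — no seasonally flooded class, no
  sub-annual dynamics.
* Below-ground WTLs exist only inside the maximum observed flood extent,
  so dry-side emissions beyond it are not counted (an underestimate when
  water tables rise near the boundary).
* Emissions CIs ignore extent uncertainty and inter-gas correlation.
* The incidence-angle model and speckle statistic are simple defaults;
  terrain flattening, orthorectification and mosaicking are out of scope.
* Rasters are plain TIFFs without geographic tags; georeferencing must be
  carried externally.
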