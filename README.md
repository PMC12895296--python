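# swampflux

Tools for quantifying changing hydrology and greenhouse-gas emissions of
tropical swamp forests from satellite observables — built around the kind of
analysis applied to the Congo Basin's permanently flooded, peat-forming
forests, and exercised end-to-end on synthetic scenes so every stage is
testable without satellite archives.

The package chains five stages:

1. **SAR preprocessing** — L-band dual-polarisation digital numbers are
   calibrated to gamma-naught (γ⁰ = 10·log₁₀(DN²) + CF, CF = −83 dB by
   default), normalised for incidence angle with the cosine-ratio model,
   speckle-filtered with a mask-aware 3×3 kernel, quality-flag masked, and
   gap-filled from a donor year.
2. **Flood mapping** — forest pixels with Height Above Nearest Drainage
   (HAND) ≤ 20 m form the flood-potential domain. A 500-tree random forest
   (`FloodClassifier`, scikit-learn estimator API) over (HH, HV, HV−HH,
   HAND) is trained on labelled ground-truth points (default *n* = 1087,
   stratified 70/30 split) and applied per year. Annual extents carry
   stratified error-adjusted confidence intervals derived from the held-out
   confusion matrix, and early-vs-late period comparison yields a
   loss/gain change map.
3. **Water-table inversion** — flooded-pixel depth is
   100·(h₉₀ − HAND) cm against the 90th percentile of flooded HAND
   (robust to isolated high-HAND flood patches); below-ground levels inside
   the maximum flood extent are −100·(HAND − h₁₀) cm against the 10th
   percentile of non-flooded HAND, clamped at −5 cm. Levels are binned into
   the six standard classes ≤−70, −70…−50, −50…−30, −30…−5, −5…40, >40 cm.
4. **Flux upscaling** — per-class net flux densities (t km⁻² yr⁻¹) for
   CO₂, CH₄ and N₂O multiply class areas; CO₂-equivalents use
   CO₂-eq = CO₂ + 34·CH₄ + 298·N₂O (100-yr horizon) or weights 82.5 / 273
   (20-yr horizon).
5. **Trend analysis** — OLS slopes with 95% CIs and t-test p-values,
   continuous one-breakpoint piecewise fits (exhaustive interior search,
   minimum RSS), vectorised pixel-wise trend maps, April–May–June
   vegetation-index compositing with an 80% availability filter,
   flood-frequency stratum means and paired t-tests.

A synthetic-scene generator (`swampflux.scene`) produces HAND terrains with
drainage channels, drying-then-wetting flood-truth series, bimodal
double-bounce backscatter, ground-truth points, EVI stacks and a
six-class flux table, all deterministic under a seed.

## Worked example

```bash
swampflux run --seed 3 --out runs/demo
```

runs the full chain on the default synthetic scenario (96×96 grid, 25 m
pixels, 14 observation years 2007–2010 and 2015–2024 around the
acquisition gap, drying until 2017 then wetting) and prints:

```json
{
  "overall_accuracy": 0.9724770642201835,
  "extent_slope_km2_yr": 0.007966302555647153,
  "extent_breakpoint_year": 2017.0,
  "ch4_slope_t_yr2": 0.3301196413849955,
  "co2eq_100yr_slope_t_yr2": -14.167739581615896
}
```

Read: the classifier separates swamp from terra-firme forest with 97%
held-out accuracy on this scene; the piecewise fit places the
drying-to-wetting reversal at 2017; and although flood expansion raises
CH₄ emissions (+0.33 t yr⁻² on this toy domain), the accompanying drop in
CO₂ release from re-wetted peat drives 100-yr CO₂-equivalent emissions
down (−14.2 t yr⁻²). `runs/demo/` holds every intermediate raster (TIFF),
the extent / class-area / emissions CSVs, a `manifest.json` with stage
provenance and the full `report.json`.

The same chain is available stage-by-stage from Python
(`generate_terrain`, `split_and_train`, `water_table_grid`,
`annual_emissions`, `ols_trend`, …), and `swampflux init-config` writes the
default YAML configuration for editing. The default flux table is a
synthetic placeholder; supply your own per-class densities via
`flux_table_csv` for real applications.

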