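"""End-to-end orchestration: simulate -> preprocess -> classify -> water
table -> emissions -> trends, as one reproducible seeded run.

A single :class:`RunConfig` carries every tunable (defaults follow the
standard analysis constants: 20 m HAND cutoff, 70/30 split, 500 trees,
90th/10th percentile references, the 14 observation years around the
2011-2014 acquisition gap). One config seed fans out to per-stage child
seeds through ``numpy.random.SeedSequence`` so any stage can be rerun in
isolation and reproduce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as sfio
from .emissions import FluxTable, GASES, emissions_series
from .flood import (
    change_map,
    classify_year,
    error_adjusted_extent,
    extent_series,
    flood_potential_mask,
    scene_features,
    split_and_train,
)
from .sar import apply_quality_mask, incidence_angle_correction, speckle_filter
from .scene import (
    FloodDynamics,
    SceneParams,
    generate_backscatter,
    generate_evi_stack,
    generate_flood_truth_series,
    generate_flux_table,
    generate_ground_truth,
    generate_terrain,
)
from .trends import (
    amj_composite,
    ols_trend,
    paired_t,
    piecewise_trend,
    pixelwise_trends,
    stratum_means,
)
from .watertable import classify_wtl, max_flood_extent, water_table_grid

DEFAULT_YEARS = tuple(range(2007, 2011)) + tuple(range(2015, 2025))

_STAGES = ("terrain", "dynamics", "scenes", "ground_truth", "train", "evi")


@dataclass
class RunConfig:
    """All pipeline parameters; round-trips losslessly through YAML."""

    seed: int = 0
    years: tuple[int, ...] = DEFAULT_YEARS
    # scene geometry
    n_rows: int = 96
    n_cols: int = 96
    pixel_size_m: float = 25.0
    n_channels: int = 2
    # flood dynamics (drying-then-wetting by default)
    base_cutoff_m: float = 1.6
    cutoff_trend_m_per_year: float = -0.04
    breakpoint_year: int | None = 2017
    post_break_trend_m_per_year: float | None = 0.08
    truth_noise_fraction: float = 0.05
    truth_noise_patch_sigma: float = 1.5
    # backscatter statistics
    hh_mean_flooded_db: float = -6.0
    hh_mean_dry_db: float = -9.0
    hv_mean_flooded_db: float = -12.0
    hv_mean_dry_db: float = -13.0
    noise_sd_db: float = 1.0
    incidence_ref_deg: float = 38.7
    # preprocessing
    speckle_kernel: int = 3
    speckle_statistic: str = "mean"
    bad_flag_values: tuple[int, ...] = ()
    # classification
    hand_threshold_m: float = 20.0
    n_ground_truth: int = 1087
    train_year: int = 2019
    train_fraction: float = 0.7
    n_trees: int = 500
    class_balanced: bool = False
    # water table
    depth_percentile: float = 90.0
    wtl_percentile: float = 10.0
    # flux table (None -> synthetic default)
    flux_table_csv: str | None = None
    # EVI
    evi_swamp_trend: float = 0.0006
    evi_terra_firme_trend: float = 0.0009
    evi_noise_sd: float = 0.01
    evi_missing_fraction: float = 0.1
    evi_availability_threshold: float = 0.8

    def to_yaml(self, path: Path | str) -> None:
        d = dataclasses.asdict(self)
        for key in ("years", "bad_flag_values"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("years", "bad_flag_values"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def stage_seeds(self) -> dict[str, int]:
        """Derive one deterministic child seed per stage (< 2**31)."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(_STAGES, children)
        }


def preprocess_scene(scene, config: RunConfig):
    """Quality mask -> incidence-angle normalisation -> speckle filter.

    Scenes are already in gamma-naught dB, so the digital-number
    calibration stage is skipped for this input dialect.
    """
    scene = apply_quality_mask(scene, set(config.bad_flag_values))
    hh = incidence_angle_correction(scene.hh_db, scene.incidence_deg, config.incidence_ref_deg)
    hv = incidence_angle_correction(scene.hv_db, scene.incidence_deg, config.incidence_ref_deg)
    hh = speckle_filter(hh, config.speckle_kernel, scene.valid_mask, config.speckle_statistic)
    hv = speckle_filter(hv, config.speckle_kernel, scene.valid_mask, config.speckle_statistic)
    return dataclasses.replace(scene, hh_db=hh, hv_db=hv)


def run_pipeline(config: RunConfig, outdir: Path | str) -> dict[str, Any]:
    """Execute the full chain and write artifacts, manifest and report.

    Returns the report dictionary (also written as ``report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest: list[dict[str, str]] = []

    def artifact(name: str, stage: str) -> Path:
        manifest.append({"file": name, "stage": stage})
        return outdir / name

    config.to_yaml(artifact("config.yaml", "config"))

    # --- simulate -----------------------------------------------------
    terrain = generate_terrain(
        config.n_rows, config.n_cols, config.pixel_size_m, config.n_channels,
        seed=seeds["terrain"],
    )
    dynamics = FloodDynamics(
        years=tuple(config.years),
        base_inundation_hand_cutoff_m=config.base_cutoff_m,
        cutoff_trend_m_per_year=config.cutoff_trend_m_per_year,
        breakpoint_year=config.breakpoint_year,
        post_break_trend_m_per_year=config.post_break_trend_m_per_year,
        noise_fraction=config.truth_noise_fraction,
        noise_patch_sigma=config.truth_noise_patch_sigma,
        seed=seeds["dynamics"],
    )
    truth_series = generate_flood_truth_series(terrain, dynamics)
    params = SceneParams(
        hh_mean_flooded_db=config.hh_mean_flooded_db,
        hh_mean_dry_db=config.hh_mean_dry_db,
        hv_mean_flooded_db=config.hv_mean_flooded_db,
        hv_mean_dry_db=config.hv_mean_dry_db,
        noise_sd_db=config.noise_sd_db,
        incidence_ref_deg=config.incidence_ref_deg,
        seed=seeds["scenes"],
    )
    scenes = [
        generate_backscatter(terrain, truth, params, year)
        for truth, year in zip(truth_series, config.years)
    ]
    sfio.write_raster(artifact("hand_m.tif", "simulate"), terrain.hand_m)
    sfio.write_raster(artifact("forest_mask.tif", "simulate"), terrain.forest_mask)

    # --- preprocess ---------------------------------------------------
    scenes = [preprocess_scene(s, config) for s in scenes]

    # --- classify -----------------------------------------------------
    potential = flood_potential_mask(terrain.forest_mask, terrain.hand_m, config.hand_threshold_m)
    year_index = {y: i for i, y in enumerate(config.years)}
    if config.train_year not in year_index:
        raise ValueError(f"train_year {config.train_year} not in years list")
    train_truth = truth_series[year_index[config.train_year]]
    truth_points = generate_ground_truth(
        train_truth, config.n_ground_truth, seed=seeds["ground_truth"]
    )
    sfio.write_points_csv(artifact("ground_truth.csv", "simulate"), truth_points)
    train_scene = scenes[year_index[config.train_year]]
    features = scene_features(train_scene, terrain.hand_m, truth_points.rows, truth_points.cols)
    clf, report_acc = split_and_train(
        features, truth_points,
        train_fraction=config.train_fraction, n_trees=config.n_trees,
        seed=seeds["train"], class_balanced=config.class_balanced,
    )
    maps = [
        classify_year(clf, s, terrain.hand_m, potential, config.pixel_size_m) for s in scenes
    ]
    for m in maps:
        sfio.write_raster(artifact(f"flood_{m.year}.tif", "classify"), m.flooded)
    extents = extent_series(maps)
    adjusted = [error_adjusted_extent(m, report_acc) for m in maps]
    sfio.write_extents_csv(artifact("extents.csv", "classify"), extents)
    sfio.write_extents_csv(artifact("extents_error_adjusted.csv", "classify"), adjusted)
    early = [m for m in maps if m.year <= 2010]
    late = [m for m in maps if m.year >= 2015]
    if early and late:
        sfio.write_raster(artifact("change_map.tif", "classify"),
                          change_map(early, late).astype(np.int16))

    # --- water table --------------------------------------------------
    domain = max_flood_extent(maps)
    wtl_grids = [
        water_table_grid(m, terrain.hand_m, domain,
                         config.depth_percentile, config.wtl_percentile)
        for m in maps
    ]
    areas_by_year = [classify_wtl(g) for g in wtl_grids]
    for g in wtl_grids:
        sfio.write_raster(artifact(f"wtl_{g.year}.tif", "wtl"), g.wtl_cm)
    sfio.write_class_areas_csv(artifact("wtl_class_areas.csv", "wtl"), areas_by_year)

    # --- emissions ----------------------------------------------------
    table = (FluxTable.from_csv(config.flux_table_csv)
             if config.flux_table_csv else generate_flux_table())
    table.to_csv(artifact("flux_table.csv", "emissions"))
    records = emissions_series(areas_by_year, table)
    sfio.write_emissions_csv(artifact("emissions.csv", "emissions"), records)

    # --- trends -------------------------------------------------------
    years = list(config.years)
    report: dict[str, Any] = {
        "seed": config.seed,
        "years": years,
        "observation_gap": sorted(set(range(years[0], years[-1] + 1)) - set(years)),
        "accuracy": {
            "overall": report_acc.overall,
            "user_accuracy": report_acc.user_accuracy,
            "producer_accuracy": report_acc.producer_accuracy,
            "confusion": report_acc.confusion.tolist(),
        },
    }
    areas = [e.area_km2 for e in extents]
    report["extent_trend"] = dataclasses.asdict(ols_trend(years, areas))
    report["extent_piecewise"] = dataclasses.asdict(piecewise_trend(years, areas))
    emis_trends: dict[str, Any] = {}
    for gas in GASES:
        emis_trends[gas] = dataclasses.asdict(
            ols_trend(years, [r.total(gas) for r in records])
        )
    for horizon in ("100yr", "20yr"):
        emis_trends[f"co2eq_{horizon}"] = dataclasses.asdict(
            ols_trend(years, [r.co2eq(horizon) for r in records])
        )
    report["emissions_trends"] = emis_trends

    # --- EVI productivity --------------------------------------------
    evi_rng = np.random.default_rng(seeds["evi"])
    annual_truth_evi, _ = generate_evi_stack(
        terrain, truth_series, years,
        trend_per_year=(config.evi_swamp_trend, config.evi_terra_firme_trend),
        noise_sd=config.evi_noise_sd, missing_fraction=0.0, seed=seeds["evi"],
    )
    # expand to AMJ monthly observations with drop-out, then recomposite
    monthly = {}
    for year, annual in zip(years, annual_truth_evi):
        for month in (4, 5, 6):
            grid = annual + evi_rng.normal(0.0, 0.005, annual.shape)
            drop = evi_rng.random(annual.shape) < config.evi_missing_fraction
            monthly[(year, month)] = np.where(drop, np.nan, grid)
    composites, availability = amj_composite(monthly, config.evi_availability_threshold)
    flood_freq = np.sum(np.stack([m.flooded for m in maps]), axis=0)
    strata = stratum_means(composites, flood_freq, len(maps))
    evi_trends = {
        name: dataclasses.asdict(ols_trend(list(series), list(series.values())))
        for name, series in strata.items()
    }
    report["evi_trends"] = evi_trends
    if "swamp" in strata and "terra_firme" in strata:
        t_stat, p = paired_t(
            [strata["swamp"][y] for y in years], [strata["terra_firme"][y] for y in years]
        )
        report["evi_paired_t"] = {"t": t_stat, "p": p}
    slope_grid, p_grid, summary = pixelwise_trends(
        [composites[y] for y in years], years
    )
    report["evi_pixelwise"] = summary
    sfio.write_raster(artifact("evi_slope.tif", "evi"), slope_grid)
    sfio.write_raster(artifact("evi_p.tif", "evi"), p_grid)
    for name, series in strata.items():
        sfio.write_series_csv(artifact(f"evi_{name}.csv", "evi"), series, "mean_evi")

    with open(artifact("report.json", "report"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"artifacts": manifest}, fh, indent=2)
    return report
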