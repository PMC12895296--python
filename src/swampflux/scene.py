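"""Synthetic Congo-Basin-like scene generation.

Every downstream stage of the pipeline (SAR preprocessing, flood
classification, water-table inversion, flux upscaling, trend analysis) is
exercised against scenes produced here: a HAND terrain with drainage
channels, per-year flood-truth grids following a configurable
drying-then-wetting trajectory, dual-polarisation backscatter with the
double-bounce separation between flooded and *terra firme* forest,
ground-truth point sets, EVI stacks with imposed productivity trends, and a
six-class water-table-level flux table.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .emissions import FluxTable, GASES, WTL_CLASSES
from .flood import GroundTruthSet
from .sar import BackscatterScene

__all__ = [
    "TerrainModel",
    "SceneParams",
    "FloodDynamics",
    "DegenerateSceneError",
    "generate_terrain",
    "generate_flood_truth_series",
    "generate_backscatter",
    "generate_ground_truth",
    "generate_flux_table",
    "generate_evi_stack",
]

# HAND accrues this many metres per (8-connected) pixel step away from the
# nearest channel; relief spans strictly less than one step so HAND ordering
# along any ray from a channel is provably monotone in channel distance,
# while still spreading values almost continuously within each distance band.
HAND_GAIN_M_PER_STEP = 0.25
RELIEF_STEP_FRACTION = 0.95

DEFAULT_N_GROUND_TRUTH = 1087


class DegenerateSceneError(ValueError):
    """A generated scene is unusable (e.g. an all-flooded or all-dry year)."""


@dataclass(frozen=True)
class TerrainModel:
    """Hydrological substrate: HAND grid plus forest and drainage masks.

    HAND (Height Above Nearest Drainage) is zero on every drainage pixel and
    grows with distance from the channel network; it is the terrain metric
    used both to delineate flood-potential forest and to invert water-table
    levels.
    """

    hand_m: np.ndarray
    forest_mask: np.ndarray
    drainage_mask: np.ndarray
    pixel_size_m: float

    def __post_init__(self) -> None:
        if self.hand_m.shape != self.forest_mask.shape or self.hand_m.shape != self.drainage_mask.shape:
            raise ValueError("terrain grids must share one shape")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        if np.any(self.hand_m < 0):
            raise ValueError("hand_m must be non-negative")
        if np.any(self.hand_m[self.drainage_mask] != 0):
            raise ValueError("hand_m must be 0 on drainage pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.hand_m.shape


@dataclass(frozen=True)
class SceneParams:
    """Class-conditional backscatter statistics for scene synthesis.

    Flooded forest sits above dry forest in HH through the double-bounce
    mechanism (canopy-penetrating L-band energy reflecting off standing
    water and then off trunks). Defaults give a clearly bimodal feature
    space; all values are in gamma-naught dB.
    """

    hh_mean_flooded_db: float = -6.0
    hh_mean_dry_db: float = -9.0
    hv_mean_flooded_db: float = -12.0
    hv_mean_dry_db: float = -13.0
    noise_sd_db: float = 1.0
    incidence_ref_deg: float = 38.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_db < 0:
            raise ValueError("noise_sd_db must be non-negative")
        if self.hh_mean_flooded_db <= self.hh_mean_dry_db:
            raise ValueError("flooded HH mean must exceed dry HH mean (double bounce)")


@dataclass(frozen=True)
class FloodDynamics:
    """Piecewise-linear trajectory of the HAND inundation cutoff over years.

    The flood-truth rule is simple bathtub filling: forest pixels with
    ``hand_m <= cutoff(year)`` are flooded. A negative ``cutoff_trend``
    followed by a positive ``post_break_trend`` reproduces the
    drying-then-wetting reversal the hydrological record shows.

    ``noise_fraction`` flips that share of forest labels each year;
    ``noise_patch_sigma`` correlates the flips into patches (0 gives
    independent per-pixel flips), emulating spatially coherent
    inter-annual flood variability that terrain alone does not explain.
    """

    years: tuple[int, ...] = tuple(range(2007, 2011)) + tuple(range(2015, 2025))
    base_inundation_hand_cutoff_m: float = 1.6
    cutoff_trend_m_per_year: float = -0.04
    breakpoint_year: int | None = 2017
    post_break_trend_m_per_year: float | None = 0.08
    noise_fraction: float = 0.0
    noise_patch_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must lie in [0, 1]")

    def cutoff(self, year: int) -> float:
        """HAND cutoff (m) for a given year, piecewise linear at the break."""
        y0 = self.years[0]
        if self.breakpoint_year is None or year <= self.breakpoint_year:
            return self.base_inundation_hand_cutoff_m + self.cutoff_trend_m_per_year * (year - y0)
        at_break = self.base_inundation_hand_cutoff_m + self.cutoff_trend_m_per_year * (
            self.breakpoint_year - y0
        )
        post = self.post_break_trend_m_per_year
        if post is None:
            post = self.cutoff_trend_m_per_year
        return at_break + post * (year - self.breakpoint_year)


def _channel_mask(n_rows: int, n_cols: int, n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """Meandering channels, one sinusoidal path per channel, 4-connected."""
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    cols = np.arange(n_cols)
    for k in range(n_channels):
        centre = (k + 1) * n_rows / (n_channels + 1)
        amplitude = rng.uniform(0.05, 0.15) * n_rows
        wavelength = rng.uniform(0.5, 1.5) * n_cols
        phase = rng.uniform(0, 2 * np.pi)
        rows = np.clip(
            np.round(centre + amplitude * np.sin(2 * np.pi * cols / wavelength + phase)).astype(int),
            0,
            n_rows - 1,
        )
        mask[rows, cols] = True
        # bridge vertical jumps so each channel is a connected curve
        for c in range(1, n_cols):
            r0, r1 = rows[c - 1], rows[c]
            lo, hi = min(r0, r1), max(r0, r1)
            mask[lo:hi + 1, c] = True
    return mask


def _smooth_noise(shape: tuple[int, int], rng: np.random.Generator, sigma: float = 4.0) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to [0, 1]."""
    raw = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros(shape)
    return (raw - lo) / (hi - lo)


def generate_terrain(
    n_rows: int,
    n_cols: int,
    pixel_size_m: float = 25.0,
    n_channels: int = 2,
    seed: int = 0,
) -> TerrainModel:
    """Build a terrain with drainage channels and a HAND surface.

    HAND is a strictly increasing function of the 8-connected (chessboard)
    pixel distance to the nearest channel, plus smooth sub-step relief, so
    the ordering of pixels by HAND agrees with their ordering by channel
    distance. Forest covers most of the grid with smooth non-forest patches.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("grid must be at least 8x8")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if pixel_size_m <= 0:
        raise ValueError("pixel_size_m must be positive")
    rng = np.random.default_rng(seed)
    drainage = _channel_mask(n_rows, n_cols, n_channels, rng)
    # chessboard distance == minimum number of 8-connected steps to a channel
    dist = ndimage.distance_transform_cdt(~drainage, metric="chessboard").astype(float)
    relief = RELIEF_STEP_FRACTION * _smooth_noise((n_rows, n_cols), rng)
    hand = HAND_GAIN_M_PER_STEP * (dist + np.where(dist > 0, relief, 0.0))
    forest = _smooth_noise((n_rows, n_cols), rng) > 0.12
    forest |= drainage  # channels sit inside forested wetland
    return TerrainModel(hand_m=hand, forest_mask=forest, drainage_mask=drainage,
                        pixel_size_m=float(pixel_size_m))


def generate_flood_truth_series(
    terrain: TerrainModel, dynamics: FloodDynamics
) -> list[np.ndarray]:
    """Per-year boolean flood-truth grids from the bathtub cutoff rule.

    Label noise, when requested, flips ``noise_fraction`` of the forest
    labels each year, optionally correlated into patches by thresholding a
    smoothed Gaussian field at the matching quantile
    (``noise_patch_sigma = 0`` recovers independent per-pixel flips).
    Raises :class:`DegenerateSceneError` if any year lacks either a flooded
    or a dry forest pixel.
    """
    rng = np.random.default_rng(dynamics.seed)
    out = []
    forest = terrain.forest_mask
    for year in dynamics.years:
        flooded = forest & (terrain.hand_m <= dynamics.cutoff(year))
        if dynamics.noise_fraction > 0:
            field = rng.standard_normal(flooded.shape)
            if dynamics.noise_patch_sigma > 0:
                field = ndimage.gaussian_filter(field, dynamics.noise_patch_sigma)
            thresh = np.quantile(field[forest], 1.0 - dynamics.noise_fraction)
            flips = (field > thresh) & forest
            flooded = flooded ^ flips
        n_flooded = int(flooded.sum())
        if n_flooded == 0 or n_flooded == int(forest.sum()):
            raise DegenerateSceneError(
                f"year {year}: cutoff {dynamics.cutoff(year):.3f} m leaves "
                f"{n_flooded} flooded of {int(forest.sum())} forest pixels"
            )
        out.append(flooded)
    return out


def generate_backscatter(
    terrain: TerrainModel,
    flood_truth: np.ndarray,
    params: SceneParams,
    year: int,
) -> BackscatterScene:
    """Draw an HH/HV scene around class-conditional means with dB noise."""
    if flood_truth.shape != terrain.shape:
        raise ValueError("flood truth and terrain shapes differ")
    rng = np.random.default_rng((params.seed, year))
    shape = terrain.shape
    hh = np.where(flood_truth, params.hh_mean_flooded_db, params.hh_mean_dry_db)
    hv = np.where(flood_truth, params.hv_mean_flooded_db, params.hv_mean_dry_db)
    if params.noise_sd_db > 0:
        hh = hh + rng.normal(0.0, params.noise_sd_db, shape)
        hv = hv + rng.normal(0.0, params.noise_sd_db, shape)
    incidence = np.full(shape, params.incidence_ref_deg) + rng.normal(0.0, 0.5, shape)
    return BackscatterScene(
        year=year,
        hh_db=hh.astype(float),
        hv_db=hv.astype(float),
        incidence_deg=incidence,
        quality_flags=np.zeros(shape, dtype=int),
        valid_mask=np.ones(shape, dtype=bool),
    )


def generate_ground_truth(
    flood_truth: np.ndarray,
    n_points: int = DEFAULT_N_GROUND_TRUTH,
    seed: int = 0,
) -> GroundTruthSet:
    """Sample labelled survey points whose labels agree with the truth grid.

    The default point count matches the size of the GPS campaign the flood
    classifier is calibrated against (1087 swamp / terra-firme coordinates).
    """
    if n_points < 2:
        raise ValueError("need at least 2 points")
    n_pixels = flood_truth.size
    if n_points > n_pixels:
        raise ValueError(f"n_points={n_points} exceeds available pixels {n_pixels}")
    if not flood_truth.any() or flood_truth.all():
        raise ValueError("both classes must be present in the truth grid")
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_pixels, size=n_points, replace=False)
    rows, cols = np.unravel_index(flat, flood_truth.shape)
    labels = np.where(flood_truth[rows, cols], "swamp", "terra_firme")
    return GroundTruthSet(rows=rows, cols=cols, labels=labels)


# Synthetic per-class flux densities (tonnes per km^2 per year, equivalently
# g m^-2 yr^-1). Placeholder values standing in for a tropical-wetland flux
# synthesis that is an external input in practice: CH4 rises and CO2 falls
# monotonically with the water table, CH4 peaks above 40 cm of standing
# water, and dry peat dominates CO2 (and N2O) release.
_DEFAULT_FLUX_ROWS: list[tuple[str, str, float, float, float]] = []
for _cls, _co2, _ch4, _n2o in [
    ("<=-70cm", 4500.0, -2.0, 0.80),
    ("-70to-50cm", 3000.0, 3.0, 0.60),
    ("-50to-30cm", 1800.0, 8.0, 0.45),
    ("-30to-5cm", 700.0, 20.0, 0.30),
    ("-5to40cm", -300.0, 45.0, 0.15),
    (">40cm", -900.0, 55.0, 0.10),
]:
    for _gas, _mean in [("CO2", _co2), ("CH4", _ch4), ("N2O", _n2o)]:
        _half = 0.5 * abs(_mean) + (50.0 if _gas == "CO2" else 2.0 if _gas == "CH4" else 0.05)
        _DEFAULT_FLUX_ROWS.append((_cls, _gas, _mean, _mean - _half, _mean + _half))


def generate_flux_table() -> FluxTable:
    """Default six-class flux table (synthetic placeholder densities).

    The real per-class tropical-wetland flux synthesis is an external input;
    this table preserves its qualitative structure only and is meant to be
    replaced by a user CSV for real applications.
    """
    df = pd.DataFrame(
        _DEFAULT_FLUX_ROWS, columns=["wtl_class", "gas", "mean", "ci_low", "ci_high"]
    )
    return FluxTable.from_frame(df)


def generate_evi_stack(
    terrain: TerrainModel,
    flood_truth_series: Sequence[np.ndarray],
    years: Sequence[int],
    trend_per_year: float | tuple[float, float] = 0.001,
    noise_sd: float = 0.01,
    missing_fraction: float = 0.0,
    seed: int = 0,
    swamp_baseline: float = 0.45,
    terra_firme_baseline: float = 0.50,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-year EVI grids plus a per-pixel availability fraction.

    Pixel series are ``baseline + trend * (year - year0) + noise`` with the
    baseline interpolated between the terra-firme (never flooded) and swamp
    (always flooded) values by flood frequency; swamp sits below terra firme,
    matching the lower productivity of permanently inundated forest.
    ``trend_per_year`` may be one scalar or a ``(swamp, terra_firme)`` pair.
    Missing observations are dropped to NaN at ``missing_fraction``.
    """
    if not 0.0 <= missing_fraction < 1.0:
        raise ValueError("missing_fraction must lie in [0, 1)")
    if len(flood_truth_series) != len(years):
        raise ValueError("one truth grid per year required")
    rng = np.random.default_rng(seed)
    freq = np.mean(np.stack(flood_truth_series), axis=0)
    baseline = terra_firme_baseline + (swamp_baseline - terra_firme_baseline) * freq
    if isinstance(trend_per_year, tuple):
        swamp_tr, tf_tr = trend_per_year
        trend = tf_tr + (swamp_tr - tf_tr) * freq
    else:
        trend = np.full(terrain.shape, float(trend_per_year))
    y0 = years[0]
    stack = []
    available = np.zeros(terrain.shape)
    for year in years:
        grid = baseline + trend * (year - y0)
        if noise_sd > 0:
            grid = grid + rng.normal(0.0, noise_sd, terrain.shape)
        if missing_fraction > 0:
            drop = rng.random(terrain.shape) < missing_fraction
            grid = np.where(drop, np.nan, grid)
        available += ~np.isnan(grid)
        stack.append(grid)
    return stack, available / len(years)
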