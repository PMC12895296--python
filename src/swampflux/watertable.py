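"""Water-table reconstruction from annual flood maps and HAND.

Flood depth over inundated pixels is the HAND inversion against a robust
per-year maximum (the 90th percentile of flooded-pixel HAND, which damps
isolated flood patches at high HAND). Below-ground water tables over
non-flooded pixels inside the maximum flood extent are referenced to the
10th percentile of non-flooded HAND. Signed levels are in centimetres
(positive above surface) and are binned into the six standard water-table
classes for flux upscaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .emissions import WTL_CLASSES
from .flood import FloodMap

__all__ = [
    "WaterTableGrid",
    "WTLClassAreas",
    "max_flood_extent",
    "water_table_grid",
    "classify_wtl",
    "WTL_BIN_EDGES_CM",
    "BELOW_GROUND_CLAMP_CM",
]

# class edges in cm; bins are lower-exclusive / upper-inclusive with the
# lowest class closed below at -inf: (-inf,-70], (-70,-50], ..., (40, inf)
WTL_BIN_EDGES_CM = (-70.0, -50.0, -30.0, -5.0, 40.0)
# a classifier-dry pixel sits just below the surface at most, so it can
# never fall into an inundated class
BELOW_GROUND_CLAMP_CM = -5.0


@dataclass(frozen=True)
class WaterTableGrid:
    """Signed per-pixel water-table level (cm) for one year.

    Positive values are standing-water depth on flooded pixels; negative
    values are depth below ground on non-flooded pixels inside the maximum
    flood extent. NaN outside the domain.
    """

    year: int
    wtl_cm: np.ndarray
    domain_mask: np.ndarray
    pixel_size_m: float
    reference_max_hand_m: float
    reference_min_hand_m: float


@dataclass(frozen=True)
class WTLClassAreas:
    """Per-class areas (km^2) of the water-table partition for one year."""

    year: int
    area_km2: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.area_km2) != WTL_CLASSES:
            raise ValueError("exactly the six standard WTL classes required")
        if any(v < 0 for v in self.area_km2.values()):
            raise ValueError("areas must be non-negative")

    @property
    def total_km2(self) -> float:
        return float(sum(self.area_km2.values()))


def max_flood_extent(maps: Sequence[FloodMap]) -> np.ndarray:
    """Union of flooded pixels across all years."""
    if not maps:
        raise ValueError("need at least one flood map")
    out = np.zeros(maps[0].flooded.shape, dtype=bool)
    for m in maps:
        if m.flooded.shape != out.shape:
            raise ValueError("all maps must share one grid")
        out |= m.flooded
    return out


def flood_depth_reference(flooded: np.ndarray, hand_m: np.ndarray, pct: float = 90.0) -> float:
    """Robust maximum flood level: percentile of HAND over flooded pixels."""
    if not flooded.any():
        raise ValueError("flood map has no flooded pixels")
    return float(np.percentile(hand_m[flooded], pct))


def water_table_grid(
    flood_map: FloodMap,
    hand_m: np.ndarray,
    domain: np.ndarray,
    depth_percentile: float = 90.0,
    wtl_percentile: float = 10.0,
) -> WaterTableGrid:
    """Signed water-table grid for one year over the maximum flood extent.

    Flooded pixels: ``100 * (h_max - hand)`` cm clamped below at 0, with
    ``h_max`` the ``depth_percentile`` of flooded-pixel HAND. Non-flooded
    domain pixels: ``-100 * (hand - h_min)`` cm clamped above at -5 cm,
    with ``h_min`` the ``wtl_percentile`` of non-flooded-domain HAND.
    Percentiles use linear interpolation between order statistics.
    """
    flooded = flood_map.flooded
    if hand_m.shape != flooded.shape or domain.shape != flooded.shape:
        raise ValueError("HAND, domain and flood map must share one grid")
    h_max = flood_depth_reference(flooded, hand_m, depth_percentile)
    dry = domain & ~flooded
    if not dry.any():
        raise ValueError(f"year {flood_map.year}: no non-flooded pixels in domain")
    h_min = float(np.percentile(hand_m[dry], wtl_percentile))

    wtl = np.full(flooded.shape, np.nan)
    wtl[flooded] = np.maximum(100.0 * (h_max - hand_m[flooded]), 0.0)
    wtl[dry] = np.minimum(-100.0 * (hand_m[dry] - h_min), BELOW_GROUND_CLAMP_CM)
    full_domain = domain | flooded
    return WaterTableGrid(
        year=flood_map.year,
        wtl_cm=wtl,
        domain_mask=full_domain,
        pixel_size_m=flood_map.pixel_size_m,
        reference_max_hand_m=h_max,
        reference_min_hand_m=h_min,
    )


def classify_wtl(grid: WaterTableGrid) -> WTLClassAreas:
    """Bin the water-table grid into the six class areas (km^2).

    Binning is lower-exclusive / upper-inclusive, so a level of exactly
    -70 cm falls in the deepest below-ground class and +40 cm in the
    shallow inundated class.
    """
    values = grid.wtl_cm[grid.domain_mask]
    if np.any(np.isnan(values)):
        raise ValueError("water table undefined on part of the domain")
    # right=True makes bins (edge_{i-1}, edge_i]
    idx = np.digitize(values, WTL_BIN_EDGES_CM, right=True)
    px_area_km2 = grid.pixel_size_m**2 / 1e6
    counts = np.bincount(idx, minlength=len(WTL_CLASSES))
    areas = {cls: float(counts[i] * px_area_km2) for i, cls in enumerate(WTL_CLASSES)}
    return WTLClassAreas(year=grid.year, area_km2=areas)
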