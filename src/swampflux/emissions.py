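"""Greenhouse-gas flux upscaling and CO2-equivalent accounting.

Per-class net flux densities (tonnes km^-2 yr^-1, numerically equal to
g m^-2 yr^-1) are applied to the annual water-table class areas to give
basin totals for CO2, CH4 and N2O, with confidence bounds propagated from
the flux-table intervals. CO2-equivalents use global-warming-potential
weights of 34 (CH4) and 298 (N2O) at the 100-year horizon, and 82.5 / 273
at the 20-year horizon. Fluxes are net: sinks are negative and allowed
everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WTL_CLASSES",
    "GASES",
    "GwpWeights",
    "FluxTable",
    "EmissionsRecord",
    "co2_equivalent",
    "annual_emissions",
    "emissions_series",
    "flux_g_per_m2_to_t_per_km2",
]

# the six standard water-table-level classes, driest to wettest
WTL_CLASSES = ("<=-70cm", "-70to-50cm", "-50to-30cm", "-30to-5cm", "-5to40cm", ">40cm")
GASES = ("CO2", "CH4", "N2O")

_GWP = {"100yr": (34.0, 298.0), "20yr": (82.5, 273.0)}


@dataclass(frozen=True)
class GwpWeights:
    """Global-warming-potential weights for one time horizon."""

    horizon: str
    w_ch4: float
    w_n2o: float

    @classmethod
    def for_horizon(cls, horizon: str) -> "GwpWeights":
        if horizon not in _GWP:
            raise ValueError(f"horizon must be one of {sorted(_GWP)}, got {horizon!r}")
        return cls(horizon, *_GWP[horizon])


def co2_equivalent(co2: float, ch4: float, n2o: float,
                   weights: GwpWeights | str = "100yr") -> float:
    """Weighted CO2-equivalent of a (CO2, CH4, N2O) flux vector.

    ``co2 + w_ch4 * ch4 + w_n2o * n2o``; signed fluxes allowed.
    """
    if isinstance(weights, str):
        weights = GwpWeights.for_horizon(weights)
    return co2 + weights.w_ch4 * ch4 + weights.w_n2o * n2o


def flux_g_per_m2_to_t_per_km2(value: float) -> float:
    """Convert g m^-2 yr^-1 to t km^-2 yr^-1 (the two are numerically equal)."""
    return value * 1.0


@dataclass(frozen=True)
class FluxTable:
    """Per-class, per-gas net flux densities with 95% confidence bounds.

    Densities are in tonnes km^-2 yr^-1. The table is an external input
    loaded from CSV (columns: wtl_class, gas, mean, ci_low, ci_high);
    a synthetic default is available from the scene generator.
    """

    frame: pd.DataFrame = field(repr=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FluxTable":
        required = {"wtl_class", "gas", "mean", "ci_low", "ci_high"}
        if not required.issubset(df.columns):
            raise ValueError(f"flux table needs columns {sorted(required)}")
        classes = set(df["wtl_class"])
        if classes != set(WTL_CLASSES):
            raise ValueError(f"flux table classes {sorted(classes)} != expected {WTL_CLASSES}")
        if set(df["gas"]) != set(GASES):
            raise ValueError("flux table must cover gases CO2, CH4, N2O")
        if len(df) != len(WTL_CLASSES) * len(GASES):
            raise ValueError("flux table must have one row per class and gas")
        if not ((df["ci_low"] <= df["mean"]) & (df["mean"] <= df["ci_high"])).all():
            raise ValueError("require ci_low <= mean <= ci_high in every row")
        return cls(frame=df.reset_index(drop=True))

    @classmethod
    def from_csv(cls, path) -> "FluxTable":
        return cls.from_frame(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def density(self, wtl_class: str, gas: str, which: str = "mean") -> float:
        row = self.frame[(self.frame["wtl_class"] == wtl_class) & (self.frame["gas"] == gas)]
        return float(row[which].iloc[0])

    def densities(self, gas: str, which: str = "mean") -> np.ndarray:
        """Densities for one gas ordered driest to wettest class."""
        return np.array([self.density(c, gas, which) for c in WTL_CLASSES])


@dataclass(frozen=True)
class EmissionsRecord:
    """Annual basin totals per gas (t yr^-1) with CIs and CO2-equivalents."""

    year: int
    totals: dict[str, tuple[float, float, float]]  # gas -> (mean, lo, hi)
    co2eq_100yr: tuple[float, float, float]
    co2eq_20yr: tuple[float, float, float]

    def total(self, gas: str) -> float:
        return self.totals[gas][0]

    def co2eq(self, horizon: str = "100yr") -> float:
        return (self.co2eq_100yr if horizon == "100yr" else self.co2eq_20yr)[0]


def _class_areas(areas) -> tuple[int, np.ndarray]:
    """Accept a WTLClassAreas-like object or a plain class->km^2 mapping."""
    if hasattr(areas, "area_km2") and isinstance(areas.area_km2, Mapping):
        mapping, year = areas.area_km2, areas.year
    elif isinstance(areas, Mapping):
        mapping, year = areas, 0
    else:
        raise TypeError("areas must be WTLClassAreas or a mapping")
    if set(mapping) != set(WTL_CLASSES):
        raise ValueError("areas must cover exactly the six WTL classes")
    return int(year), np.array([mapping[c] for c in WTL_CLASSES], dtype=float)


def annual_emissions(areas, table: FluxTable) -> EmissionsRecord:
    """Basin totals for one year: per gas, ``sum_class area * density``.

    Confidence bounds apply the same area vector to the lower and upper
    flux densities (the flux-table interval, not the extent uncertainty,
    dominates the emissions uncertainty). CO2-equivalents at both horizons
    are aggregated from the per-gas totals.
    """
    year, a = _class_areas(areas)
    totals: dict[str, tuple[float, float, float]] = {}
    for gas in GASES:
        mean = float(a @ table.densities(gas, "mean"))
        lo = float(a @ table.densities(gas, "ci_low"))
        hi = float(a @ table.densities(gas, "ci_high"))
        totals[gas] = (mean, lo, hi)
    eq = {}
    for horizon in ("100yr", "20yr"):
        w = GwpWeights.for_horizon(horizon)
        eq[horizon] = tuple(
            co2_equivalent(totals["CO2"][i], totals["CH4"][i], totals["N2O"][i], w)
            for i in range(3)
        )
    return EmissionsRecord(year=year, totals=totals,
                           co2eq_100yr=eq["100yr"], co2eq_20yr=eq["20yr"])


def emissions_series(areas_by_year: Sequence, table: FluxTable) -> list[EmissionsRecord]:
    """One emissions record per year, both horizons populated."""
    years = [_class_areas(a)[0] for a in areas_by_year]
    if len(set(years)) != len(years):
        raise ValueError("years must be distinct")
    return [annual_emissions(a, table) for a in areas_by_year]
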