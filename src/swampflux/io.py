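"""File I/O: single-band TIFF rasters and CSV tables.

Rasters are written as plain single-band TIFFs (float32 for continuous
grids, uint8 for masks and class maps). Tabular artifacts (extents,
class areas, emissions, point sets) go through pandas CSV with six
significant digits.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .emissions import EmissionsRecord, GASES, WTL_CLASSES
from .flood import ExtentEstimate, FloodMap, GroundTruthSet

FLOAT_FORMAT = "%.6g"


def write_raster(path: Path | str, grid: np.ndarray) -> None:
    grid = np.asarray(grid)
    if grid.dtype == bool:
        grid = grid.astype(np.uint8)
    elif grid.dtype.kind == "f":
        grid = grid.astype(np.float32)
    tifffile.imwrite(str(path), grid)


def read_raster(path: Path | str) -> np.ndarray:
    return tifffile.imread(str(path))


def write_points_csv(path: Path | str, points: GroundTruthSet) -> None:
    pd.DataFrame({"row": points.rows, "col": points.cols, "label": points.labels}).to_csv(
        path, index=False
    )


def read_points_csv(path: Path | str) -> GroundTruthSet:
    df = pd.read_csv(path)
    return GroundTruthSet(
        rows=df["row"].to_numpy(), cols=df["col"].to_numpy(), labels=df["label"].to_numpy()
    )


def write_extents_csv(path: Path | str, extents: Sequence[ExtentEstimate]) -> None:
    pd.DataFrame(
        [
            {"year": e.year, "area_km2": e.area_km2,
             "ci_low_km2": e.ci_low_km2, "ci_high_km2": e.ci_high_km2}
            for e in extents
        ]
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_class_areas_csv(path: Path | str, areas_by_year: Sequence) -> None:
    rows = []
    for a in areas_by_year:
        row = {"year": a.year}
        row.update({c: a.area_km2[c] for c in WTL_CLASSES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_emissions_csv(path: Path | str, records: Sequence[EmissionsRecord]) -> None:
    rows = []
    for r in records:
        row: dict = {"year": r.year}
        for gas in GASES:
            mean, lo, hi = r.totals[gas]
            row[f"{gas}_t_yr"] = mean
            row[f"{gas}_ci_low"] = lo
            row[f"{gas}_ci_high"] = hi
        for horizon, vals in (("100yr", r.co2eq_100yr), ("20yr", r.co2eq_20yr)):
            row[f"co2eq_{horizon}_t_yr"] = vals[0]
            row[f"co2eq_{horizon}_ci_low"] = vals[1]
            row[f"co2eq_{horizon}_ci_high"] = vals[2]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_series_csv(path: Path | str, series: dict[int, float], value_name: str = "value") -> None:
    pd.DataFrame({"year": list(series), value_name: list(series.values())}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )
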