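"""Radiometric preprocessing for L-band SAR backscatter scenes.

Turns raw digital-number imagery into analysis-ready gamma-naught dB grids:
calibration, incidence-angle normalisation, speckle filtering, quality-flag
masking and cross-year gap filling. Every operator is mask-aware — invalid
pixels never contaminate their neighbours and only :func:`fill_gaps` can
turn an invalid pixel valid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "BackscatterScene",
    "dn_to_gamma0",
    "incidence_angle_correction",
    "speckle_filter",
    "apply_quality_mask",
    "fill_gaps",
    "DEFAULT_CALIBRATION_DB",
    "DEFAULT_REFERENCE_INCIDENCE_DEG",
]

# JAXA PALSAR calibration convention: gamma0 = 10 log10(DN^2) - 83 dB.
DEFAULT_CALIBRATION_DB = -83.0
DEFAULT_REFERENCE_INCIDENCE_DEG = 38.7


@dataclass(frozen=True)
class BackscatterScene:
    """One annual dual-polarisation scene in gamma-naught dB."""

    year: int
    hh_db: np.ndarray
    hv_db: np.ndarray
    incidence_deg: np.ndarray
    quality_flags: np.ndarray
    valid_mask: np.ndarray
    filled_from_donor: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {
            self.hh_db.shape, self.hv_db.shape, self.incidence_deg.shape,
            self.quality_flags.shape, self.valid_mask.shape,
        }
        if len(shapes) != 1:
            raise ValueError("all scene grids must share one shape")
        for grid in (self.hh_db, self.hv_db):
            if not np.all(np.isfinite(grid[self.valid_mask])):
                raise ValueError("dB values must be finite wherever valid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.hh_db.shape


def dn_to_gamma0(dn: np.ndarray, calibration_factor_db: float = DEFAULT_CALIBRATION_DB
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Calibrate digital numbers to gamma-naught dB.

    gamma0 = 10 log10(DN^2) + CF. Zero DN has no defined dB value; those
    pixels are returned NaN with ``valid=False`` rather than letting -inf
    propagate downstream.

    Returns ``(gamma0_db, valid_mask)``.
    """
    dn = np.asarray(dn, dtype=float)
    if np.any(dn < 0):
        raise ValueError("digital numbers must be non-negative")
    valid = dn > 0
    out = np.full(dn.shape, np.nan)
    out[valid] = 10.0 * np.log10(dn[valid] ** 2) + calibration_factor_db
    return out, valid


def incidence_angle_correction(
    gamma0_db: np.ndarray,
    incidence_deg: np.ndarray,
    reference_deg: float = DEFAULT_REFERENCE_INCIDENCE_DEG,
    exponent: float = 1.0,
) -> np.ndarray:
    """Normalise gamma-naught to a reference incidence angle.

    Uses the cosine-ratio model
    ``out = in - 10 n log10(cos(theta) / cos(theta_ref))`` with n=1 by
    default; pixels already at the reference angle are unchanged and the
    correction is exactly invertible.
    """
    incidence_deg = np.asarray(incidence_deg, dtype=float)
    finite = np.isfinite(incidence_deg)
    if np.any((incidence_deg[finite] <= 0) | (incidence_deg[finite] >= 90)):
        raise ValueError("incidence angles must lie strictly between 0 and 90 degrees")
    if not 0 < reference_deg < 90:
        raise ValueError("reference angle must lie strictly between 0 and 90 degrees")
    ratio = np.cos(np.radians(incidence_deg)) / np.cos(np.radians(reference_deg))
    return np.asarray(gamma0_db, dtype=float) - 10.0 * exponent * np.log10(ratio)


def speckle_filter(
    grid: np.ndarray,
    kernel: int = 3,
    valid_mask: np.ndarray | None = None,
    statistic: str = "mean",
) -> np.ndarray:
    """Local-window speckle suppression in the dB domain.

    Each valid pixel is replaced by the mean (default) or median of the
    valid pixels in its ``kernel x kernel`` window; invalid pixels are
    excluded from every window and stay NaN in the output.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd positive integer")
    grid = np.asarray(grid, dtype=float)
    if valid_mask is None:
        valid_mask = np.isfinite(grid)
    if kernel == 1:
        return np.where(valid_mask, grid, np.nan)
    pad = kernel // 2
    padded = np.pad(np.where(valid_mask, grid, np.nan), pad, constant_values=np.nan)
    windows = np.lib.stride_tricks.sliding_window_view(padded, (kernel, kernel))
    flat = windows.reshape(grid.shape + (kernel * kernel,))
    with np.errstate(invalid="ignore"):
        if statistic == "mean":
            out = np.nanmean(flat, axis=-1)
        elif statistic == "median":
            out = np.nanmedian(flat, axis=-1)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    return np.where(valid_mask, out, np.nan)


def apply_quality_mask(scene: BackscatterScene, bad_flag_values: set[int]) -> BackscatterScene:
    """Invalidate layover/shadow pixels flagged by the sensor quality layer."""
    bad = np.isin(scene.quality_flags, list(bad_flag_values))
    return replace(scene, valid_mask=scene.valid_mask & ~bad)


def fill_gaps(target: BackscatterScene, donor: BackscatterScene) -> BackscatterScene:
    """Fill invalid target pixels from a donor year's valid pixels.

    Mirrors the treatment of partial mosaic gaps, where a neighbouring
    year's acquisition stands in for missing overpass paths. The provenance
    of filled pixels is recorded on the returned scene.
    """
    if target.shape != donor.shape:
        raise ValueError("target and donor scenes must share one shape")
    if target.year == donor.year:
        raise ValueError("donor year must differ from target year")
    fill = ~target.valid_mask & donor.valid_mask
    hh = np.where(fill, donor.hh_db, target.hh_db)
    hv = np.where(fill, donor.hv_db, target.hv_db)
    inc = np.where(fill, donor.incidence_deg, target.incidence_deg)
    return replace(
        target,
        hh_db=hh,
        hv_db=hv,
        incidence_deg=inc,
        valid_mask=target.valid_mask | fill,
        filled_from_donor=fill,
    )
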