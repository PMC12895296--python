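"""Trend statistics for extent, productivity and emissions series.

:class:`LinearTrend` and :class:`PiecewiseTrend` follow the scikit-learn
estimator contract (fit / predict, fitted attributes with trailing
underscores) so they compose with pipelines and model selection; the
module-level :func:`ols_trend` / :func:`piecewise_trend` helpers are thin
wrappers returning frozen result records. Raster-stack utilities cover
pixel-wise trend maps, April-May-June vegetation-index compositing,
flood-frequency stratum means and the paired t-test.

Series with observation gaps (e.g. missing acquisition years) are fitted on
the available years only; no imputation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TrendFit",
    "PiecewiseFit",
    "LinearTrend",
    "PiecewiseTrend",
    "ols_trend",
    "piecewise_trend",
    "pixelwise_trends",
    "amj_composite",
    "stratum_means",
    "paired_t",
]

AMJ_MONTHS = (4, 5, 6)


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not (self.slope_ci_low <= self.slope <= self.slope_ci_high):
            raise ValueError("CI must bracket the slope")


@dataclass(frozen=True)
class PiecewiseFit:
    breakpoint_year: float
    slope_pre: float
    slope_post: float
    intercept: float
    rss: float
    n: int


class LinearTrend(RegressorMixin, BaseEstimator):
    """Ordinary-least-squares trend with a two-sided CI and t-test p-value.

    Inference uses the t distribution with n-2 degrees of freedom. A series
    fitted exactly (zero residual variance) gets a zero-width interval and
    the limiting p-value (0 for a nonzero slope, 1 for a flat series).

    Parameters
    ----------
    confidence : two-sided confidence level for the slope interval.
    """

    def __init__(self, confidence: float = 0.95):
        self.confidence = confidence

    def fit(self, years: Sequence[float], values: Sequence[float]) -> "LinearTrend":
        x = np.asarray(years, dtype=float)
        y = np.asarray(values, dtype=float)
        if x.ndim == 2:  # sklearn-style column vector
            x = x.ravel()
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("years and values must be equal-length 1-d sequences")
        n = len(x)
        if n < 3:
            raise ValueError("need at least 3 observations")
        if len(np.unique(x)) != n:
            raise ValueError("years must be distinct")
        xm, ym = x.mean(), y.mean()
        sxx = float(np.sum((x - xm) ** 2))
        sxy = float(np.sum((x - xm) * (y - ym)))
        slope = sxy / sxx
        intercept = ym - slope * xm
        rss = float(np.sum((y - intercept - slope * x) ** 2))
        dof = n - 2
        scale = max(float(np.sum((y - ym) ** 2)), 1.0)
        if rss <= 1e-12 * scale:  # numerically exact fit
            se = 0.0
            p = 1.0 if slope == 0.0 else 0.0
        else:
            se = math.sqrt(rss / dof / sxx)
            t = slope / se
            p = 2.0 * float(stats.t.sf(abs(t), dof))
        tcrit = float(stats.t.ppf(0.5 + self.confidence / 2.0, dof))
        self.slope_ = slope
        self.intercept_ = intercept
        self.slope_ci_ = (slope - tcrit * se, slope + tcrit * se)
        self.p_value_ = p
        self.rss_ = rss
        self.n_ = n
        return self

    def predict(self, years: Sequence[float]) -> np.ndarray:
        return self.intercept_ + self.slope_ * np.asarray(years, dtype=float)

    def result(self) -> TrendFit:
        return TrendFit(
            slope=self.slope_, intercept=self.intercept_,
            slope_ci_low=self.slope_ci_[0], slope_ci_high=self.slope_ci_[1],
            p_value=self.p_value_, n=self.n_,
        )


class PiecewiseTrend(RegressorMixin, BaseEstimator):
    """Continuous one-breakpoint (two-segment) piecewise linear trend.

    The model is a linear hinge, ``y = b0 + b1 t + b2 max(t - b, 0)``,
    continuous at the breakpoint. The breakpoint is chosen by exhaustive
    search over the interior observed years, minimising residual sum of
    squares; ties go to the earliest year. Because the hinge model nests
    the single line for every candidate, the piecewise RSS never exceeds
    the single-segment RSS.
    """

    def fit(self, years: Sequence[float], values: Sequence[float]) -> "PiecewiseTrend":
        x = np.asarray(years, dtype=float)
        y = np.asarray(values, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("years and values must be equal-length 1-d sequences")
        n = len(x)
        if n < 6:
            raise ValueError("need at least 6 observations for a two-segment fit")
        if len(np.unique(x)) != n:
            raise ValueError("years must be distinct")
        order = np.argsort(x)
        x, y = x[order], y[order]
        best: tuple[float, float, np.ndarray] | None = None
        for b in x[1:-1]:
            design = np.column_stack([np.ones(n), x, np.maximum(x - b, 0.0)])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            rss = float(np.sum((y - design @ coef) ** 2))
            if best is None or rss < best[0] - 1e-12 * max(abs(best[0]), 1.0):
                best = (rss, float(b), coef)
        rss, b, coef = best
        self.breakpoint_year_ = b
        self.intercept_ = float(coef[0])
        self.slope_pre_ = float(coef[1])
        self.slope_post_ = float(coef[1] + coef[2])
        self.rss_ = rss
        self.n_ = n
        return self

    def predict(self, years: Sequence[float]) -> np.ndarray:
        t = np.asarray(years, dtype=float)
        return (self.intercept_ + self.slope_pre_ * t
                + (self.slope_post_ - self.slope_pre_) * np.maximum(t - self.breakpoint_year_, 0.0))

    def result(self) -> PiecewiseFit:
        return PiecewiseFit(
            breakpoint_year=self.breakpoint_year_, slope_pre=self.slope_pre_,
            slope_post=self.slope_post_, intercept=self.intercept_,
            rss=self.rss_, n=self.n_,
        )


def ols_trend(years: Sequence[float], values: Sequence[float],
              confidence: float = 0.95) -> TrendFit:
    """OLS slope with two-sided CI and p-value (thin estimator wrapper)."""
    return LinearTrend(confidence=confidence).fit(years, values).result()


def piecewise_trend(years: Sequence[float], values: Sequence[float]) -> PiecewiseFit:
    """Best continuous two-segment fit (thin estimator wrapper)."""
    return PiecewiseTrend().fit(years, values).result()


def pixelwise_trends(
    stack: Sequence[np.ndarray],
    years: Sequence[float],
    alpha: float = 0.05,
    min_years: int = 3,
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Vectorised per-pixel OLS over a grid stack with missing data.

    NaNs mark missing observations; pixels with fewer than ``min_years``
    valid years are excluded. Returns the slope grid, the two-sided p-value
    grid and summary fractions of valid pixels with p < alpha split by
    slope sign (raw p-values, no multiplicity adjustment, matching the
    usual reporting convention for vegetation-index trend maps).
    """
    y = np.stack(stack).astype(float)
    t = np.asarray(years, dtype=float)[:, None, None]
    if y.shape[0] != len(years):
        raise ValueError("one grid per year required")
    valid = np.isfinite(y)
    n = valid.sum(axis=0)
    ok = n >= min_years
    yv = np.where(valid, y, 0.0)
    tv = np.where(valid, np.broadcast_to(t, y.shape), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = tv.sum(axis=0)
        sy = yv.sum(axis=0)
        sxx = (tv**2).sum(axis=0) - sx**2 / n
        sxy = (tv * yv).sum(axis=0) - sx * sy / n
        syy = (yv**2).sum(axis=0) - sy**2 / n
        slope = sxy / sxx
        rss = np.maximum(syy - slope * sxy, 0.0)
        dof = n - 2
        se2 = rss / np.maximum(dof, 1) / sxx
        tstat = slope / np.sqrt(se2)
    p = np.full(slope.shape, np.nan)
    exact = ok & (rss <= 1e-12 * np.maximum(syy, 1.0))
    with np.errstate(invalid="ignore"):
        finite = ok & ~exact
        p[finite] = 2.0 * stats.t.sf(np.abs(tstat[finite]), dof[finite])
    p[exact & (slope != 0)] = 0.0
    p[exact & (slope == 0)] = 1.0
    slope = np.where(ok, slope, np.nan)
    p = np.where(ok, p, np.nan)
    n_ok = int(ok.sum())
    sig = ok & (p < alpha)
    summary = {
        "n_pixels": float(n_ok),
        "frac_significant_increase": float((sig & (slope > 0)).sum() / n_ok) if n_ok else math.nan,
        "frac_significant_decrease": float((sig & (slope < 0)).sum() / n_ok) if n_ok else math.nan,
    }
    return slope, p, summary


def amj_composite(
    monthly: Mapping[tuple[int, int], np.ndarray],
    availability_threshold: float = 0.8,
) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Annual April-May-June composites with an availability filter.

    ``monthly`` maps ``(year, month)`` to a grid (NaN = missing). Each
    year's composite is the mean of the available AMJ observations; pixels
    observed in less than ``availability_threshold`` of all AMJ slots
    across the time series are masked from every year, keeping the pixel
    set consistent over time.

    Returns ``(composites_by_year, availability_fraction)``.
    """
    amj = {k: v for k, v in monthly.items() if k[1] in AMJ_MONTHS}
    if not amj:
        raise ValueError("no April-June observations in the stack")
    years = sorted({y for y, _ in amj})
    shape = next(iter(amj.values())).shape
    n_slots = len(amj)
    avail = np.zeros(shape)
    for grid in amj.values():
        if grid.shape != shape:
            raise ValueError("all monthly grids must share one shape")
        avail += np.isfinite(grid)
    avail /= n_slots
    keep = avail >= availability_threshold
    composites = {}
    for year in years:
        grids = np.stack([g for (y, _), g in amj.items() if y == year])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            comp = np.nanmean(grids, axis=0)
        composites[year] = np.where(keep, comp, np.nan)
    return composites, avail


def stratum_means(
    evi_annual: Mapping[int, np.ndarray],
    flood_frequency: np.ndarray,
    n_maps: int,
) -> dict[str, dict[int, float]]:
    """Mean EVI per year for all forest, always-flooded and never-flooded strata.

    Swamp is the always-flooded stratum (frequency n_maps / n_maps), terra
    firme never flooded (0 / n_maps); intermediate-frequency pixels count
    only toward "all". Empty strata are omitted with a warning.
    """
    strata = {
        "all": np.ones(flood_frequency.shape, dtype=bool),
        "swamp": flood_frequency == n_maps,
        "terra_firme": flood_frequency == 0,
    }
    out: dict[str, dict[int, float]] = {}
    for name, mask in strata.items():
        if not mask.any():
            warnings.warn(f"stratum {name!r} is empty; series omitted")
            continue
        series = {}
        for year, grid in evi_annual.items():
            vals = grid[mask]
            vals = vals[np.isfinite(vals)]
            series[year] = float(vals.mean()) if len(vals) else math.nan
        out[name] = series
    return out


def paired_t(series_a: Sequence[float], series_b: Sequence[float],
             alternative: str = "two-sided") -> tuple[float, float]:
    """Classic paired t-test on per-year differences a - b.

    Degenerate cases are reported as limits: constant nonzero differences
    give ``(±inf, 0)``, identically zero differences give ``(0, 1)``.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be equal-length 1-d sequences")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return math.copysign(math.inf, d.mean()), 0.0
    res = stats.ttest_rel(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
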