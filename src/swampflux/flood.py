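"""Flood-potential delineation, swamp/terra-firme classification and extents.

The classifier follows the scikit-learn estimator contract so it can be
dropped into pipelines and model selection: :class:`FloodClassifier` wraps a
random forest over the four-feature space (HH, HV, HV-HH polarisation
difference in dB, HAND) with a deterministic tie-break. Around it sit the
raster-level operations: masking to flood-potential forest, per-year
classification, extent series, the stratified error-adjusted area estimator
and the loss/gain change map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .sar import BackscatterScene

__all__ = [
    "GroundTruthSet",
    "FloodMap",
    "AccuracyReport",
    "ExtentEstimate",
    "FloodClassifier",
    "flood_potential_mask",
    "scene_features",
    "split_and_train",
    "classify_year",
    "extent_series",
    "error_adjusted_extent",
    "change_map",
    "CHANGE_TERRA_FIRME",
    "CHANGE_STABLE_SWAMP",
    "CHANGE_LOSS",
    "CHANGE_GAIN",
]

SWAMP = "swamp"
TERRA_FIRME = "terra_firme"

CHANGE_TERRA_FIRME = 0
CHANGE_STABLE_SWAMP = 1
CHANGE_LOSS = 2
CHANGE_GAIN = 3


@dataclass(frozen=True)
class GroundTruthSet:
    """Labelled survey points (pixel coordinates) for the two forest classes."""

    rows: np.ndarray
    cols: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.rows) == len(self.cols) == len(self.labels)):
            raise ValueError("rows, cols and labels must have equal length")
        bad = set(np.unique(self.labels)) - {SWAMP, TERRA_FIRME}
        if bad:
            raise ValueError(f"unknown labels: {bad}")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class FloodMap:
    """Per-year binary inundation map restricted to the analysis domain."""

    year: int
    flooded: np.ndarray
    analysis_mask: np.ndarray
    pixel_size_m: float

    def __post_init__(self) -> None:
        if self.flooded.shape != self.analysis_mask.shape:
            raise ValueError("flooded and analysis_mask must share one shape")
        if np.any(self.flooded & ~self.analysis_mask):
            raise ValueError("flooded pixels must lie inside the analysis mask")

    @property
    def area_km2(self) -> float:
        return float(self.flooded.sum()) * self.pixel_size_m**2 / 1e6


@dataclass(frozen=True)
class AccuracyReport:
    """Held-out confusion matrix and derived accuracies.

    ``confusion[i, j]`` counts points mapped as class i whose reference
    label is class j, with classes ordered ``(swamp, terra_firme)``.
    User accuracy is the complement of commission error (row-wise),
    producer accuracy of omission error (column-wise).
    """

    confusion: np.ndarray

    @property
    def classes(self) -> tuple[str, str]:
        return (SWAMP, TERRA_FIRME)

    @property
    def overall(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    @property
    def user_accuracy(self) -> dict[str, float]:
        rows = self.confusion.sum(axis=1)
        return {c: float(self.confusion[i, i] / rows[i]) for i, c in enumerate(self.classes)}

    @property
    def producer_accuracy(self) -> dict[str, float]:
        cols = self.confusion.sum(axis=0)
        return {c: float(self.confusion[i, i] / cols[i]) for i, c in enumerate(self.classes)}


@dataclass(frozen=True)
class ExtentEstimate:
    year: int
    area_km2: float
    ci_low_km2: float
    ci_high_km2: float

    def __post_init__(self) -> None:
        if not (self.ci_low_km2 <= self.area_km2 + 1e-9 and
                self.area_km2 <= self.ci_high_km2 + 1e-9):
            raise ValueError("CI must bracket the area estimate")


def flood_potential_mask(
    forest_mask: np.ndarray, hand_m: np.ndarray, hand_threshold_m: float = 20.0
) -> np.ndarray:
    """Forest pixels low enough above drainage to flood.

    High ground — HAND strictly greater than the threshold (20 m by
    default) — is removed; a pixel exactly at the threshold stays in.
    """
    if forest_mask.shape != hand_m.shape:
        raise ValueError("forest mask and HAND grid must share one shape")
    return forest_mask & (hand_m <= hand_threshold_m)


def scene_features(
    scene: BackscatterScene, hand_m: np.ndarray, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """Feature matrix (HH, HV, HV-HH, HAND) at the given pixel coordinates."""
    hh = scene.hh_db[rows, cols]
    hv = scene.hv_db[rows, cols]
    return np.column_stack([hh, hv, hv - hh, hand_m[rows, cols]])


class FloodClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest swamp vs terra-firme classifier.

    500 trees by default, operating on the four-feature space
    (HH, HV, HV-HH, HAND). Prediction thresholds the forest's swamp vote
    fraction at 0.5 with ties assigned to terra firme, which is conservative
    for mapped swamp area.

    Parameters
    ----------
    n_trees : number of trees in the forest.
    seed : random state for bootstrap and feature sampling.
    class_balanced : if True, bootstrap with class-balanced sample weights
        rather than raw prevalence.
    """

    def __init__(self, n_trees: int = 500, seed: int = 0, class_balanced: bool = False):
        self.n_trees = n_trees
        self.seed = seed
        self.class_balanced = class_balanced

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FloodClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            random_state=self.seed,
            class_weight="balanced" if self.class_balanced else None,
        )
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        swamp_idx = int(np.where(self.classes_ == SWAMP)[0][0])
        # strict > 0.5: an exact tie goes to terra firme
        return np.where(proba[:, swamp_idx] > 0.5, SWAMP, TERRA_FIRME)


def split_and_train(
    features: np.ndarray,
    truth: GroundTruthSet,
    train_fraction: float = 0.7,
    n_trees: int = 500,
    seed: int = 0,
    class_balanced: bool = False,
) -> tuple[FloodClassifier, AccuracyReport]:
    """Stratified 70/30 split, forest training and held-out accuracy report."""
    labels = truth.labels
    idx = np.arange(len(truth))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=labels, random_state=seed
    )
    for part in (train_idx, test_idx):
        if min(np.sum(labels[part] == c) for c in (SWAMP, TERRA_FIRME)) < 2:
            raise ValueError("each split needs at least 2 points per class")
    clf = FloodClassifier(n_trees=n_trees, seed=seed, class_balanced=class_balanced)
    clf.fit(features[train_idx], labels[train_idx])
    pred = clf.predict(features[test_idx])
    ref = labels[test_idx]
    classes = (SWAMP, TERRA_FIRME)
    confusion = np.array(
        [[np.sum((pred == pc) & (ref == rc)) for rc in classes] for pc in classes]
    )
    return clf, AccuracyReport(confusion=confusion)


def classify_year(
    clf: FloodClassifier,
    scene: BackscatterScene,
    hand_m: np.ndarray,
    potential_mask: np.ndarray,
    pixel_size_m: float,
) -> FloodMap:
    """Apply the trained classifier to one annual scene.

    Only valid pixels inside the flood-potential mask are labelled; invalid
    pixels are excluded from the map (and therefore from any area).
    """
    check_is_fitted(clf, "forest_")
    domain = potential_mask & scene.valid_mask
    flooded = np.zeros(scene.shape, dtype=bool)
    rows, cols = np.nonzero(domain)
    if len(rows):
        pred = clf.predict(scene_features(scene, hand_m, rows, cols))
        flooded[rows, cols] = pred == SWAMP
    return FloodMap(year=scene.year, flooded=flooded, analysis_mask=domain,
                    pixel_size_m=pixel_size_m)


def extent_series(maps: Sequence[FloodMap]) -> list[ExtentEstimate]:
    """Point-estimate mapped areas (pixel count x pixel area) per year."""
    if not maps:
        raise ValueError("need at least one flood map")
    return [
        ExtentEstimate(year=m.year, area_km2=m.area_km2,
                       ci_low_km2=m.area_km2, ci_high_km2=m.area_km2)
        for m in maps
    ]


def error_adjusted_extent(
    flood_map: FloodMap, report: AccuracyReport, z: float = 1.96
) -> ExtentEstimate:
    """Stratified error-adjusted swamp area with a 95% confidence interval.

    Good-practice area estimation from the confusion matrix: mapped-class
    proportions reweight the per-stratum reference proportions, and the
    standard error follows from the within-stratum binomial variances. The
    interval collapses to the mapped area when the confusion matrix is
    diagonal.
    """
    conf = report.confusion.astype(float)
    n_h = conf.sum(axis=1)
    if np.any(n_h <= 0):
        raise ValueError("every mapped stratum needs reference points")
    total_px = float(flood_map.analysis_mask.sum())
    if total_px == 0:
        raise ValueError("empty analysis mask")
    mapped_swamp = float(flood_map.flooded.sum())
    # stratum weights: mapped proportions of (swamp, terra_firme)
    w = np.array([mapped_swamp, total_px - mapped_swamp]) / total_px
    p_ref_swamp = conf[:, 0] / n_h  # per-stratum proportion referenced swamp
    p_swamp = float(np.dot(w, p_ref_swamp))
    var = float(np.sum(w**2 * p_ref_swamp * (1 - p_ref_swamp) / np.maximum(n_h - 1, 1)))
    total_km2 = total_px * flood_map.pixel_size_m**2 / 1e6
    area = p_swamp * total_km2
    half = z * np.sqrt(var) * total_km2
    return ExtentEstimate(year=flood_map.year, area_km2=area,
                          ci_low_km2=area - half, ci_high_km2=area + half)


def _period_presence(maps: Sequence[FloodMap]) -> np.ndarray:
    """Flooded in a strict majority of the period's maps."""
    stack = np.stack([m.flooded for m in maps])
    return stack.sum(axis=0) > len(maps) / 2


def change_map(early_maps: Sequence[FloodMap], late_maps: Sequence[FloodMap]) -> np.ndarray:
    """Loss/gain change classes from early-period vs late-period presence.

    A pixel is "present" in a period when flooded in a strict majority of
    that period's maps. Classes: 0 terra firme (neither), 1 stable swamp
    (both), 2 flood loss (early only), 3 flood gain (late only); -1 outside
    the analysis mask.
    """
    if not early_maps or not late_maps:
        raise ValueError("both periods need at least one map")
    shape = early_maps[0].flooded.shape
    for m in list(early_maps) + list(late_maps):
        if m.flooded.shape != shape:
            raise ValueError("all maps must share one grid")
    early = _period_presence(early_maps)
    late = _period_presence(late_maps)
    out = np.full(shape, CHANGE_TERRA_FIRME, dtype=int)
    out[early & late] = CHANGE_STABLE_SWAMP
    out[early & ~late] = CHANGE_LOSS
    out[~early & late] = CHANGE_GAIN
    mask = np.zeros(shape, dtype=bool)
    for m in list(early_maps) + list(late_maps):
        mask |= m.analysis_mask
    out[~mask] = -1
    return out
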