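"""Threshold calibration and clinical-style evaluation metrics.

The K thresholds governing the detectors are "golden values": the
threshold that maximizes detection accuracy on a labeled calibration set,
found by exhaustive grid search with predictions ``score > K``.  The
metric suite mirrors the clinical report card — accuracy, sensitivity,
specificity, false-positive rate and false-negative rate, each with a 95%
confidence interval — plus per-region IOU summaries for segmentation.

False-positive and false-negative rates are divided by the total count N
(not by condition negatives/positives), the definition under which
accuracy + FP-rate + FN-rate = 100 holds exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import LEVELS


class CalibrationError(ValueError):
    """Score set is degenerate (single class) and cannot be calibrated."""


@dataclass
class CalibrationResult:
    best_threshold: float
    best_accuracy: float  # percent
    thresholds: np.ndarray
    accuracies: np.ndarray  # percent, aligned with thresholds

    def curve(self) -> np.ndarray:
        """(n, 2) array of (threshold, accuracy%) for plotting/export."""
        return np.column_stack([self.thresholds, self.accuracies])


def calibrate_threshold(
    scores, labels, grid
) -> CalibrationResult:
    """Grid-search the accuracy-maximizing decision threshold.

    Predictions are ``score > K`` for each candidate K.  Ties are broken
    toward the smallest K, which favors sensitivity.  Requires at least
    one positive and one negative label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if scores.shape != labels.shape or scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if labels.all() or not labels.any():
        raise CalibrationError("calibration needs both positive and negative labels")
    order = np.argsort(grid, kind="stable")
    grid = grid[order]
    preds = scores[None, :] > grid[:, None]  # (n_grid, n_points)
    acc = 100.0 * (preds == labels[None, :]).mean(axis=1)
    best = int(np.argmax(acc))  # first maximum = smallest K on the sorted grid
    return CalibrationResult(
        best_threshold=float(grid[best]),
        best_accuracy=float(acc[best]),
        thresholds=grid,
        accuracies=acc,
    )


def _wilson_interval(k: int, n: int, ci_level: float) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, in percent."""
    if n == 0:
        return (math.nan, math.nan)
    from scipy.stats import norm

    z = float(norm.ppf(0.5 + ci_level / 2.0))
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return (100.0 * max(0.0, center - half), 100.0 * min(1.0, center + half))


def _normal_interval(k: int, n: int, ci_level: float) -> tuple[float, float]:
    if n == 0:
        return (math.nan, math.nan)
    from scipy.stats import norm

    z = float(norm.ppf(0.5 + ci_level / 2.0))
    p = k / n
    half = z * math.sqrt(p * (1 - p) / n)
    return (100.0 * max(0.0, p - half), 100.0 * min(1.0, p + half))


@dataclass
class MetricsTable:
    """Confusion counts, rate metrics (percent) and their confidence
    intervals.  Metrics with a zero denominator are ``nan`` (reported as
    not available), never silently 0."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    fp_rate: float
    fn_rate: float
    ci: dict[str, tuple[float, float]]
    ci_level: float = 0.95

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        def clean(v: float):
            return None if isinstance(v, float) and math.isnan(v) else v

        return {
            "counts": {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn},
            "accuracy": clean(self.accuracy),
            "sensitivity": clean(self.sensitivity),
            "specificity": clean(self.specificity),
            "fp_rate": clean(self.fp_rate),
            "fn_rate": clean(self.fn_rate),
            "ci_level": self.ci_level,
            "ci": {k: [clean(v[0]), clean(v[1])] for k, v in self.ci.items()},
        }

    def format_table(self) -> str:
        rows = [
            ("Accuracy", self.accuracy, self.ci["accuracy"]),
            ("Sensitivity", self.sensitivity, self.ci["sensitivity"]),
            ("Specificity", self.specificity, self.ci["specificity"]),
            ("False positive", self.fp_rate, self.ci["fp_rate"]),
            ("False negative", self.fn_rate, self.ci["fn_rate"]),
        ]
        lines = [f"{'Metric':<16}{'Value':>8}   {int(self.ci_level*100)}% CI"]
        for name, val, (lo, hi) in rows:
            if math.isnan(val):
                lines.append(f"{name:<16}{'n/a':>8}")
            else:
                lines.append(f"{name:<16}{val:7.2f}%   ({lo:.0f}%-{hi:.0f}%)")
        return "\n".join(lines)


def compute_metrics(predictions, truth, ci_level: float = 0.95,
                    ci_method: str = "wilson") -> MetricsTable:
    """Confusion-matrix metrics with confidence intervals.

    accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), fp_rate = FP/N, fn_rate = FN/N, all x100.
    Intervals are Wilson score by default ("normal" for the plain
    normal approximation).
    """
    pred = np.asarray(predictions, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if pred.shape != true.shape or pred.ndim != 1 or pred.size == 0:
        raise ValueError("predictions and truth must be equal-length, non-empty")
    tp = int(np.sum(pred & true))
    tn = int(np.sum(~pred & ~true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    n = pred.size
    interval = _wilson_interval if ci_method == "wilson" else _normal_interval

    def ratio(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else math.nan

    ci = {
        "accuracy": interval(tp + tn, n, ci_level),
        "sensitivity": interval(tp, tp + fn, ci_level),
        "specificity": interval(tn, tn + fp, ci_level),
        "fp_rate": interval(fp, n, ci_level),
        "fn_rate": interval(fn, n, ci_level),
    }
    return MetricsTable(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=ratio(tp + tn, n),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        fp_rate=ratio(fp, n),
        fn_rate=ratio(fn, n),
        ci=ci,
        ci_level=ci_level,
    )


@dataclass
class SegScore:
    """Per-region IOU plus the mean, with the 0.5 detection rule."""

    per_region: dict[str, float]
    miou: float
    detected: dict[str, bool]  # IOU > 0.5


REGION_NAMES: dict[int, str] = {i + 1: lv for i, lv in enumerate(LEVELS)}
REGION_NAMES[6] = "sacrum"


def compute_miou(pred_mask, truth_mask,
                 region_labels=tuple(REGION_NAMES)) -> SegScore:
    """Per-region intersection-over-union between two label masks.

    IOU is |pred ∩ truth| / |pred ∪ truth| per region label; the mean is
    taken over regions present in either mask; a region counts detected
    when its IOU exceeds 0.5.
    """
    pred = np.asarray(pred_mask)
    truth = np.asarray(truth_mask)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth masks differ in shape")
    per_region: dict[str, float] = {}
    detected: dict[str, bool] = {}
    for label in region_labels:
        name = REGION_NAMES.get(label, str(label))
        p = pred == label
        t = truth == label
        union = int(np.sum(p | t))
        if union == 0:
            continue
        iou = float(np.sum(p & t)) / union
        per_region[name] = iou
        detected[name] = iou > 0.5
    miou = float(np.mean(list(per_region.values()))) if per_region else math.nan
    return SegScore(per_region=per_region, miou=miou, detected=detected)
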