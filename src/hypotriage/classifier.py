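"""Quadrature overlap metric and the single-threshold eligibility classifier.

The classifier predicts *ineligible* whenever the chosen feature value is
greater than or equal to a scalar threshold; the threshold is learned by
exhaustive search over candidate cutoffs, maximizing training accuracy.
Sensitivity and specificity follow the triage convention: the positive
class is *eligible* (true positives are eligible patients classified as
eligible; true negatives are ineligible patients classified as ineligible).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FEATURE_NAMES, Cohort
from .errors import DegenerateCohortError

__all__ = [
    "overlap_metric",
    "ThresholdModel",
    "classify",
    "fit_threshold",
    "ConfusionCounts",
    "evaluate",
    "rank_sum_test",
    "compare_groups",
]

ELIGIBLE = "eligible"
INELIGIBLE = "ineligible"


def overlap_metric(f_bw: float, f_rw: float) -> float:
    """Combine the two wall-overlap fractions in quadrature.

    Returns sqrt(f_bw^2 + f_rw^2) — the radial distance of the patient's
    point from the origin of the (f_bw, f_rw) plane.
    """
    for name, value in (("f_bw", f_bw), ("f_rw", f_rw)):
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    return math.hypot(f_bw, f_rw)


@dataclass(frozen=True)
class ThresholdModel:
    """Scalar decision cutoff: predict ineligible iff value >= threshold."""

    threshold: float
    feature_name: str = "metric"
    training_accuracy: float | None = None

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.feature_name not in FEATURE_NAMES:
            raise ValueError(f"feature_name must be one of {FEATURE_NAMES}")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump({"feature": self.feature_name, "threshold": self.threshold}, handle)

    @classmethod
    def from_json(cls, path) -> "ThresholdModel":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        return cls(threshold=float(payload["threshold"]), feature_name=payload["feature"])


def classify(value: float, model: ThresholdModel) -> str:
    """Apply the inclusive threshold rule to one feature value."""
    if not np.isfinite(value):
        raise ValueError(f"feature value must be finite, got {value}")
    return INELIGIBLE if value >= model.threshold else ELIGIBLE


# -- array kernels (shared with cross-validation for speed) ---------------

def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct values plus two sentinels.

    The lower sentinel (0, below every nonnegative feature value) flags the
    whole cohort ineligible; the upper sentinel (max + 1) flags everyone
    eligible.  Together the candidates realize every distinct labelling the
    inclusive >= rule can produce.
    """
    unique = np.unique(values)
    midpoints = (unique[:-1] + unique[1:]) / 2.0
    return np.concatenate(([0.0], midpoints, [unique[-1] + 1.0]))


def _fit_array(values: np.ndarray, eligible: np.ndarray):
    candidates = _candidate_thresholds(values)
    predicted_ineligible = values[None, :] >= candidates[:, None]
    correct = predicted_ineligible == ~eligible[None, :]
    accuracy = correct.mean(axis=1)
    best = int(np.argmax(accuracy))  # ties -> smallest candidate (argmax keeps first)
    return float(candidates[best]), float(accuracy[best])


def _confusion_arrays(values: np.ndarray, eligible: np.ndarray, threshold: float):
    predicted_eligible = values < threshold
    tp = int(np.count_nonzero(predicted_eligible & eligible))
    fn = int(np.count_nonzero(~predicted_eligible & eligible))
    tn = int(np.count_nonzero(~predicted_eligible & ~eligible))
    fp = int(np.count_nonzero(predicted_eligible & ~eligible))
    return tp, fp, tn, fn


def fit_threshold(cohort: Cohort, feature_name: str = "metric") -> ThresholdModel:
    """Learn the accuracy-maximizing cutoff for one feature on a labelled cohort.

    Candidates are midpoints between consecutive distinct sorted feature
    values plus one sentinel below the minimum and one above the maximum;
    among accuracy ties the smallest candidate is returned (conservative:
    flags more patients ineligible, favoring an early planning consult).
    Deterministic for fixed input.
    """
    labelled = cohort.require_both_classes()
    values = labelled.feature_values(feature_name)
    if np.isnan(values).any():
        raise ValueError(f"feature {feature_name!r} has missing values")
    threshold, accuracy = _fit_array(values, labelled.labels())
    return ThresholdModel(threshold=threshold, feature_name=feature_name, training_accuracy=accuracy)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with eligible as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


def evaluate(cohort: Cohort, model: ThresholdModel) -> ConfusionCounts:
    """Apply a fitted threshold to a labelled cohort and count outcomes."""
    labelled = cohort.labelled()
    if len(labelled) == 0:
        raise DegenerateCohortError("cannot evaluate on an empty labelled cohort")
    values = labelled.feature_values(model.feature_name)
    tp, fp, tn, fn = _confusion_arrays(values, labelled.labels(), model.threshold)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# Group comparison (Wilcoxon rank-sum)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # standardized z
    pvalue: float


def rank_sum_test(group_a, group_b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test with mid-ranks for ties.

    The p-value uses the normal approximation with tie-corrected variance
    and a 0.5 continuity correction.  (scipy's ``ranksums`` applies no tie
    correction, hence the explicit formula; ``mannwhitneyu`` serves as the
    cross-check in the test suite.)
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must contain at least one observation")
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([a, b]))
    w = ranks[:n1].sum()
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum() / (n * (n - 1))) if n > 1 else 0.0
    variance = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if variance <= 0:
        return RankSumResult(statistic=0.0, pvalue=1.0)
    diff = w - mean_w
    correction = min(0.5, abs(diff))  # continuity correction toward the mean
    z = (diff - math.copysign(correction, diff)) / math.sqrt(variance) if diff != 0 else 0.0
    pvalue = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return RankSumResult(statistic=float(z), pvalue=float(pvalue))


def compare_groups(cohort: Cohort, feature_names=FEATURE_NAMES) -> pd.DataFrame:
    """Eligible-vs-ineligible rank-sum comparison for each feature.

    Returns one row per feature with group medians, the standardized
    rank-sum statistic and the two-sided p-value — the statistical summary
    accompanying the cohort feature distributions.
    """
    labelled = cohort.require_both_classes()
    labels = labelled.labels()
    rows = []
    for feature_name in feature_names:
        values = labelled.feature_values(feature_name)
        keep = ~np.isnan(values)
        eligible_values = values[keep & labels]
        ineligible_values = values[keep & ~labels]
        if eligible_values.size == 0 or ineligible_values.size == 0:
            continue
        result = rank_sum_test(eligible_values, ineligible_values)
        rows.append(
            {
                "feature": feature_name,
                "median_eligible": float(np.median(eligible_values)),
                "median_ineligible": float(np.median(ineligible_values)),
                "z": result.statistic,
                "p_value": result.pvalue,
            }
        )
    return pd.DataFrame(rows)
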