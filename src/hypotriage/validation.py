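"""Repeated stratified two-fold cross-validation of the threshold classifier.

Each repetition randomly halves the eligible and ineligible patients
separately into two folds (so both folds keep the cohort's class mix),
fits the threshold on one fold, evaluates on the other, then swaps roles.
Means and standard deviations of sensitivity, specificity, accuracy and
the fitted threshold are aggregated over all 2 x n_repetitions fold
evaluations.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import _confusion_arrays, _fit_array
from .cohort import Cohort
from .errors import StratificationError

__all__ = ["CVConfig", "CVReport", "stratified_split", "cross_validate", "cv_summary_table"]

_METRIC_COLUMNS = ("sensitivity_pct", "specificity_pct", "accuracy_pct", "threshold")


@dataclass(frozen=True)
class CVConfig:
    """Settings for repeated two-fold cross-validation.

    ``n_repetitions`` defaults to 1000 independent random splits; the fold
    count is fixed at two (both folds serve as training and testing within
    each repetition).
    """

    n_repetitions: int = 1000
    seed: int = 0
    feature_name: str = "metric"
    n_folds: int = 2

    def __post_init__(self) -> None:
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.n_folds != 2:
            raise ValueError("only two-fold cross-validation is supported")


@dataclass
class CVReport:
    """Aggregated cross-validation outcome plus per-fold audit records."""

    feature_name: str
    n_repetitions: int
    seed: int
    means: dict
    sds: dict
    records: pd.DataFrame = field(repr=False)

    @property
    def n_folds_evaluated(self) -> int:
        return len(self.records)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"quantity": name, "mean": self.means[name], "sd": self.sds[name]}
            for name in _METRIC_COLUMNS
        ]
        return pd.DataFrame(rows).set_index("quantity")

    def to_json(self, path) -> None:
        payload = {
            "feature": self.feature_name,
            "n_repetitions": self.n_repetitions,
            "seed": self.seed,
            "n_folds_evaluated": self.n_folds_evaluated,
            "means": self.means,
            "sds": self.sds,
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2)


def _split_class_indices(indices: np.ndarray, rng: np.random.Generator):
    """Randomly halve one class; an odd extra member goes to a coin-flipped fold."""
    if indices.size < 2:
        raise StratificationError(
            "each eligibility class needs at least two members for a stratified split"
        )
    shuffled = rng.permutation(indices)
    half = indices.size // 2
    if indices.size % 2 == 1 and rng.integers(2) == 1:
        half += 1
    return shuffled[:half], shuffled[half:]


def _split_indices(eligible: np.ndarray, rng: np.random.Generator):
    all_indices = np.arange(eligible.size)
    a_parts, b_parts = [], []
    for class_mask in (eligible, ~eligible):
        part_a, part_b = _split_class_indices(all_indices[class_mask], rng)
        a_parts.append(part_a)
        b_parts.append(part_b)
    return np.sort(np.concatenate(a_parts)), np.sort(np.concatenate(b_parts))


def stratified_split(cohort: Cohort, rng: np.random.Generator):
    """Randomly partition a labelled cohort into two class-balanced folds."""
    labelled = cohort.require_both_classes()
    fold_a, fold_b = _split_indices(labelled.labels(), rng)
    return labelled.subset(fold_a), labelled.subset(fold_b)


def cross_validate(cohort: Cohort, config: CVConfig) -> CVReport:
    """Run repeated stratified two-fold cross-validation on one feature.

    Per repetition the cohort is split, the threshold fitted on fold A and
    scored on fold B, then the folds swap.  The report aggregates the mean
    and sample standard deviation of sensitivity, specificity and accuracy
    (in percent) and of the fitted threshold over all fold evaluations.
    """
    labelled = cohort.require_both_classes()
    values = labelled.feature_values(config.feature_name)
    if np.isnan(values).any():
        raise ValueError(f"feature {config.feature_name!r} has missing values")
    eligible = labelled.labels()
    rng = np.random.default_rng(config.seed)

    rows = []
    for repetition in range(config.n_repetitions):
        fold_a, fold_b = _split_indices(eligible, rng)
        for fold_id, (train, test) in enumerate(((fold_a, fold_b), (fold_b, fold_a))):
            threshold, _ = _fit_array(values[train], eligible[train])
            tp, fp, tn, fn = _confusion_arrays(values[test], eligible[test], threshold)
            rows.append(
                {
                    "repetition": repetition,
                    "fold": fold_id,
                    "sensitivity_pct": 100.0 * tp / (tp + fn),
                    "specificity_pct": 100.0 * tn / (tn + fp),
                    "accuracy_pct": 100.0 * (tp + tn) / (tp + fp + tn + fn),
                    "threshold": threshold,
                }
            )
    records = pd.DataFrame(rows)
    means = {name: float(records[name].mean()) for name in _METRIC_COLUMNS}
    sds = {
        name: float(records[name].std(ddof=1)) if len(records) > 1 else 0.0
        for name in _METRIC_COLUMNS
    }
    return CVReport(
        feature_name=config.feature_name,
        n_repetitions=config.n_repetitions,
        seed=config.seed,
        means=means,
        sds=sds,
        records=records,
    )


def cv_summary_table(reports) -> pd.DataFrame:
    """Combine per-feature CV reports into a 'mean (sd)' summary table.

    Rows are sensitivity/specificity/accuracy/threshold; one column per
    feature, matching the layout used to report predictive efficacy.
    """
    columns = {}
    for report in reports:
        cells = {}
        for name in _METRIC_COLUMNS:
            digits = 1 if name.endswith("_pct") else 3
            cells[name] = f"{report.means[name]:.{digits}f} ({report.sds[name]:.{digits}f})"
        columns[report.feature_name] = cells
    return pd.DataFrame(columns).loc[list(_METRIC_COLUMNS)]
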