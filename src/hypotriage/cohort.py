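"""Patient records and cohorts of fractional-overlap features.

A patient is summarized by the pair (f_bw, f_rw) — the fractions of the
bladder wall and rectal wall overlapped by the PTV — plus an optional PTV
volume and an optional dosimetric-eligibility label (True = the plan can
meet the accepted dose constraints).  The derived quadrature metric
m = sqrt(f_bw^2 + f_rw^2) is the radial coordinate used throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DegenerateCohortError

__all__ = ["OverlapFeatures", "PatientRecord", "Cohort", "FEATURE_NAMES"]

logger = logging.getLogger(__name__)

#: Feature columns a threshold classifier may operate on.
FEATURE_NAMES = ("metric", "f_bw", "f_rw", "ptv_volume_cc")


@dataclass(frozen=True)
class OverlapFeatures:
    """Per-patient fractional overlaps and their quadrature combination."""

    f_bw: float
    f_rw: float

    def __post_init__(self) -> None:
        for name, value in (("f_bw", self.f_bw), ("f_rw", self.f_rw)):
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")

    @property
    def metric(self) -> float:
        """Quadrature overlap metric sqrt(f_bw^2 + f_rw^2), in [0, sqrt(2)]."""
        return math.hypot(self.f_bw, self.f_rw)


@dataclass(frozen=True)
class PatientRecord:
    id: str
    features: OverlapFeatures
    ptv_volume_cc: float | None = None
    eligible: bool | None = None

    def __post_init__(self) -> None:
        if not str(self.id):
            raise ValueError("patient id must be nonempty")
        if self.ptv_volume_cc is not None and self.ptv_volume_cc < 0:
            raise ValueError("ptv_volume_cc must be >= 0")

    def feature_value(self, feature_name: str) -> float | None:
        if feature_name == "metric":
            return self.features.metric
        if feature_name == "f_bw":
            return self.features.f_bw
        if feature_name == "f_rw":
            return self.features.f_rw
        if feature_name == "ptv_volume_cc":
            return self.ptv_volume_cc
        raise ValueError(f"unknown feature {feature_name!r}; expected one of {FEATURE_NAMES}")


@dataclass
class Cohort:
    """Ordered collection of patient records with unique ids."""

    patients: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def __getitem__(self, index):
        return self.patients[index]

    # -- label handling --------------------------------------------------
    def labelled(self) -> "Cohort":
        """Sub-cohort of patients with a non-missing eligibility label.

        Patients with missing labels are excluded with a logged warning;
        prediction-time records legitimately lack labels.
        """
        kept = [p for p in self.patients if p.eligible is not None]
        dropped = len(self.patients) - len(kept)
        if dropped:
            logger.warning("excluding %d unlabelled patient(s) from a labelled operation", dropped)
        return Cohort(kept)

    def require_both_classes(self) -> "Cohort":
        labelled = self.labelled()
        eligible = sum(p.eligible for p in labelled)
        if len(labelled) == 0 or eligible == 0 or eligible == len(labelled):
            raise DegenerateCohortError(
                "operation requires a labelled cohort with at least one "
                "eligible and one ineligible patient"
            )
        return labelled

    def feature_values(self, feature_name: str) -> np.ndarray:
        return np.array([p.feature_value(feature_name) for p in self.patients], dtype=float)

    def labels(self) -> np.ndarray:
        """Boolean eligibility labels; raises if any are missing."""
        if any(p.eligible is None for p in self.patients):
            raise ValueError("cohort contains unlabelled patients; call .labelled() first")
        return np.array([bool(p.eligible) for p in self.patients])

    def subset(self, indices) -> "Cohort":
        return Cohort([self.patients[i] for i in indices])

    # -- tabular I/O -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [p.id for p in self.patients],
                "f_bw": [p.features.f_bw for p in self.patients],
                "f_rw": [p.features.f_rw for p in self.patients],
                "metric": [p.features.metric for p in self.patients],
                "ptv_volume_cc": [p.ptv_volume_cc for p in self.patients],
                "eligible": [p.eligible for p in self.patients],
            }
        )

    def to_csv(self, path) -> None:
        frame = self.to_frame().drop(columns=["metric"])
        frame["eligible"] = frame["eligible"].map(
            lambda v: "" if v is None else ("true" if v else "false")
        )
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        """Read a cohort table (columns id, f_bw, f_rw[, ptv_volume_cc, eligible])."""
        frame = pd.read_csv(path, dtype={"id": str})
        required = {"id", "f_bw", "f_rw"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"cohort CSV is missing columns: {sorted(missing)}")
        patients = []
        for _, row in frame.iterrows():
            eligible = None
            if "eligible" in frame.columns and not pd.isna(row["eligible"]):
                raw = str(row["eligible"]).strip().lower()
                if raw in {"true", "1", "yes"}:
                    eligible = True
                elif raw in {"false", "0", "no"}:
                    eligible = False
                elif raw:
                    raise ValueError(f"unparseable eligible value {row['eligible']!r}")
            ptv = None
            if "ptv_volume_cc" in frame.columns and not pd.isna(row["ptv_volume_cc"]):
                ptv = float(row["ptv_volume_cc"])
            patients.append(
                PatientRecord(
                    id=str(row["id"]),
                    features=OverlapFeatures(float(row["f_bw"]), float(row["f_rw"])),
                    ptv_volume_cc=ptv,
                    eligible=eligible,
                )
            )
        return cls(patients)
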