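"""Cumulative-DVH dose constraints and dosimetric-eligibility labelling.

A patient is *dosimetrically eligible* when a treatment plan meets every
constraint in the accepted set for the 6000 cGy / 20 fraction
hypofractionated prescription:

========== ====== ============ =========
structure   DX     limit (cGy)  direction
========== ====== ============ =========
rectal     D30     <= 4710      upper
rectal     D50     <= 3790      upper
bladder    D30     <= 4710      upper
bladder    D50     <= 3790      upper
femur      D05     <= 4400      upper
CTV        D99     >= 6000      lower (coverage)
PTV        D99     >= 5700      lower (coverage)
========== ====== ============ =========

DX is the dose received by x% of the structure volume, read from the
cumulative DVH with piecewise-linear interpolation; exact equality with a
limit passes in both directions.  A stricter "preferred" set is shipped as
an alternative but is not used for labelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingStructureError

__all__ = [
    "CumulativeDVH",
    "Constraint",
    "ACCEPTED_CONSTRAINTS",
    "PREFERRED_CONSTRAINTS",
    "dose_at_volume",
    "check_eligibility",
    "EligibilityReport",
    "read_dvh_csv",
    "write_dvh_csv",
]


@dataclass
class CumulativeDVH:
    """Cumulative dose-volume histogram for one structure.

    ``dose_cgy`` is strictly increasing and starts at 0; the fractional
    volume receiving at least each dose is non-increasing and starts at 1.
    """

    structure_name: str
    dose_cgy: np.ndarray
    fractional_volume: np.ndarray

    def __post_init__(self) -> None:
        self.dose_cgy = np.asarray(self.dose_cgy, dtype=float)
        self.fractional_volume = np.asarray(self.fractional_volume, dtype=float)
        if self.dose_cgy.ndim != 1 or self.dose_cgy.shape != self.fractional_volume.shape:
            raise ValueError("dose and volume arrays must be 1D and the same length")
        if self.dose_cgy.size < 1:
            raise ValueError("DVH needs at least one point")
        if self.dose_cgy[0] != 0.0:
            raise ValueError("cumulative DVH must start at dose 0")
        if np.any(np.diff(self.dose_cgy) <= 0):
            raise ValueError("dose values must be strictly increasing")
        if np.any(self.dose_cgy < 0):
            raise ValueError("doses must be >= 0")
        if abs(self.fractional_volume[0] - 1.0) > 1e-9:
            raise ValueError("fractional volume at dose 0 must be 1")
        if np.any(np.diff(self.fractional_volume) > 1e-12):
            raise ValueError("fractional volumes must be non-increasing")
        if np.any((self.fractional_volume < -1e-12) | (self.fractional_volume > 1 + 1e-12)):
            raise ValueError("fractional volumes must lie in [0, 1]")


def dose_at_volume(dvh: CumulativeDVH, x_percent: float) -> float:
    """DX: the largest dose received by at least x% of the structure.

    Linear interpolation between tabulated points; beyond the last point
    the curve is treated as ending (DX saturates at the final dose when
    the final volume still meets x%).
    """
    if not (0.0 < x_percent <= 100.0):
        raise ValueError(f"x_percent must be in (0, 100], got {x_percent}")
    target = x_percent / 100.0
    volume = dvh.fractional_volume
    dose = dvh.dose_cgy
    if volume[-1] >= target:
        return float(dose[-1])
    # First index where the curve has dropped below the target; the
    # crossing lies on the preceding segment (volume is non-increasing).
    below = int(np.argmax(volume < target))
    if below == 0:
        # volume[0] = 1 >= target always for target <= 1, so this cannot
        # happen for valid DVHs; guard for safety.
        return float(dose[0])
    v_high, v_low = volume[below - 1], volume[below]
    d_low, d_high = dose[below - 1], dose[below]
    if v_high == v_low:
        return float(d_high)
    fraction = (v_high - target) / (v_high - v_low)
    return float(d_low + fraction * (d_high - d_low))


@dataclass(frozen=True)
class Constraint:
    """One DX dose constraint on a named structure."""

    structure: str
    x_percent: float
    limit_cgy: float
    direction: str  # "upper" (dose must be <= limit) or "lower" (>= limit)

    def __post_init__(self) -> None:
        if self.direction not in ("upper", "lower"):
            raise ValueError("direction must be 'upper' or 'lower'")

    @property
    def name(self) -> str:
        return f"{self.structure} D{self.x_percent:g}"


def _constraint_set(limits) -> tuple:
    return (
        Constraint("rectal_wall", 30, limits[0], "upper"),
        Constraint("rectal_wall", 50, limits[1], "upper"),
        Constraint("bladder_wall", 30, limits[2], "upper"),
        Constraint("bladder_wall", 50, limits[3], "upper"),
        Constraint("femur", 5, limits[4], "upper"),
        Constraint("ctv", 99, limits[5], "lower"),
        Constraint("ptv", 99, limits[6], "lower"),
    )


#: The accepted constraint set — the basis of the eligibility label.
ACCEPTED_CONSTRAINTS = _constraint_set((4710, 3790, 4710, 3790, 4400, 6000, 5700))
#: The stricter preferred set (shipped for reference, not used for labels).
PREFERRED_CONSTRAINTS = _constraint_set((4600, 3700, 4600, 3700, 4300, 6000, 5700))


@dataclass
class EligibilityReport:
    eligible: bool
    rows: pd.DataFrame

    def __bool__(self) -> bool:
        return self.eligible


def check_eligibility(dvhs, constraints=ACCEPTED_CONSTRAINTS) -> EligibilityReport:
    """Evaluate a plan's DVHs against a constraint set.

    A plan is eligible iff every upper constraint has DX <= limit and
    every lower constraint has DX >= limit (equality passes).  The report
    holds one row per constraint with the measured DX, the limit, the
    signed margin (positive = passing headroom) and the verdict.
    """
    by_name = {dvh.structure_name: dvh for dvh in dvhs}
    rows = []
    for constraint in constraints:
        dvh = by_name.get(constraint.structure)
        if dvh is None:
            raise MissingStructureError(
                f"no DVH provided for structure {constraint.structure!r}"
            )
        dx = dose_at_volume(dvh, constraint.x_percent)
        if constraint.direction == "upper":
            passed = dx <= constraint.limit_cgy
            margin = constraint.limit_cgy - dx
        else:
            passed = dx >= constraint.limit_cgy
            margin = dx - constraint.limit_cgy
        rows.append(
            {
                "constraint": constraint.name,
                "direction": constraint.direction,
                "dx_cgy": dx,
                "limit_cgy": constraint.limit_cgy,
                "margin_cgy": margin,
                "passed": bool(passed),
            }
        )
    frame = pd.DataFrame(rows)
    return EligibilityReport(eligible=bool(frame["passed"].all()), rows=frame)


# ---------------------------------------------------------------------------
# DVH CSV I/O: columns structure, dose_cgy, fractional_volume
# ---------------------------------------------------------------------------

def read_dvh_csv(path) -> list:
    frame = pd.read_csv(path)
    required = {"structure", "dose_cgy", "fractional_volume"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"DVH CSV is missing columns: {sorted(missing)}")
    dvhs = []
    for structure, group in frame.groupby("structure", sort=False):
        ordered = group.sort_values("dose_cgy")
        dvhs.append(
            CumulativeDVH(
                structure_name=str(structure),
                dose_cgy=ordered["dose_cgy"].to_numpy(),
                fractional_volume=ordered["fractional_volume"].to_numpy(),
            )
        )
    return dvhs


def write_dvh_csv(dvhs, path) -> None:
    frames = [
        pd.DataFrame(
            {
                "structure": dvh.structure_name,
                "dose_cgy": dvh.dose_cgy,
                "fractional_volume": dvh.fractional_volume,
            }
        )
        for dvh in dvhs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
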