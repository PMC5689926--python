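"""Radial feasible / uncertain / not-feasible decision zones.

A patient's point (f_bw, f_rw) lives in the first quadrant; its radial
distance from the origin is the overlap metric.  Two quarter-circle
boundaries partition the plane:

* ``r_inner`` — the minimum metric observed among ineligible patients in
  the reference cohort; below it every reference patient met constraints
  (*feasible*, green);
* ``r_outer`` — the maximum metric observed among eligible patients; above
  it every reference patient failed (*not feasible*, red);
* between the two radii both outcomes occurred (*uncertain*, yellow).

Points exactly on a boundary are classified *uncertain* (conservative
triage).  For a cohort that is perfectly separable the raw radii invert;
they are then swapped and flagged, keeping the three-zone contract total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum

import matplotlib
import numpy as np

matplotlib.use("Agg", force=False)

from .classifier import overlap_metric  # noqa: E402
from .cohort import Cohort, OverlapFeatures  # noqa: E402

__all__ = [
    "ZoneLabel",
    "ZoneBoundaries",
    "DEFAULT_BOUNDARIES",
    "derive_zones",
    "zone_classify",
    "zone_census",
    "render_decision_plot",
    "save_boundaries",
    "load_boundaries",
]


class ZoneLabel(str, Enum):
    FEASIBLE = "feasible"
    UNCERTAIN = "uncertain"
    NOT_FEASIBLE = "not_feasible"


@dataclass(frozen=True)
class ZoneBoundaries:
    """Radii of the feasible/uncertain and uncertain/not-feasible arcs."""

    r_inner: float
    r_outer: float
    separable: bool = False
    source: str = "fitted"

    def __post_init__(self) -> None:
        if self.r_inner < 0 or self.r_outer < 0:
            raise ValueError("zone radii must be >= 0")
        if self.r_inner > self.r_outer:
            raise ValueError("r_inner must be <= r_outer after normalization")


#: Boundaries from the 150-patient development cohort: the smallest metric
#: observed among ineligible patients (0.274) and the largest among
#: eligible patients (0.305).  Optimal radii depend on local contouring and
#: planning practice, so centres should refit on their own cohorts.
DEFAULT_BOUNDARIES = ZoneBoundaries(0.274, 0.305, source="development-cohort-defaults")


def derive_zones(cohort: Cohort) -> ZoneBoundaries:
    """Fit zone radii from a labelled cohort.

    r_inner is the minimum overlap metric among ineligible patients and
    r_outer the maximum among eligible patients.  If the cohort is
    perfectly separated these invert; the radii are swapped and the result
    flagged ``separable`` (the uncertain band then contains no training
    patient but remains defined).
    """
    labelled = cohort.require_both_classes()
    metrics = labelled.feature_values("metric")
    labels = labelled.labels()
    r_inner = float(metrics[~labels].min())
    r_outer = float(metrics[labels].max())
    if r_inner > r_outer:
        return ZoneBoundaries(r_outer, r_inner, separable=True)
    return ZoneBoundaries(r_inner, r_outer)


def _metric_of(features) -> float:
    if isinstance(features, OverlapFeatures):
        return features.metric
    return float(features)


def zone_classify(features, zones: ZoneBoundaries) -> ZoneLabel:
    """Assign a zone to a patient's features (or a bare metric value)."""
    metric = _metric_of(features)
    if metric < zones.r_inner:
        return ZoneLabel.FEASIBLE
    if metric > zones.r_outer:
        return ZoneLabel.NOT_FEASIBLE
    return ZoneLabel.UNCERTAIN


def zone_census(cohort: Cohort, zones: ZoneBoundaries) -> dict:
    """Per-zone patient counts with eligible/ineligible breakdown.

    Unlabelled patients count toward totals with breakdown key ``None``
    mapped to 'unlabelled'.
    """
    census = {
        label: {"total": 0, "eligible": 0, "ineligible": 0, "unlabelled": 0}
        for label in ZoneLabel
    }
    for patient in cohort:
        zone = zone_classify(patient.features, zones)
        census[zone]["total"] += 1
        if patient.eligible is None:
            census[zone]["unlabelled"] += 1
        elif patient.eligible:
            census[zone]["eligible"] += 1
        else:
            census[zone]["ineligible"] += 1
    return census


def save_boundaries(zones: ZoneBoundaries, path) -> None:
    payload = {
        "r_inner": zones.r_inner,
        "r_outer": zones.r_outer,
        "source": zones.source,
        "separable_flag": zones.separable,
    }
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2)


def load_boundaries(path) -> ZoneBoundaries:
    with open(path, encoding="utf-8") as handle:
        payload = json.load(handle)
    return ZoneBoundaries(
        r_inner=float(payload["r_inner"]),
        r_outer=float(payload["r_outer"]),
        separable=bool(payload.get("separable_flag", False)),
        source=str(payload.get("source", "file")),
    )


_ZONE_COLORS = {
    ZoneLabel.FEASIBLE: "#2ca02c",
    ZoneLabel.UNCERTAIN: "#ffdd57",
    ZoneLabel.NOT_FEASIBLE: "#d62728",
}


def render_decision_plot(
    features,
    zones: ZoneBoundaries,
    path,
    fmt: str = "png",
    cohort: Cohort | None = None,
    colors: dict | None = None,
) -> None:
    """Write the decision-support plot for one patient.

    The first-quadrant (f_bw, f_rw) plane is split by quarter-circle arcs
    at ``r_inner`` and ``r_outer`` into green/yellow/red regions and the
    patient appears as a square marker.  Optionally a reference cohort is
    scattered underneath.  Colors are configurable for accessibility.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle, Wedge

    palette = dict(_ZONE_COLORS)
    if colors:
        palette.update(colors)

    if isinstance(features, OverlapFeatures):
        f_bw, f_rw = features.f_bw, features.f_rw
    else:
        f_bw, f_rw = float(features[0]), float(features[1])
    metric = overlap_metric(f_bw, f_rw)

    limit = max(0.5, 1.15 * max(f_bw, f_rw, zones.r_outer))
    fig, ax = plt.subplots(figsize=(5.2, 5.0))
    ax.add_patch(
        Rectangle((0, 0), limit, limit, facecolor=palette[ZoneLabel.NOT_FEASIBLE], zorder=0)
    )
    ax.add_patch(
        Wedge((0, 0), zones.r_outer, 0, 90, facecolor=palette[ZoneLabel.UNCERTAIN], zorder=1)
    )
    ax.add_patch(
        Wedge((0, 0), zones.r_inner, 0, 90, facecolor=palette[ZoneLabel.FEASIBLE], zorder=2)
    )
    if cohort is not None:
        for patient in cohort:
            marker = "o" if patient.eligible else ("x" if patient.eligible is False else ".")
            ax.plot(
                patient.features.f_bw,
                patient.features.f_rw,
                marker,
                color="0.25",
                markersize=4,
                zorder=3,
            )
    ax.plot(f_bw, f_rw, "s", color="black", markersize=9, zorder=4)
    zone = zone_classify(OverlapFeatures(min(f_bw, 1.0), min(f_rw, 1.0)), zones)
    ax.set_xlim(0, limit)
    ax.set_ylim(0, limit)
    ax.set_xlabel("bladder wall-PTV fractional overlap  $f_{BW}$")
    ax.set_ylabel("rectal wall-PTV fractional overlap  $f_{RW}$")
    ax.set_title(f"overlap metric = {metric:.3f}  ->  {zone.value.replace('_', ' ')}")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(str(path), format=fmt, dpi=150)
    plt.close(fig)
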