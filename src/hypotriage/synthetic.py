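"""Synthetic cohorts, anatomy and DVHs for testing the triage pipeline.

Three generators, all seed-reproducible:

* :func:`generate_cohort` — statistical cohorts of (f_bw, f_rw) features
  drawn from right-skewed scaled-Beta distributions, labelled by a latent
  noisy threshold rule on the quadrature metric.  Defaults emulate a
  150-patient planning series with ~29.3% ineligibility and overlapping
  eligible/ineligible feature distributions.
* :func:`generate_anatomy` — a geometric phantom (prostate ellipsoid CTV,
  posterior rectum tube, superior-anterior bladder sphere, walls by
  erosion) from which fractional overlaps arise through the actual
  geometry pipeline.
* :func:`generate_dvhs` — plausible cumulative DVHs whose rectal/bladder
  D30 and D50 rise with the corresponding wall overlap through a logistic
  link that crosses the 4710 cGy accepted limit near 30% overlap — the
  mechanism that makes high-overlap patients fail constraints.

These phantoms capture the statistical and geometric structure the method
assumes, not real pelvic anatomy or planned dose (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .cohort import Cohort, OverlapFeatures, PatientRecord
from .constraints import ACCEPTED_CONSTRAINTS, CumulativeDVH, check_eligibility
from .errors import ExtentError
from .geometry import MarginSpec, StructureMask, expand_margin, fractional_overlap, wall_from_solid

__all__ = [
    "CohortGeneratorConfig",
    "AnatomyConfig",
    "SyntheticAnatomy",
    "generate_cohort",
    "generate_anatomy",
    "generate_dvhs",
    "generate_planned_cohort",
]


@dataclass(frozen=True)
class CohortGeneratorConfig:
    """Statistical-cohort settings.

    Labels follow a latent-noise threshold rule: a patient is eligible iff
    metric + eps < true_threshold with eps ~ Normal(0, label_noise_sd); at
    zero noise labels are exactly threshold-determined.  The Beta
    parameters are calibrated so that the default configuration realizes
    the target ineligible fraction (0.293) in expectation.
    """

    n_patients: int = 150
    ineligible_fraction_target: float = 0.293
    true_threshold: float = 0.28
    label_noise_sd: float = 0.02
    # (alpha, beta, scale) of scaled-Beta feature distributions
    f_bw_dist: tuple = (1.6, 4.5, 0.48)
    f_rw_dist: tuple = (1.8, 3.5, 0.51)
    # log-normal PTV volume (cc): log-median per class, common log-sd
    ptv_log_median_eligible: float = float(np.log(195.0))
    ptv_log_median_ineligible: float = float(np.log(215.0))
    ptv_log_sd: float = 0.35
    include_ptv_volume: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0.0 < self.ineligible_fraction_target < 1.0):
            raise ValueError("ineligible_fraction_target must be in (0, 1)")
        if self.label_noise_sd < 0:
            raise ValueError("label_noise_sd must be >= 0")


def generate_cohort(config: CohortGeneratorConfig | None = None, **overrides) -> Cohort:
    """Draw a labelled synthetic cohort of overlap features.

    Keyword overrides are applied on top of ``config`` (or the defaults),
    e.g. ``generate_cohort(seed=7, label_noise_sd=0.0)``.
    """
    config = replace(config or CohortGeneratorConfig(), **overrides)
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    a, b, scale = config.f_bw_dist
    f_bw = np.clip(scale * rng.beta(a, b, n), 0.0, 1.0)
    a, b, scale = config.f_rw_dist
    f_rw = np.clip(scale * rng.beta(a, b, n), 0.0, 1.0)
    metric = np.hypot(f_bw, f_rw)

    noise = (
        rng.normal(0.0, config.label_noise_sd, n) if config.label_noise_sd > 0 else np.zeros(n)
    )
    eligible = (metric + noise) < config.true_threshold
    if eligible.all() or not eligible.any():
        import warnings

        warnings.warn(
            "generated cohort contains a single eligibility class; "
            "consider more patients or a threshold inside the metric range",
            stacklevel=2,
        )

    patients = []
    for i in range(n):
        ptv = None
        if config.include_ptv_volume:
            log_median = (
                config.ptv_log_median_eligible
                if eligible[i]
                else config.ptv_log_median_ineligible
            )
            ptv = float(np.exp(rng.normal(log_median, config.ptv_log_sd)))
        patients.append(
            PatientRecord(
                id=f"synth-{i:04d}",
                features=OverlapFeatures(float(f_bw[i]), float(f_rw[i])),
                ptv_volume_cc=ptv,
                eligible=bool(eligible[i]),
            )
        )
    return Cohort(patients)


# ---------------------------------------------------------------------------
# Geometric phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnatomyConfig:
    """Phantom geometry in mm on an RAS-labelled isotropic grid.

    The prostate (CTV) is an ellipsoid at the grid center; the rectum is a
    tube running inferior-superior, displaced posteriorly; the bladder is
    a sphere displaced superiorly and slightly anteriorly.  Walls are
    extracted with :func:`wall_from_solid`.  ``jitter`` scales random
    perturbations of sizes and offsets when an rng is supplied.
    """

    spacing_mm: float = 2.5
    shape: tuple = (64, 76, 84)
    prostate_semi_axes_mm: tuple = (26.0, 24.0, 22.0)
    rectum_radius_mm: float = 9.5
    rectum_posterior_offset_mm: float = 29.0
    rectum_half_length_mm: float = 35.0
    bladder_radius_mm: float = 30.0
    bladder_superior_offset_mm: float = 46.0
    bladder_anterior_offset_mm: float = 10.0
    wall_thickness_mm: float = 3.0
    margins: MarginSpec = field(default_factory=MarginSpec)
    jitter: float = 1.0

    def __post_init__(self) -> None:
        lengths = (
            self.spacing_mm,
            *self.prostate_semi_axes_mm,
            self.rectum_radius_mm,
            self.rectum_half_length_mm,
            self.bladder_radius_mm,
            self.wall_thickness_mm,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all phantom lengths must be > 0")


@dataclass
class SyntheticAnatomy:
    """Masks plus the analytic descriptors they were built from."""

    ctv: StructureMask
    rectum: StructureMask
    rectal_wall: StructureMask
    bladder: StructureMask
    bladder_wall: StructureMask
    descriptors: dict


def _grid_coordinates(config: AnatomyConfig):
    spacing = (config.spacing_mm,) * 3
    shape = config.shape
    # Grid centered on the prostate: origin at the negative half-extent.
    origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    axes = [origin[i] + spacing[i] * np.arange(shape[i]) for i in range(3)]
    x, y, z = np.meshgrid(*axes, indexing="ij", sparse=True)
    template = StructureMask(np.zeros(shape, bool), spacing, origin, ("R", "A", "S"))
    return template, x, y, z


def _check_extent(name, voxels):
    boundary = (
        voxels[0].any()
        or voxels[-1].any()
        or voxels[:, 0].any()
        or voxels[:, -1].any()
        or voxels[:, :, 0].any()
        or voxels[:, :, -1].any()
    )
    if boundary:
        raise ExtentError(f"synthetic structure {name!r} reaches the grid boundary")


def generate_anatomy(config: AnatomyConfig | None = None, rng=None) -> SyntheticAnatomy:
    """Build the geometric phantom and its wall structures.

    With an rng, sizes and offsets are jittered (scaled by
    ``config.jitter``) so repeated calls produce an anatomically varied
    cohort; without one the phantom is exactly the configured geometry.
    """
    config = config or AnatomyConfig()
    if rng is not None:
        jitter = lambda s, cap=3.0: float(  # noqa: E731
            np.clip(rng.normal(0.0, s * config.jitter), -cap * s, cap * s)
        )
    else:
        jitter = lambda s, cap=3.0: 0.0  # noqa: E731

    semi_axes = tuple(
        max(14.0, v + jitter(3.0)) for v in config.prostate_semi_axes_mm
    )
    rectum_radius = max(7.0, config.rectum_radius_mm + jitter(1.0))
    # The rectum abuts the posterior prostate surface directly; in
    # challenging anatomy the gland bulges into the anterior rectal wall,
    # modelled here as up to 8 mm of indentation.
    rectum_offset = max(
        rectum_radius + semi_axes[1] - 8.0,
        config.rectum_posterior_offset_mm + jitter(5.0),
    )
    bladder_radius = max(22.0, config.bladder_radius_mm + jitter(3.0))
    # The bladder rests on the prostate base; allow <= 12 mm indentation.
    bladder_sup = max(
        bladder_radius + semi_axes[2] - 12.0,
        config.bladder_superior_offset_mm + jitter(5.0),
    )
    bladder_ant = config.bladder_anterior_offset_mm + jitter(3.0)

    template, x, y, z = _grid_coordinates(config)
    # Axis labels are ("R", "A", "S"): +x right, +y anterior, +z superior.
    ax, ay, az = semi_axes
    ctv_voxels = (x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2 <= 1.0
    rectum_voxels = (x**2 + (y + rectum_offset) ** 2 <= rectum_radius**2) & (
        np.abs(z) <= config.rectum_half_length_mm
    )
    bladder_voxels = (
        x**2 + (y - bladder_ant) ** 2 + (z - bladder_sup) ** 2 <= bladder_radius**2
    )
    for name, voxels in (
        ("ctv", ctv_voxels),
        ("rectum", rectum_voxels),
        ("bladder", bladder_voxels),
    ):
        _check_extent(name, voxels)

    ctv = template.with_voxels(ctv_voxels)
    rectum = template.with_voxels(rectum_voxels)
    bladder = template.with_voxels(bladder_voxels)
    rectal_wall = wall_from_solid(rectum, config.wall_thickness_mm)
    bladder_wall = wall_from_solid(bladder, config.wall_thickness_mm)

    descriptors = {
        "prostate_semi_axes_mm": semi_axes,
        "prostate_volume_cc": 4.0 / 3.0 * np.pi * ax * ay * az / 1000.0,
        "rectum_radius_mm": rectum_radius,
        "rectum_posterior_offset_mm": rectum_offset,
        "bladder_radius_mm": bladder_radius,
        "bladder_center_mm": (0.0, bladder_ant, bladder_sup),
        "wall_thickness_mm": config.wall_thickness_mm,
    }
    return SyntheticAnatomy(
        ctv=ctv,
        rectum=rectum,
        rectal_wall=rectal_wall,
        bladder=bladder,
        bladder_wall=bladder_wall,
        descriptors=descriptors,
    )


# ---------------------------------------------------------------------------
# Synthetic DVHs
# ---------------------------------------------------------------------------

#: Logistic link from wall-overlap fraction to the wall D30 (cGy): the
#: curve crosses the 4710 cGy accepted limit near overlap 0.30, encoding
#: the planning heuristic that >30% overlap precludes the D30 constraint.
_D30_BASE = 3000.0
_D30_SPAN = 3500.0
_D30_MIDPOINT = 0.30
_D30_WIDTH = 0.05


def _oar_d30(overlap: float) -> float:
    return _D30_BASE + _D30_SPAN * expit((overlap - _D30_MIDPOINT) / _D30_WIDTH)


def _survival_dvh(name: str, median_cgy: float, spread_cgy: float) -> CumulativeDVH:
    """Cumulative DVH of a Normal(median, spread) differential dose distribution.

    The grid runs far past any constraint level; the residual tail at the
    final dose is closed to zero so the curve is a complete DVH.
    """
    doses = np.arange(0.0, 12000.0 + 1.0, 25.0)
    volume = norm.sf(doses, loc=median_cgy, scale=max(spread_cgy, 1.0))
    volume[0] = 1.0
    volume = np.minimum.accumulate(np.clip(volume, 0.0, 1.0))
    volume[-1] = 0.0
    return CumulativeDVH(name, doses, volume)


def generate_dvhs(features: OverlapFeatures, rng=None, prescription_cgy: float = 6000.0):
    """Synthesize a plan's cumulative DVHs from the patient's overlaps.

    Rectal/bladder D30 follows the logistic link in the corresponding
    overlap fraction (D50 = 0.8 x D30), targets sit near the prescription
    and the femur stays far below its limit; the rng adds ~80 cGy of plan-
    to-plan variability.  Feeding the result to
    :func:`~hypotriage.constraints.check_eligibility` yields labels that
    correlate with the overlap metric.
    """
    noise = (lambda s: float(rng.normal(0.0, s))) if rng is not None else (lambda s: 0.0)

    dvhs = []
    for name, overlap in (("rectal_wall", features.f_rw), ("bladder_wall", features.f_bw)):
        d30 = max(500.0, _oar_d30(overlap) + noise(80.0))
        d50 = 0.8 * d30 + noise(40.0)
        d50 = min(d50, d30 - 1.0)
        # Normal survival curve through the two quantiles:
        # P(D >= d50) = 0.5 -> median = d50; P(D >= d30) = 0.3 fixes the spread.
        spread = (d30 - d50) / norm.isf(0.3)
        dvhs.append(_survival_dvh(name, d50, spread))
    dvhs.append(_survival_dvh("femur", 2000.0 + noise(100.0), 300.0))
    dvhs.append(_survival_dvh("ctv", prescription_cgy + 150.0 + noise(15.0), 30.0))
    dvhs.append(_survival_dvh("ptv", prescription_cgy + 50.0 + noise(25.0), 100.0))
    return dvhs


def generate_planned_cohort(
    n_patients: int = 150,
    seed: int = 0,
    anatomy_config: AnatomyConfig | None = None,
) -> Cohort:
    """End-to-end cohort: phantom anatomy -> overlaps -> DVHs -> labels.

    Each patient gets a jittered phantom, fractional overlaps computed
    through the geometry pipeline (PTV by margin expansion of the CTV),
    synthetic DVHs driven by those overlaps, and an eligibility label from
    the accepted constraint set.  This exercises every stage the triage
    tool chains together, with no circular use of the classifier.
    """
    anatomy_config = anatomy_config or AnatomyConfig()
    rng = np.random.default_rng(seed)
    patients = []
    for i in range(n_patients):
        anatomy = generate_anatomy(anatomy_config, rng=rng)
        ptv = expand_margin(anatomy.ctv, anatomy_config.margins)
        features = OverlapFeatures(
            f_bw=fractional_overlap(anatomy.bladder_wall, ptv),
            f_rw=fractional_overlap(anatomy.rectal_wall, ptv),
        )
        dvhs = generate_dvhs(features, rng=rng)
        report = check_eligibility(dvhs, ACCEPTED_CONSTRAINTS)
        patients.append(
            PatientRecord(
                id=f"plan-{i:04d}",
                features=features,
                ptv_volume_cc=ptv.volume_cc,
                eligible=report.eligible,
            )
        )
    return Cohort(patients)
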