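# Methods

This note records the model behind `hypotriage`, the conventions chosen
where more than one reasonable definition exists, and what the synthetic
generators do and do not emulate.

## Eligibility model

A patient is *dosimetrically eligible* when a 6000 cGy / 20 fraction plan
can meet the accepted constraint set (rectal wall D30 ≤ 4710 / D50 ≤ 3790
cGy, bladder wall D30 ≤ 4710 / D50 ≤ 3790 cGy, femur D05 ≤ 4400 cGy, CTV
D99 ≥ 6000 cGy, PTV D99 ≥ 5700 cGy). Because the wall OARs must receive
far less than prescription, a PTV that overlaps more than roughly 30 % of
a wall makes the corresponding D30 constraint geometrically impossible
without sacrificing coverage. The predictor therefore uses only the two
fractional overlaps `f_BW`, `f_RW` and their quadrature combination
`m = sqrt(f_BW² + f_RW²)`, with the fixed rule *ineligible iff m ≥ t*.
The boundary case belongs to the ineligible side (inclusive ≥): the rule
errs toward flagging a patient for early consult rather than wasted
planning.

## Geometry conventions

* **Voxel model.** A voxel belongs to a structure iff its *center*
  satisfies the defining predicate; all boundary comparisons are
  inclusive (≤). No partial-volume weighting. This makes every operation
  match its brute-force definition exactly, which the test suite exploits.
* **Orientation.** Masks carry explicit anatomical axis labels (the
  direction in which each grid index increases, e.g. `("R","A","S")`).
  "Posterior" is always resolved from the labels, never from array order,
  so a flipped acquisition cannot silently invert the asymmetric margin.
* **Margin kernel.** The CTV-to-PTV expansion uses a piecewise-ellipsoidal
  kernel: displacement d lies inside the margin iff
  `Σ_axis (d_axis / m_axis(sign d_axis))² ≤ 1`, where each axis
  contributes the margin of the half-axis matching the component's sign.
  It reduces to a ball for isotropic margins and is smooth across the six
  octant boundaries, unlike a box kernel. Defaults: 10 mm everywhere,
  7 mm posteriorly. Implemented as a binary dilation with a physical-unit
  structuring element; a zero margin admits zero displacement along that
  half-axis, so all-zero margins are the identity.
* **Walls.** `wall_from_solid` erodes the solid organ by a ball of the
  wall thickness (default 3 mm, configurable) and subtracts; the wall is
  a subset of the organ by construction. Whether clinical wall contours
  are outer surfaces or fixed-thickness shells varies by protocol; the
  synthetic walls are an explicit stand-in, not a claim about any trial's
  contouring.
* **Rasterization.** Contour slices are matched to the nearest voxel
  plane within half a slice spacing; point-in-polygon is boundary-
  inclusive (shapely `intersects_xy`). Fractional overlap is a ratio of
  true-voxel counts on co-registered grids — co-registration (identical
  shape, spacing, origin, labels) is enforced, never resampled silently.

At 1 mm spacing the digitized sphere-pair overlap fraction is within 0.2 %
of the analytic spherical-cap value (3 % is the tolerance the tests
enforce; 1.5 % at 0.5 mm).

## Threshold search

Candidate cutoffs are the midpoints between consecutive distinct sorted
feature values plus two sentinels: 0 (labels every patient ineligible —
all features are nonnegative) and max + 1 (labels everyone eligible).
These candidates realize every labelling the inclusive rule can produce,
so the search is exhaustive. The objective is classification accuracy;
among ties the *smallest* candidate is returned — deterministic and
conservative in the same triage direction as the inclusive boundary rule.
The same polarity (larger value → ineligible) is applied to all candidate
features, including PTV volume, since larger targets are harder to plan.

## Cross-validation

Stratified two-fold: eligible and ineligible patients are halved
independently (an odd class's extra member goes to a coin-flipped fold),
both folds serve as training and testing within each repetition, and the
default 1000 repetitions yield 2000 fold evaluations. Means and sample
standard deviations (ddof = 1) are taken over fold evaluations, not over
per-repetition averages — simpler to audit and equivalent in mean. All
randomness flows through one named generator seeded from the config, so
reports are bitwise reproducible.

A subtlety worth recording: under *stratified* splitting, label-shuffled
(null) cohorts only score at the 50 % chance level when the shuffled
labels are exactly class-balanced. With free Bernoulli labels the
cohort's majority share is preserved between train and test folds, which
biases null accuracy upward (measured: ~52.8 % at n = 40 versus 50.0 %
for balanced assignment). The null checks in the test suite therefore
shuffle balanced labels.

## Zones

`r_inner` = minimum metric among ineligible patients, `r_outer` = maximum
among eligible patients. Points on either arc are classified *uncertain*
(conservative). A perfectly separated cohort inverts the raw radii; they
are swapped and flagged `separable`, keeping the three-zone contract total
(the uncertain band then contains no training patient). Zone colors are
green/yellow/red by default and configurable for accessibility. The
shipped defaults (0.274, 0.305) are development-cohort values intended as
out-of-the-box anchors, not universal constants.

## DVH constraints

DX is read from the cumulative DVH as the largest dose received by at
least x % of the structure, with piecewise-linear interpolation between
tabulated points (nearest-bin lookup is the plausible alternative in some
planning systems; linear interpolation is the standard convention and the
documented choice here). Exact equality with a limit passes in both
directions. Target D99 constraints are lower bounds (coverage); OAR and
femur constraints are upper bounds. The stricter "preferred" constraint
set ships alongside the accepted set but is never used for labelling.

## Synthetic generators

The generators provide the *study conditions* for every test; they are
calibrated once and documented here.

**Statistical cohorts** (`generate_cohort`). `f_BW ~ 0.48·Beta(1.6, 4.5)`
and `f_RW ~ 0.51·Beta(1.8, 3.5)`: bounded, unimodal, right-skewed, metric
spanning ≈ 0.05–0.46. Labels follow a latent-noise threshold rule
`eligible iff m + ε < t*` with `t* = 0.28` and `ε ~ N(0, 0.02)`; at zero
noise labels are exactly threshold-determined. The defaults realize a
mean ineligible fraction of 0.296 against the 0.293 target (n = 150).
PTV volume is log-normal (medians 195 cc eligible / 215 cc ineligible,
log-sd 0.35): correlated with ineligibility but deliberately the weakest
of the four candidate features, so the cross-validated feature ranking
(combined metric ≥ f_RW ≥ f_BW ≥ PTV volume) is stable across seeds.
The Beta scales give f_RW the larger spread, making it the stronger
single-wall predictor.

**Phantom anatomy** (`generate_anatomy`). Ellipsoid prostate (semi-axes
26/24/22 mm) at the grid center, rectum as a 35 mm-half-length tube of
radius 9.5 mm displaced posteriorly, bladder as a 30 mm sphere displaced
superior-anteriorly, on a 2.5 mm isotropic RAS grid; walls by 3 mm
erosion. Jitter draws sizes and offsets per patient; the rectum may
indent the posterior prostate surface by up to 8 mm and the bladder base
by up to 12 mm — the anatomically challenging tail that produces wall
overlaps above 30 %. A straight tube under strict surface abutment cannot
reach such overlaps, which is a limitation of the phantom, not of the
metric.

**Synthetic DVHs** (`generate_dvhs`). Wall D30 follows a logistic link in
the wall's overlap fraction, `D30 = 3000 + 3500·expit((f − 0.30)/0.05)`
cGy, crossing the 4710 cGy accepted limit near f = 0.30 — the same 30 %
argument the metric rests on — with D50 = 0.8·D30 and ~80 cGy of
plan-to-plan noise. Targets sit near prescription with enough headroom
that coverage essentially never fails on its own: the label mechanism is
overlap-driven by design. Cumulative curves are normal survival functions
through the two quantiles, tabulated to 12 000 cGy and closed to zero.

Chaining phantom → overlaps → DVHs → constraint checker yields end-to-end
cohorts (≈ 20 % ineligible at defaults) on which the combined metric
achieves ≥ 85 % (typically 92–94 %) cross-validated accuracy with fitted
thresholds near 0.33 — without the classifier ever seeing the label
mechanism.

**What the phantoms do not emulate.** Real pelvic anatomy (curved rectum,
non-spherical bladder filling, seminal-vesicle CTVs), real dose
distributions, inter-observer contouring variation, and any correlation
structure beyond overlap-driven failure. Passing tests demonstrate that
the pipeline's statistics and geometry behave correctly under the model's
own assumptions; they do not validate the clinical thresholds, which must
come from local cohorts.

## Problem sizes

Oracle-equivalence checks run on grids up to 40³ with small CTVs (the
brute-force predicate is O(N·|CTV|)); phantom grids are 64×76×84 at
2.5 mm; cohort tests use n = 150 with 50–200 CV repetitions and the
acceptance script uses the full 1000 repetitions. These sizes keep the
whole suite under a minute apart from the end-to-end phantom cohort
(~150 phantom constructions).

## Known limitations

* The threshold objective (accuracy) is one defensible reading of
  "maximizes prediction"; balanced accuracy or Youden's J would shift the
  learned cutoff on imbalanced cohorts.
* Whether zone arcs are inclusive or exclusive is a convention; this
  package places them in the uncertain zone.
* `fractional_overlap` requires co-registered grids and does not resample;
  mismatched acquisitions must be resampled upstream.
* The RTSTRUCT importer is best-effort (axial, non-keyhole contours only).
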