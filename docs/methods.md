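# Methods

`limbusvd` quantifies perfused limbal vasculature on 2-D en-face
anterior-segment OCT-angiography (AS-OCTA) frames, grades angular loss of
perfusion (limbal ischemia) after chemical injury, and runs the
longitudinal group statistics of a serial-imaging study with within-eye
control quadrants.  Because no public AS-OCTA limbal data set with
per-quadrant ground truth exists, the package ships a synthetic phantom
of the limbal vasculature whose ground truth is exact by construction;
every pipeline stage is validated against it.

## Imaging model and coordinate conventions

An en-face frame is a square intensity field normalized to [0, 1] with a
physical pixel spacing (default 9 mm / 256 px ≈ 35.2 µm/px, matching a
9 mm × 9 mm scan sampled at 256 A-scans).  Image row 0 is at the top;
"superior" means smaller row indices.  Angles about the limbus center are
measured counterclockwise from the +x image direction in a y-up frame.
Laterality fixes the nasal–temporal axis: +x is temporal in a right eye
(OD) and nasal in a left eye (OS).  The quadrant intervals are therefore

| interval   | OD | OS |
|------------|----|----|
| [0°, 90°)  | ST | SN |
| [90°, 180°)| SN | ST |
| [180°, 270°)| IN | IT |
| [270°, 360°)| IT | IN |

All radial and angular boundaries are half-open, so no pixel belongs to
two regions.  Flipping an image about the vertical axis while toggling
OD↔OS leaves every per-quadrant measurement unchanged (this is a test).

The region of interest for vessel density is a perilimbal annulus
(default 2.5–3.5 mm from the limbus center) intersected with a quadrant
sector and with the complement of an optional manual exclusion mask (the
analogue of excluding iris vessels from the en-face projection).  The
annulus width is an analysis choice, not a measured anatomical value; it
is configurable per annotation.

## Synthetic limbal phantom

The phantom draws a stylized whole-eye limbus: a circle of radius 3 mm
centered in the field, crossed by branching arcade vessels.  Each vessel
family is a quadratic Bézier trunk running radially across the annulus
with two generations of side branches; centerlines carry a Gaussian
cross-profile whose full width at half maximum is the vessel width
(1.5–3.0 px ≈ 50–105 µm; the rendered width represents the
PSF-broadened vessel as imaged, since the scanner's 20 µm lateral
resolution exceeds Nyquist on a 35 µm grid).  A ground-truth pixel is
any pixel whose profile reaches half maximum, so per-quadrant true VD is
an exact pixel count.

Families of one quadrant are confined to that quadrant's 90° wedge and
placed on a jittered stratified angular grid, which keeps arcades mostly
parallel (as in a real limbus) and makes the four quadrants' ground
truths independent.  Each quadrant owns three pools: *base* arcades
(2 parent families, the uninjured vasculature), *reserve* arcades
(4 families of identical morphology, used only as calibration headroom),
and *ingrowth* families (4 deeper, more tortuous, mildly dilated
families emulating reparative neovascularization).  The density ceiling
is ≈ 25% VD per quadrant.

Noise: the clean image is `background + intensity · profile`, multiplied
by Gamma speckle with shape 4 (speckle contrast 1/√4 = 0.5, the
speckle-dominated regime of OCT-derived en-face images) and perturbed by
additive Gaussian noise (σ = 0.02).  Setting `speckle_shape=None` and
`additive_sigma=0` yields noise-free frames for fidelity tests.

Injury phases: vessel dropout is applied per segment (between branch
points) to segments whose centerline midpoint falls in an injured
angular sector, so residual vessels remain anatomically plausible.
Default dropout fractions follow the acute-loss/recovery trajectory
implied by the study's group means (day 1: 0.45, day 3: 0.15, week 1
and month 1: 0); at month 1 ingrowth families are added inside injured
sectors, pushing VD above its pre-injury level.

**Calibration.**  `calibrate_to_target_vd` bisects a continuous
inclusion parameter over an ordered pool of candidate segments (base
arcades first, then headroom families in a greedy max-angular-spread
order; at month 1 the headroom pools ingrowth with reserve), recomputing
the exact ground-truth pixel count at every step, until the quadrant's
true VD is within `tol` (default 0.2 points) of the target.  The greedy
spread ordering matters: filling adjacent angular slots first would pile
up vessel crossings, which both misrepresents limbal anatomy and is
systematically harder to segment.  Targets above the model ceiling raise
`CalibrationError`.

**Study simulation.**  A study design lists eyes (with laterality and
injured quadrants), timepoints, and per-(group, timepoint) VD normal
distributions; drawn targets are clamped at 0 (which biases the lowest
mean upward by ≈ 0.09 points at mean 3.3, SD 2.4 — tests against drawn
targets use the analytic clamped-normal mean).  The bundled replicate
design has 12 eyes (6 subjects × OD/OS) with graded injury extent
(0,0,1,1,2,2,3,3,4,4,4,4 quadrants), i.e. 28 injured and 20 control
quadrants, five timepoints, 240 quadrant-level records.

Determinism: one integer seed drives separate deterministic substreams
for geometry, dropout selection, noise, and study draws; identical
inputs give bit-identical scenes.

What the phantom does **not** emulate: decorrelation-signal statistics,
projection and motion artifacts, vessel caliber variation along a
vessel, capillary-scale plexus, curved (non-planar) limbal geometry,
and inter-eye anatomical variability.  Passing tests therefore show the
pipeline is correct and unbiased *under this model*, not that its
absolute accuracy transfers to device images.

## Vessel segmentation

The chain is the standard en-face OCTA recipe: median filter (5×5) then
Gaussian smoothing (σ = 0.5 px); multi-scale Frangi vesselness; local
adaptive mean-offset thresholding; removal of small 8-connected
components under the exclusion mask.  All filters use reflection
padding; the pipeline is fully deterministic.

Frangi filter: per scale σ ∈ {0.8, 1.2, 1.6, 2.0} px the γ-normalized
Hessian (γ = 1, i.e. σ²·∂²) is computed by separable correlation with
sampled Gaussian-derivative kernels.  The sampled second-derivative
kernel is mean-corrected to sum exactly to zero — without this, a
multiple of the local image mean leaks into the Hessian at small σ and
breaks shift invariance (a property test).  With eigenvalues
|λ₁| ≤ |λ₂|, the bright-vessel response is 0 where λ₂ ≥ 0 and otherwise
`exp(−R_B²/2β²)·(1 − exp(−S²/2c²))` with R_B = λ₁/λ₂, S = √(λ₁²+λ₂²),
β = 0.5; the map is the pixelwise maximum over scales.  `c` may be a
constant or `"auto"` (half the maximum S at that scale).

Thresholding: foreground iff vesselness > local mean (25 px window) +
offset.  Cleanup: exclusion first, then components with fewer than
10 pixels are dropped (8-connectivity), so a component split by the
exclusion boundary is re-measured on its surviving part.

Parameter provenance: the source method names the chain but no
parameter values, so defaults here are design choices validated against
phantom ground truth.  The working point (median 5, σ 0.5, scales
0.8–2.0, window 25, and the threshold settings recorded in
`SegmentationConfig`) was selected so that measured VD tracks true VD
across the 2–12% range on noise-free frames while cohort-level bias on
speckled frames stays small at all study densities.  Two systematic
errors trade off against each other: on clean images the vesselness
ridge is wider than the vessel's half-maximum support, inflating VD
(halo); under speckle, dense vascular beds raise the local threshold
window mean and fragment weak vessels, deflating VD.  The offset
balances the two; no setting removes both.

## VD, ischemia extent and grading

VD of an ROI is `100 × vessel pixels / ROI pixels`.  The denominator is
the ROI, making "the entire area of the binarized image" explicit —
quadrant VDs are therefore directly comparable across quadrants and
eyes.  An empty ROI is an error, never a silent 0.

The angular profile divides the annulus into bins (default 30°, one
clock hour — coarse enough that every healthy bin of the sparse limbal
arcade contains at least one vessel); the area-weighted mean of bin VDs
equals whole-annulus VD exactly (a conservation test).  A bin is
ischemic iff its VD falls below `drop_threshold_frac` (default 0.5) of
a reference VD — by default the same eye's baseline whole-annulus VD,
falling back to the control-group mean.  Ischemia extent is the percent
of valid bins that are ischemic, and maps onto six grades:

| grade | ischemia (% of circumference) |
|-------|-------------------------------|
| I     | 0                             |
| II    | > 0 and < 25                  |
| III   | ≥ 25 and < 50                 |
| IV    | ≥ 50 and < 75                 |
| V     | ≥ 75 and < 100                |
| VI    | 100                           |

Boundaries are exact; 25, 50, 75 belong to the higher grade.  The
ischemia operationalization (bin width, drop threshold, reference) is a
design choice of this package — the grading table defines intervals, not
a measurement procedure.

## Longitudinal statistics

Between groups (injured vs control quadrants, per timepoint): Student's
pooled-variance two-sample t-test, two-sided (Welch behind
`equal_var=False`); a summary-statistics variant is provided.  Zero
variance conventions: equal means → t = 0, p = 1; unequal means →
t = ±∞, p = 0.

Within group across timepoints: one-way ANOVA, then pairwise
each-timepoint-vs-baseline Student t-tests with Bonferroni adjustment
(multiplied by the number of comparisons, capped at 1); Tukey HSD is
available behind `adjust="tukey"`.  Bonferroni is the default because
capped-at-1 adjusted p-values match the reporting style of the study
this design replicates; the choice is a documented default, not a claim
about the original software's internals.

Eye-level dose–response: ordinary least squares of the per-eye day-1 VD
response on the number of injured quadrants (0–4).  The response is the
*sum* of the four quadrant VDs by default (`response="mean"` for the
mean variant).  The slope CI is t-based at 95%; Pearson r and its
two-sided p accompany the fit.  A flat response returns slope 0, r 0
exactly.  α = 0.05 two-sided throughout.

Quadrant-level records are treated as independent, as in the replicated
design; clustering of quadrants within eyes and eyes within subjects is
not modelled.  This inflates nominal precision and is a known
limitation, documented rather than "fixed".

## Problem sizes used in tests and the acceptance script

Simulation sizes were chosen to keep the full validation cycle at
desk scale: operator-oracle equivalence uses 100 random 32×32 fields
(exact operators) and 12 random fields for the vesselness oracle;
VD fidelity uses one noise-free calibrated scene per target in
{2,4,6,8,10,12}%; group-mean recovery uses full-size cohorts (28 or 20
quadrants) rendered through the image pipeline; the correlation
recovery check uses 200 replicate ground-truth study tables without
image rendering, since the image stage adds approximately unbiased
noise on top of the drawn truth and its contribution is covered by the
cohort-level checks.  The acceptance script draws cohort targets by
stratified (Latin-hypercube) sampling of the clamped normal — the
cohort is still an exact sample from the study distribution, but the
Monte-Carlo error of its mean no longer dominates the comparison.

## Known limitations

- Absolute VD accuracy is phantom-relative; device images differ in
  speckle statistics, artifacts and vessel morphology.
- The ischemia metric needs a positive reference VD; an eye without a
  usable baseline falls back to the cohort control mean.
- The clock-hour tie-break of slit-lamp-style grading is not defined by
  the grading table; only the AS-OCTA ischemia column is implemented
  with half-open intervals.
- Dense vascular beds (> ~14% quadrant VD) are measured with a mild
  negative bias under speckle; see the segmentation section.
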