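# Methods

## Problem and scope

Mesial temporal lobe epilepsy (mTLE) surgery hinges on correctly lateralizing
the epileptogenic temporal lobe. `epilat` implements a decision framework in
which several quantitative neuroimaging measures each emit an ordinal
five-level laterality decision — L, UL, U, UR, R (confident left, weak left,
indeterminate, weak right, confident right) — and a majority-voting scheme
fuses them into a multimodal decision. Upstream image processing
(segmentation, registration, tractography, fMRI preprocessing) is out of
scope: inputs arrive as ROI-labeled intensity grids, tabulated features,
per-fiber region-incidence records, or region time series. Two special table
tokens are carried through everywhere: `_` (metric not performed) and `F`
(metric failed, e.g. a segmentation failure).

## Per-modality features

**Normalized hippocampal volumes.** f₁ (left) and f₂ (right) are each
hippocampal ROI volume ÷ brain volume × 100. Voxel volume is the product of
the spacings; partial-volume weighting is not modeled. The brain volume
counts all labeled voxels (the brain-mask label plus structure labels carved
out of it), so structure labels do not shrink the denominator.

**FLAIR intensity ratios.** f₃ = mean(left)/mean(right) and f₄ =
sd(left)/sd(right) of hippocampal FLAIR intensities, restricted to a caller-
supplied anterior–posterior coronal slice range `(lo, hi)` (half-open,
0-based voxel indices along the declared AP axis). The anatomical boundary
planes are upstream landmarks; here they are plain slice indices. Both the
bounded and unbounded computation are supported.

**Tristructural asymmetries.** For hippocampus, amygdala and thalamus:
100(v_L − v_R)/(v_L + v_R), each in [−100, 100]. Any empty ROI raises a
segmentation failure, which tabulates as `F` and is excluded downstream.

**PET hypometabolism-asymmetry (HA) profile.** For every coronal slice where
both hippocampal ROIs are present, the left and right SUV voxel samples are
compared with a two-sided Welch test at α = 0.05 (direction read from the
sign of the mean difference; ≥ 2 voxels per side required). If significant
and left < right: HA = (SUV_l − SUV_r)/SUV_r; if significant and right <
left: HA = (SUV_l − SUV_r)/SUV_l; otherwise HA = 0. SUV_l/SUV_r are slice
means, so HA ∈ [−1, 1] with negative = left hypometabolic. If both sides
have zero variance and equal means, HA = 0 (no error). The scalar summary is
the unweighted mean of slice HA values; it is banded into a decision with
symmetric thresholds t_unc = 0.05 and t_def = 0.15 (|s| ≥ t_def → L/R,
≥ t_unc → UL/UR, else U). These thresholds are package defaults exposed as
configuration — the summary-to-decision mapping was an open design point —
and were chosen so that a uniformly hypometabolic hippocampus at a clearly
visible effect (≳20 % SUV deficit over most slices) is definitive while
single-slice noise is not.

## Banded classifiers

All four classifiers are linear rules with symmetric uncertainty bands,
implemented as scikit-learn estimators.

**Eigenline (volumetry and FLAIR).** Controls define a decision line through
their centroid along the first principal axis of their 2-D scatter; the band
unit is the standard deviation (ddof = 1) of control signed perpendicular
distances. Decisions: |d| < 1 sd → U, 1 sd ≤ |d| < 2 sd → UL/UR, |d| ≥ 2 sd
→ L/R. Which side of the line means "left" is not derivable from geometry,
so at least one labeled calibration case is required; the orientation sign
maps the mean signed distance of left-labeled cases to L. Exactly collinear
controls (perpendicular sd ≤ 10⁻¹⁰ of the along-line sd) are rejected.

**Tristructural logistic.** Logistic regression (scikit-learn, default
regularization C = 1) on the three volume asymmetries, with p = modeled
probability of left-sided epileptogenicity. Bands: p = 0.5 exactly → U,
0.5 < p < 0.7 → UL, p ≥ 0.7 → L, mirrored below 0.5. The published boundary
description for this model was not implementable as written; the probability
bands are the operative rule.

**Max-margin (connectivity).** A linear SVM with near-hard-margin
regularization (C = 10⁶, exposed as a parameter, since the source model's
regularization is unstated) on the connectivity feature vectors. With M =
1/‖w‖ the geometric margin, decisions band the signed distance at 0.5 M and
M. The categorization variant (mTLE vs non-mTLE) uses the same banding but
emits the class name when |d| ≥ 0.5 M and "uncertain" otherwise.

**HVU voting (diffusion).** Asymmetry of a diffusion scalar is
(L − R)/((L + R)/2) (positive inputs required). Per measure — hippocampal
mean diffusivity, posteroinferior cingulum FA, forniceal crus FA — the
hemispheric variation uncertainty is mean + 2 sd of control |asymmetry|
(≥ 5 controls). A subject's measure votes L/R only when its asymmetry
exceeds the HVU in the direction expected ipsilateral to seizure onset (MD
elevated; both FA measures reduced). Unanimous votes → L/R; one-sided votes
with abstentions → UL/UR; conflicts or no votes → U. The mean + 2 sd
threshold and the aggregation are this package's design (the source method's
exact thresholds live in prior work).

**Band edges.** A value exactly on a band edge takes the more lateralized of
the two adjacent labels (|d| = 1 sd → UL/UR, |d| = 2 sd → L/R, p = 0.7 → L),
matching the explicit inequalities of the published decision rules; only the
exact boundary point (d = 0, p = 0.5) is U. Certainty is therefore
non-decreasing in |d| and in |p − 0.5|.

## Majority-voting fusion

Not-performed and failed outcomes are dropped; the remaining m ∈ [2, 5]
decisions are counted (nX definitive votes for side X, nUX weak votes toward
X, nU indeterminate). Side X is declared if any rule fires:

* R1: nX ≥ 3;
* R2: nX = 2 and m ≤ 3;
* R3: nX = 2, m ∈ {4, 5}, and at most one of the remaining outcomes is a
  definitive opposite;
* R4: nX = 1 and every remaining outcome is in {UX, U}.

If neither side (or degenerately both) fires, the decision is U. The voting
score for a declared side is (nX + 0.5·nUX)/m ∈ [0, 1]; no score is emitted
for U. R4 is deliberately amended from its published form, which required at
least one weak same-side vote and is contradicted by several published
per-patient fusions (e.g. {R, U, U} → R 0.333); the amended rule reproduces
all 48 published multimodal cells, and the printed variant remains available
via `strict_printed_rule4=True`. Exhaustive enumeration over all five-level
multisets of sizes 2–5 (checked in the test suite against an independent
rule evaluator) confirms no input fires both sides. Only laterality-type
decisions are fused; the categorization (mTLE vs non-mTLE) outputs are not.

## Outcome evaluation

Concordance is scored on patients treated by resection alone (the two
resection+neurostimulator cases are grouped with the implant group and
excluded), split on the 24-month Engel class (class 1 = seizure-free). A
decision matches when it points to the operated side (L/UL ↔ left,
R/UR ↔ right); U is eligible but counts against; `_`/`F` are excluded from
eligibility. Per-patient agreement is matches ÷ available metrics × 100 over
all eight decision columns (multimodal included). Group means use the exact
percentages; the printed-style table rounds half-up for display. The group
contrast is a classical pooled-variance two-sample t-test (two-sided,
df = n₁ + n₂ − 2), which reproduces the published p = 0.0216 from the
packaged table; integer-rounded percentages would give 0.0210.

Two published seizure-free concordance cells (tristructural 15/17, diffusion
uncertainty 7/10) cannot be re-derived from the published per-patient table
under any counting rule tried (recounts give 14/17 and 6/10, the latter
agreeing with the published body text's "six (60%)"); the report computes the
recounts and flags those cells rather than forcing agreement. The published
fMRI-connectivity cell (2/2) is likewise not derivable — only one resected
patient carries an fMRI decision — and is reported as computed.

## Connectivity features

NFC(i, j) = fibers incident on both regions ÷ fibers incident on either
(undefined → missing when no fiber touches either); FAC(i, j) = unweighted
mean over connecting fibers of each fiber's mean voxel FA (two-level
averaging; fibers are not voxel-count weighted). A fiber is a plain region-
incidence set — endpoints and traversals are not distinguished, mirroring
the definition's "passing through or connecting". Pearson connectivity is
the correlation matrix of region time series (≥ 3 time points; constant
series yield missing entries). Hemispheric Δ features subtract the
homologous right-hemisphere value from the left one; the printed feature
vectors are F1–F3 (categorization: left-hemisphere values) and F4–F6
(lateralization: Δs). A feature naming a single region (F1, F4) is read as
that region's overall connectivity (row sum excluding the diagonal); a
feature naming a pair is the edge value. The region inventory is
configurable rather than fixed at 164 regions, because published
descriptions alternate between 82 per hemisphere and 164 total.

## Synthetic cohorts

The generators emulate the study's input side so every downstream stage is
testable without patient data: controls cluster tightly around hemispheric
symmetry; left/right cases are displaced by configurable fractional effects.
Defaults describe a typical affected mesial temporal lobe: 30 % ipsilateral
hippocampal volume reduction (amygdala 15 %, thalamus 7.5 % — graded
involvement), 10 % FLAIR mean elevation, 15 % SUV reduction tapering
anterior→posterior (head involvement strongest; the HA summary of such a
case sits near −0.75 × effect), 30 % connectivity reduction, and a 30 % × 0.3
shift of the diffusion asymmetries. Channel noise defaults are small relative
to these effects (e.g. 0.01 on normalized-volume features against a control
between-subject sd of 0.03), so the default cohort is a strong-signal
regime: it validates calibration and decision logic, not the difficulty of
real clinical data, where overlapping distributions, segmentation error and
scanner variation make accuracy far lower than the near-perfect recovery
seen here. Group sizes default to 50 controls / 50 left / 50 right, matching
the scale used for the recovery checks.

Phantom volumes are ellipsoidal ROIs (hippocampus, amygdala, thalamus per
hemisphere plus a brain mask) on a 64³ grid at 1 mm isotropic — the smallest
grid giving ≥ 10 coronal sections through each hippocampus (the default
hippocampus spans ~23). Left/right centers are mirror-symmetric under a grid
flip, so a side-free phantom has exactly equal voxel counts and the
reflection property can be asserted exactly. ROI overlap raises an error at
construction. Fiber sets draw Poisson fiber counts per within-hemisphere
region pair with the ipsilateral rate reduced; time series come from a
Cholesky factorization of a block correlation matrix (within-hemisphere
correlation 0.5, reduced ipsilaterally; between 0.1; 145 time points ≈ a
5-minute resting acquisition at 2 s after discarding equilibration volumes).
One integer seed drives everything; sub-generators derive independent
streams from it, and fixed seeds reproduce outputs bitwise on a platform.

## Numerical and design notes

* Decisions are plain strings; missing/failed are distinct tokens, never
  conflated with U.
* Welch test via `scipy.stats.ttest_ind(equal_var=False)`; logistic fit via
  scikit-learn; the max-margin fit via `SVC(kernel="linear")`; eigenline via
  `numpy.linalg.eigh` on the 2 × 2 control covariance.
* The packaged cohort CSV transcribes the published table verbatim,
  including one internally inconsistent volumetry ratio (P47 "R 1.39"),
  which is stored uninterpreted; the printed ratio column's left/right
  convention is not stated, so the package never interprets it. Explicit
  `procedure`/`operated_side` columns are included because the two
  resection+RNS patients are not distinguishable from pure implant patients
  by the printed procedure token.
* Degenerate inputs raise informative errors rather than guessing: empty
  ROIs, zero right-side FLAIR SD, collinear control scatter, single-class
  training sets, non-positive diffusion values, fusion input outside 2–5
  usable outcomes.

## Known limitations

* No anatomical realism in phantoms (no texture, partial volume, bias
  fields, registration error) and no DICOM ingestion.
* PET summary-to-decision thresholds and the HVU threshold/aggregation are
  package choices where the published description defers to companion work.
* The published training accuracies of the source single-modality models
  (e.g. 98.5 % tristructural) concern external training cohorts and are not
  reproduction targets here.
* Weighted or reliability-aware voting is not implemented; all modalities
  vote equally.
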