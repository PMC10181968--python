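# Methods

## Scope and data model

The package analyses 3-D chest CT volumes in Hounsfield units with per-axis
voxel spacing (NIfTI-1, axes normalized to z,y,x) together with
co-registered integer label maps (lobes 1–5 = RUL, RML, RLL, LUL, LLL;
airway lumen 6; wall 7; nodule 8). All volume/area conversions use the
product of voxel spacings, so anisotropic voxels are handled uniformly.
Clinical-grade segmentation of patient CT is out of scope: label maps are
supplied (phantoms carry exact ones), and only a simple threshold-based
lung segmentation is provided for images with clear body/lung contrast
(voxels < −400 HU, border-connected ambient air removed, small components
dropped, interior holes filled).

## Density panel

Per region (whole lung, a lobe, or any label set), with N voxels:

- MLD = mean HU; lung volume = N · voxel volume / 1000 (mL).
- EI = 100·#{HU < −950}/N. The strict inequality is the dominant LAA-950
  convention.
- GGOI = 100·#{−800 ≤ HU < −700}/N; FIBI = 100·#{HU ≥ −700}/N. FIBI has no
  upper HU cap; the mask/labels are responsible for excluding soft tissue.
- Perc15 = 15th percentile by linear interpolation between order
  statistics (deterministic, the common default).
- Emphysema clusters: 26-connectivity; cluster volume = voxel count ×
  voxel volume. EI_CC120 = 100·(emphysema voxels in clusters > 120 mm³)/N.
  The denominator is all lung voxels (percent of lung volume): with
  whole-lung EI medians near 1 %, a percent-of-emphysema reading would be
  orders of magnitude larger than the ~0.03–0.2 % values this quantity is
  reported with, so the percent-of-lung interpretation is forced by the
  printed magnitudes.
- BI (bulla surrogate) = 100·(emphysema voxels lying in clusters
  > 1000 mm³ of the one-voxel-closed emphysema mask)/N. The original
  bulla detector is shape-based and not fully specified in the
  literature available to us; this volume-based surrogate is configurable
  (threshold, closing) and documented as such. Counting only original
  emphysema voxels inside qualifying closed clusters guarantees BI ≤ EI.
- pEI = 100·(emphysema voxels in the peripheral zone)/(all emphysema
  voxels); *missing* (not zero) when the region has no emphysema. This
  percent-of-emphysema reading is likewise forced by magnitudes: reported
  pEI medians are ~40–45 % while EI is ~1 %, which rules out reading pEI
  as the LAA % within the peripheral zone.

### Central/peripheral partition

Per connected lung component, the Euclidean distance of every lung voxel
to the nearest non-lung voxel is computed in millimetres (exact EDT); the
cut-off is the median distance and voxels at distance ≤ cut-off are
peripheral. Ties at the cut-off go peripheral, making the rule
deterministic, so the peripheral share is ≥ 50 % with the excess exactly
the tie mass at the cut-off; `ZonePartition.tie_fraction` exposes it. On
blocky geometry (cubes, box-lobe phantoms) distance values are heavily
tied and the peripheral share can exceed 50 % by a large margin (a 10³
cube gives 78.4 %); on rounded anatomy the tie mass is far smaller. The
invariant maintained and tested is
`peripheral_fraction − tie_fraction ≤ 0.5 ≤ peripheral_fraction`.

Nodule voxels are *included* in region metrics by default (an
`exclude_nodule` flag removes them), mirroring densitometry pipelines that
cannot segment the nodule out of the parenchyma; the nodule's host lobe is
the lobe its dilation touches first.

## Airway metrics

Phantom tubes are straight, axis-aligned cylinders; the principal axis is
the coordinate axis of largest physical lumen extent. Per cross-section,
lumen and wall areas come from voxel counts, the internal perimeter Pi
from the marching-squares contour of the lumen at the 0.5 level, and wall
thickness from wall area / Pi. Segment values are means over
cross-sections. Note that even analytically wall-area/Pi for an annulus is
t·(1 + t/2r), not t — a known property of this estimator, inherited by the
measurements. WP = 100·WA/(WA+LA), averaged without weighting over
segments of generation ≥ 3 (configurable; trachea and main bronchi
excluded as is standard). AWT-Pi10 fits wall thickness (mm) on Pi (mm) by
OLS and evaluates at 10 mm, reported in cm. Regressing the thickness
itself (rather than √wall-area) matches the centimetre unit and ~0.22 cm
magnitude this quantity is reported with; a √WA variant would produce a
different scale and is deliberately not mixed in.

## Phantoms

Phantoms are box-world chests: ambient air at the border (−1000 HU), a
soft-tissue body (+20 HU), five rectangular lobes with parenchyma HU drawn
away from class boundaries, and compartments whose HU respect the class
intervals — emphysema cubes (< −950), GGO boxes ([−800, −700)), fibrosis
boxes (≥ −700), a spherical nodule. Emphysema compartments are cubes with
≥ 3-voxel clearance, so 26-connected labelling sees each as one cluster
and the one-voxel closing is the identity; every panel metric therefore
has an exact integer-arithmetic expected value computed from the placed
geometry. Optional Gaussian noise is truncated per class (0.5 HU margin,
±3σ) so no voxel crosses a class threshold: count-based metrics stay
exact under noise while MLD shifts within the noise scale. pEI ground
truth applies the partition definition (exact EDT + median cut-off) to the
placed lung mask; the partition itself is validated separately against a
brute-force distance oracle. Default grid 36×44×44 at 1 mm — large enough
for five lobes and multi-cluster geometry, small enough that a
twenty-phantom exactness sweep runs in seconds.

What the phantoms do *not* emulate: anatomical lobe shapes and fissures,
vascular/airway texture, scanner kernel and noise correlation, partial
volume effects. Passing the exactness tests shows the metric definitions
and their implementation are correct, not that segmentation-dependent
steps would work on clinical images.

## Cohort simulator

Two-group cohorts mirror the summary structure of a published 251-subject
incidental-nodule cohort (200 benign / 51 malignant). Each QCT metric is
parameterized by (median, IQR): normal families for MLD, Perc15, lung
volume, WP, AWT-Pi10; log-normal for EI, EI_CC120, BI, GGOI, FIBI
(non-negative, right-skewed, as the published IQR asymmetry suggests);
logit-normal for pEI (a percentage bounded at 100). σ is recovered from
the IQR via the 1.349 normal quartile span; when a printed lower quartile
is 0 the scale comes from the upper half-spread only. Clinical covariates
use the published per-group frequencies; the prior-extrathoracic-cancer
rate (needed by the Mayo score but not tabulated) is fixed once at
0.10/0.30 (benign/malignant) as a plausible choice. All draws come from a
single seeded generator in fixed column order (bit-reproducible).

Outcome mechanisms: *group-conditional* (fixed group sizes, per-group
covariate distributions — reproduces descriptive tables) or *logistic*
(covariates from the base distributions, outcome from user-specified true
coefficients — gives known ground truth for estimator calibration).

## Statistical chain

- Group comparisons: two-sided Mann-Whitney U — exact when both groups
  have n ≤ 8 with no ties, otherwise normal approximation with tie and
  continuity correction; Pearson chi-square without continuity correction
  for categorical variables.
- Logistic regression: IRLS to the ML solution, convergence at relative
  log-likelihood change < 1e−10 (≤ 100 iterations), Wald SEs from the
  observed information, OR CIs as exp(β ± 1.96·SE). Perfect separation is
  detected (diverging coefficients with vanishing deviance) and raised
  explicitly; rank-deficient designs raise an error naming the collinear
  columns (pivoted QR).
- Backward elimination: starting from the univariate screen (p < 0.05),
  repeatedly refit without each covariate, drop the one with the largest
  1-df LR removal p while that p ≥ 0.10 (ties broken by name order). The
  0.10 removal threshold is the common statistical-package default.
- Mayo/Brock scores: evaluated from packaged, cited JSON constants files
  (`src/qctlung/models/`), auditable and replaceable; the Brock variant is
  the parsimonious covariate set (sex, size transform, nodule type, upper
  lobe, count, spiculation). Subjects with unknown smoking status are
  excluded listwise from model fits (with a logged count) but retained in
  descriptive tables.
- Model extension: the base score enters as its logit with a free
  recalibration slope; the QCT covariates (default MLD, pEI) are added;
  base and extended models are then properly nested and the added value is
  the LR test with df = number of added covariates. A fixed-offset mode
  (slope 1) is available behind a flag. The logit-covariate default was
  chosen because it makes the LR comparison well-defined under base-model
  miscalibration.
- ROC: AUC as the Mann-Whitney statistic with half credit for ties;
  variance and CI by DeLong's structural components, CI truncated to
  [0, 1]. AUCs are in-sample ("all available data") by design, matching
  the exploratory character of the analysis; no train/test split is
  applied by default.

## Simulation study sizes

The validation suite and `scripts/acceptance.py` use: 20 phantoms for the
exactness sweep; 100 random 20³ grids for oracle equivalence; 200
replicates of n = 2000 for Wald coverage and backward-selection retention
(signal effects standardized to Wald z ≈ 5, matching a regime where the
two true QCT covariates should essentially always survive selection); 100
null replicates of n = 600 for null retention; 40 seeds of 500 + 500 for
group-direction reproduction; 30 seeds of n = 1000 for the Mayo/Brock
extension gain; 300 replicates for the null LR calibration. Direction
simulations use 500 per group rather than the original 200/51 because the
published effect sizes sit near the detection boundary at the original
sample size (observed p-values 0.003–0.03); with groups of 500 the same
calibrated effects are comfortably detectable, so the check isolates
directionality rather than power at a marginal n.

## Known limitations

- Threshold segmentation is phantom-grade; real lungs need dedicated
  software, and the lobar fissure geometry here is rectangular.
- The bulla index is a volume-threshold surrogate for a shape-based
  detector; absolute BI values are not comparable with that detector.
- The wall-area/perimeter thickness estimator carries the annular bias
  t(1 + t/2r) and voxelization error O(spacing).
- Simulated cohorts draw QCT metrics independently per subject; real
  metric panels are strongly correlated (EI with Perc15, etc.), so
  multivariate selection behaviour on real data may differ.
- Whether the −950 HU threshold should be applied after smoothing is
  scanner-pipeline-dependent; no smoothing is applied here.
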