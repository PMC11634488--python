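# Methods

`hipmorph` quantifies lateral-hip muscle morphometry — volume and
intramuscular fat infiltration (MFI) — from Dixon fat/water MRI with
multi-label muscle masks, evaluates segmentation agreement and rater
reliability, and compares groups with 1D statistical parametric mapping (SPM)
and covariate-adjusted regression. Because studies of this kind rarely
release imaging data, the package ships a synthetic phantom/cohort generator
with analytic ground truth; every downstream stage is validated against it.

## Image model and conventions

Inputs are co-registered 3D fat and water magnitude images plus an integer
label mask on the same grid, all NIfTI. Voxel indices are 0-based; all
anatomical reasoning goes through the 4×4 voxel-to-world affine with RAS+
world axes. The axial (slice) axis is the array axis most aligned with the
world superior–inferior direction; **proximal** is the most superior slice
and maps to profile node 0. The label dictionary (id → muscle, side) lives in
a YAML sidecar because numeric ids are site-specific conventions, not
anatomy. Readers reject shape mismatches, affine mismatches (element-wise
tolerance 1e-4), non-positive voxel sizes, non-integer mask values and labels
absent from the dictionary, each with a distinct error.

## Morphometry

* **Cross-sectional area (CSA)**: labelled voxel count on an axial slice ×
  in-plane voxel area (mm²).
* **Volume**: Σ CSA × slice thickness, which for orthogonal grids equals
  voxel count × voxel volume exactly.
* **Slice MFI**: the pooled proportion Σfat/(Σfat+Σwater) over the labelled
  voxels of the slice. A ratio of sums was chosen over a mean of voxel-wise
  ratios because "proportion of fat to total muscle volume" is a pooled
  quantity; the voxel-mean alternative differs when intensity varies within a
  slice and is deliberately not offered to avoid silent inconsistency.
  Slices with no labelled voxels or zero total signal return NaN ("missing"),
  never 0 — a zero would read as a real fat-free slice and corrupt profiles.
* **MFI profile**: the slice-wise series over the muscle's observed
  superior–inferior span, normalised to 101 equally spaced nodes (proximal 0%
  → distal 100%) with a cubic interpolating spline; muscles observed on fewer
  than 4 slices fall back to linear interpolation, and fewer than 2 valid
  slices is an error. Missing interior slices are bridged by the interpolant
  with a logged warning. Node values are clipped to [0, 1] (a cubic spline
  can overshoot by a hair near steep gradients).
* **Subregions**: gluteus medius is split into anterior/middle/posterior
  thirds and gluteus minimus into anterior/posterior halves. The anatomical
  literature defines these segments by fibre orientation and innervation,
  which a mask alone cannot reproduce; we use a deterministic geometric
  proxy — on each axial slice, labelled voxels are partitioned into
  equal-extent bins along the world anterior–posterior axis (anterior = larger
  +A world coordinate under RAS). The partition is exhaustive and disjoint by
  construction, so subregion volumes sum exactly to the whole-muscle volume,
  and each subregion feeds the profile machinery unchanged.

Flipping the image stack along any axis together with the matching affine
update leaves the voxel-to-world map unchanged, so volumes and profiles are
invariant; flipping the array *without* updating the affine reverses
proximal/distal, and profiles reverse accordingly. Both behaviours are
tested.

## Segmentation agreement and reliability

For two masks on one grid, per label: TP/FP/FN/TN voxel counts and
Dice = 2TP/(2TP+FP+FN), Jaccard = TP/(TP+FP+FN), conformity
CC = 1 − (FP+FN)/TP (algebraically 3 − 2/Dice), TPR, TNR, PPV and volume
ratio VR = |comparison|/|ground truth|. Design choices where conventions
vary:

* TN is counted over the full image grid; this affects TNR only and is
  stated so values are comparable across grids.
* VR direction is fixed as comparison over ground truth.
* Undefined metrics (CC with TP = 0, anything with an empty denominator) are
  reported as missing with a machine-readable reason, never as 0 — silent
  zeros would bias summary means toward pessimism.

Reliability between two measurement series: ICC(2,1) — two-way
random-effects, absolute-agreement, single-measurement — computed from the
ANOVA mean squares (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n), with the
Shrout–Fleiss F-based 95% CI using a Satterthwaite denominator df. The
implementation is cross-checked in the test suite against pingouin's
independent implementation. Bland–Altman bias and limits of agreement use
bias ± 1.96 × sample SD (n−1) of the paired differences. MAE, RMSE, Pearson
r, and **prediction** R² = 1 − SS_res/SS_tot with the first series as ground
truth — not squared correlation, so a biased predictor can score negative.
Constant inputs flag r/R² as NaN rather than erroring.

## Synthetic phantom

Muscles are axis-aligned ellipsoids or elliptic tubes: crude shapes, chosen
because their volumes are closed-form, making volume accuracy a measurable
quantity rather than an article of faith. Intensities follow
water = S·(1 − MFI), fat = S·MFI with S = 1000, so fat/(fat+water) *is* the
designed MFI; the designed profile is constant within each axial slice and
evaluated at the slice's proximal fraction, so the morphometry spline should
recover it node-for-node on noise-free data (observed max node error ~1e-16
for linear designs; ≤ 0.005 is the tested bound for smooth designs).
Gaussian noise (SD as a fraction of S) is added to both channels and clipped
at zero. Overlapping primitives are an error naming the offending label pair
— a later-label-wins rule would silently bias volumes.

The simulated second rater flips only voxels on label boundaries
(6-connectivity), reassigning each flipped voxel the label of a random
differing neighbour, all decisions evaluated against the original mask (no
cascade). This mirrors the empirical fact that interrater disagreement
concentrates at muscle borders; expected Dice decreases monotonically with
the flip probability.

Synthetic cohorts default to the study scale this package was built around:
180 symptomatic / 48 control, female fraction 0.19 / 0.29, Australian
football fraction 0.49 / 0.42, age ~ N(28.3, 5.9) years, BMI ~ N(24.7, 3.2)
kg/m². Muscle volume is baseline + linear covariate effects + group effect +
Gaussian noise. Baselines (Gmax 760 000, Gmed 305 000, Gmin 90 000,
TFL 71 600 mm³) put the default group effects (18 265 / 23 858 / 3 893 /
6 660 mm³) in the single-digit-percent range typical of this population, and
residual SDs (120 000 / 50 000 / 19 000 / 16 000 mm³) are of the order implied
by study-scale confidence intervals around such effects. Covariate
coefficients (volume rising with BMI and male sex, mildly with sport, falling
slightly with age) make group contrasts confounded, so adjustment genuinely
matters in recovery tests. Subject-level MFI curves for SPM testing are a
shared mean profile plus smooth Gaussian noise (white noise convolved with a
Gaussian kernel, default FWHM 12 nodes, rescaled to a target pointwise SD)
— i.i.d. across subjects, hence exchangeable under the null.

What the generator does **not** emulate: real muscle shapes, bias fields,
fat–water swaps, partial-volume mixtures, registration error, or anatomically
defined subregion boundaries. Passing tests therefore demonstrate the
correctness of the measurement and inference machinery, not robustness to
acquisition artefacts.

## Limb selection

One limb per participant enters analysis. Symptomatic participants contribute
their self-reported most-symptomatic limb and are never altered. For
controls, within each sex stratum, round(p·n) participants are assigned their
kicking limb — p being the symptomatic stratum's proportion of
most-symptomatic limbs coinciding with the kicking limb — with the specific
assignment a seeded random permutation. Rounding keeps the deviation from the
target below one person per stratum. A sex stratum with no symptomatic
members falls back to the overall proportion with a logged warning.

## 1D SPM

Node-wise equal-variance two-sample t statistics (df = n_a + n_b − 2) along
the 101 nodes; nodes with zero pooled variance are flagged NaN and excluded
from maxima. The family-wise critical threshold t* comes from one of:

* **permutation** (default): the (1−α) quantile of max|t| over `n_perm`
  seeded group-label permutations, observed labeling included. Default
  n_perm = 10 000; assumption-light and exactly testable by simulation.
* **rft**: the closed-form 1D random-field solution of the expected-Euler-
  characteristic equation for |t|, with residual smoothness (FWHM) estimated
  from the gradients of the variance-normalised residuals.

Testing is two-sided at α = 0.05. Supra-threshold clusters are maximal runs
of |t| > t*. Simulations in the acceptance suite confirm the permutation
threshold controls the family-wise error near α and sits between the
uncorrected and Bonferroni critical values in every simulated dataset.

## Volume regression

OLS of volume on group + age + BMI + sex + sport, reference levels control /
female / soccer (arbitrary but fixed so signs are reproducible). A
group-by-sex interaction is screened first and retained only when its
p-value ≤ 0.05; with an interaction in the model the reported "adjusted mean
difference" is the marginal group contrast averaged over the sample's sex mix
(a linear contrast with an exact t-based CI), since a sex-specific coefficient
would not be a single adjusted difference. The percent difference divides the
adjusted difference by the adjusted control mean — the mean model prediction
with every participant set to the control group. Exactly collinear covariates
raise an error naming the pair; single-sex cohorts skip the interaction with
a logged warning. Categorical single-level covariates are dropped from the
formula rather than passed through as constants.

## Problem sizes and numerical choices

The acceptance script and tests run at deliberately chosen sizes: 200 random
16³ mask pairs for metric-oracle equivalence; ellipsoid rasterisation at 1.5
and 0.75 mm; 500 null simulations × 1000 permutations (n = 20 per group) for
family-wise error; 200 study-scale cohort replicates (180/48) for effect
recovery and CI coverage; 1000 reseeded limb selections; and a compact
64×64×72 phantom for the end-to-end determinism check. These sizes give
Monte-Carlo error comfortably inside the tested tolerance bands while keeping
a full run in the order of minutes on one CPU.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global RNG state is touched, and pipeline
outputs are byte-identical across reruns with the same config. The pipeline
writes uncompressed `.nii` (readers accept `.nii.gz` too) because gzip
headers can embed timestamps and break bit-for-bit reproducibility.

## Known limitations

* Subregion boundaries are a geometric proxy, not the anatomical definitions
  based on fibre direction; absolute subregion MFI values are therefore not
  directly comparable to anatomically segmented data.
* Whether slice MFI should be a pooled ratio or a mean of voxel ratios is a
  genuine convention fork; only the pooled form is implemented.
* The RFT threshold uses the standard stationary-smoothness approximation;
  for strongly non-stationary residuals the permutation method is preferred
  (and is the default).
* No mixed-effects support for analysing both limbs; one limb per participant
  by design.
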