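# Methods

## The analysis model

The package analyses voxelwise metric maps (typically ALFF, the Amplitude of
Low Frequency Fluctuation of resting-state BOLD) from a cohort scanned under
two conditions — eyes closed (EC) and eyes open (EO) — on one or more
visits.  Subjects are partitioned into an EC-EO group and an EO-EC group;
each subject contributes one condition-difference map per visit (EC−EO for
the first group, EO−EC for the second), so a within-group two-condition
design imitates the between-group designs in which covariance-pattern
analysis is usually applied.

### SSM-PCA derivation

For one visit the M in-mask voxels × N subjects difference matrix is
processed as:

1. each subject column is centred to zero mean;
2. the Group Mean Profile (GMP) is the voxelwise mean of the centred
   matrix; subtracting it row-wise leaves the Subject Residual Profile
   (SRP);
3. a reduced SVD, `SRP = U Σ Vᵀ`, yields the spatial patterns
   (Group Invariant Subprofiles, `GIS_k = U[:, k]`, unit norm, mutually
   orthogonal), the singular values σ_k, the variance fractions
   `VAF_k = σ_k² / Σ σ²`, and each pattern's expression per subject
   (Subject Scaling Factor) `SSF_jk = Σ_i SRP_ij · GIS_ik`.

No log transform is applied before centering: the classic formulation on
PET applies one to strictly positive uptake maps, but condition-difference
maps are signed, and only the two centering steps are part of this chain.

Because SRP is centred along both axes its rank is at most N−1; the N-th
singular value is always zero to machine precision.  Components with
σ_k < 1e−12·σ_1 are flagged rank-deficient and excluded from group
statistics, so the final component of a complete derivation never enters a
t-test or a reliability table.

The SVD leaves each component's sign arbitrary.  The package fixes it
deterministically: when group labels are available, the mean SSF of the
EC-EO group minus that of the EO-EC group is made non-negative; otherwise
(or on an exact tie) the voxel with the largest absolute weight is made
positive.  Serialized models are therefore comparable across runs.

The *difference-related pattern* of a derivation is the lowest-index
retained component whose SSF separates the two groups at p < 0.05 in a
pooled-variance two-sample t-test.  When no component passes, the pattern
is reported as absent, not as an error.  No multiplicity correction is
applied across components in this screening step.

### Pattern projection (TPR)

A pattern derived on one dataset is applied prospectively to another by
Topographic Profile Rating: the new subject's difference map is column-
centred, the *derivation* GMP is subtracted, and the inner product with the
pattern is the projected expression.  Projecting the derivation data onto
its own model reproduces the derivation SSFs exactly, which the tests
assert at 1e−10.  Whether held-out subjects should be column-centred before
GMP subtraction is not fixed by the derivation algebra; the package centres
them (mirroring the derivation side) and exposes `center_columns=False` for
the alternative.

### Reliability statistics

Expression reliability across two visits uses the one-way intraclass
correlation printed in the field's reliability studies,

    ICC = (BMS − WMS) / (BMS + WMS),

with subjects as targets and the two visits as the k = 2 ratings
(equivalent to Shrout–Fleiss ICC(1,1)).  BMS and WMS are the between- and
within-target mean squares of the one-way ANOVA.  Pattern similarity across
visits is the Pearson correlation of the two patterns after sign alignment
(the second pattern is flipped when the raw correlation is negative, and
the flip is reported).  The sensitivity of the expression ICC to the
arbitrary group division is quantified by re-partitioning the subjects
uniformly at random into groups of the original sizes, re-deriving the
models per visit, and recomputing the ICC — repeated B times with
percentile 95% intervals.  Re-division ignores demographic matching: the
generator carries no covariates, and the statistic being studied is the
dependence of ICC on the division itself.

### Comparison with the univariate T map

The voxelwise pooled-variance t map between the two groups is thresholded
at the two-tailed critical value for its degrees of freedom (2.09 at
df = 19) and cluster-filtered at a user-supplied minimum extent
(26-connectivity by default, matching the conventions of the Monte-Carlo
cluster tools used with such maps; 6 and 18 are available).  The pattern is
z-transformed over in-mask voxels (mean 0, sd 1, M−1 denominator) and its
|z| threshold is chosen from the observed distinct |z| values so that,
after the same cluster filter, the surviving voxel count is as close as
possible to the T map's count without exceeding it; ties go to the largest
threshold.  The cut is inclusive (|z| ≥ θ).  Survivor count is monotone
non-increasing in θ even with cluster filtering (adding voxels can only
grow connected components), so the search is a binary search over the
sorted candidates.  Agreement between the two binary maps is the Dice
coefficient 2|A∩B|/(|A|+|B|); two empty maps give 0 with a warning.

Cluster-extent calibration itself (Monte-Carlo simulation, smoothness
estimation) is out of scope; the extent threshold is a parameter.

### ALFF

ALFF of a voxel is the mean single-sided spectral amplitude of its
linearly detrended time course over a band, 0.01–0.08 Hz by default.  The
amplitude at DFT bin k is (2/T)·|X_k|, with DC and (for even T) the
Nyquist bin not doubled, and band endpoints are inclusive; at T = 230
samples and TR = 2 s the default band covers bins k = 5…36 (32 bins).
Whether a given toolbox scales the spectrum by 2/T or reports the root
periodogram differs only by a constant factor, which cancels under the
global-mean normalization (division by the in-mask mean) applied before
any group analysis.  No zero-padding is used — padding silently changes the
bin frequencies.  Frame removal, slice timing, realignment, normalization
and smoothing are upstream of this package: it consumes preprocessed 4D
series or ready ALFF maps.

## The synthetic cohort generator

Real cohorts of this design are rarely shareable, so the generator builds
cohorts with the exact statistical structure the chain assumes, on a small
grid (default 20×24×20 voxels, ellipsoidal mask of ≈ 3,700 voxels):

* a unit-norm planted pattern P made of signed Gaussian blobs (posterior
  and superior positive foci, bilateral frontal negative foci);
* per subject j and visit v a loading s_jv = s_j + e_jv with
  s_j ~ N(μ_s, σ_b²) (stable subject trait) and e_jv ~ N(0, σ_w²)
  (session noise);
* condition maps EC = baseline + anatomy_j + ½·s_jv·P + η and
  EO = baseline + anatomy_j − ½·s_jv·P + η′, with iid voxel noise of sd
  σ_v per map and a smooth per-subject anatomy field, so the difference
  map carries s_jv·P + noise and the condition order is interchangeable;
* a per-visit scanner gain multiplying the final maps (default 1.1 on
  visit 3, emulating a scanner change; gains cancel for metrics that are
  global-mean normalized downstream, but the difference maps consumed here
  retain them);
* all draws flow from one seed through per-(subject, visit) seed
  substreams, so enlarging the cohort or adding visits never perturbs
  existing draws.

The signed difference column of subject j is g_j·s_jv·P + noise, where
g_j = ±1 encodes the group.  That signed loading — not s_jv itself — is
what the derivation's SSF estimates, so the planted reliability and effect
are defined on it:

    σ_t² = σ_b² + 4·p₁p₂·μ_s²                (between-subject variance,
                                              including the group split)
    true_icc    = σ_t² / (σ_t² + σ_w² + 2σ_v²)
    true_effect = 2μ_s / sqrt(σ_b² + σ_w² + 2σ_v²)

with p₁, p₂ the group proportions and 2σ_v² the voxel-noise power that a
unit-norm pattern projection inherits from the two condition maps.
`SimulationConfig.from_targets(true_icc, effect_size)` inverts these
relations (σ_w fixed at 1, its role is the unit of loading noise), so
cohorts are requested directly by the quantities the pipeline estimates.
The defaults plant true ICC 0.6 and effect 1.2 — the reliability regime
(fair-to-good, ICC ≈ 0.49–0.66) and the weakest per-visit standardized
group separation that studies of this design report.

The voxel noise default σ_v = 0.025 places the generator in the regime such
data occupy: single-visit pattern recovery is strong but imperfect
(|corr(GIS₁, P)| ≈ 0.95 at the default conditions), patterns derived on
different visits correlate at ≈ 0.9 — adjacent to the 0.81–0.86 reported
for real condition-difference patterns — and the leading component carries
roughly a third of the residual variance, dominant without being total.

### What the generator does not emulate

Passing recovery tests on these cohorts shows the chain is algebraically
and statistically sound, not that real data meet its assumptions.  The
generator omits: spatial autocorrelation of the noise (real ALFF residuals
are smoothed; here only the anatomy field is smooth), anatomical
templates, physiological and motion artefacts, condition-order effects,
voxel-count realism (≈ 3,700 vs ≈ 70,000 in-mask voxels at 3 mm), and any
demographic structure.  Scanner differences are reduced to a global gain.

### Detection power at the planted effect

With n₁ = 11, n₂ = 10 the pooled t-test at α = 0.05 (two-tailed, df = 19)
has noncentrality d·√(n₁n₂/N) = 2.29·d.  At the planted d = 1.2 the
nominal power is 0.741, so the difference-related pattern is expected to be
flagged in roughly three quarters of same-size cohorts — detection of the
planted pattern's *topography* (the GIS) is far more reliable than
detection of its *expression difference* at this sample size.  The
acceptance script reports the empirically realized rate.

## Numerical choices

* Canonical voxel order: first grid axis fastest, ascending, over in-mask
  positions (Fortran ravel).  Every vector and matrix in the pipeline uses
  it; masks compare by grid shape and in-mask index set.
* All images of one analysis must share the grid exactly; no resampling.
* Rank tolerance: σ_k < 1e−12·σ_1 marks a component rank-deficient.
* An all-zero residual matrix (identical subjects) is reported as a
  degenerate model — SSF = 0, VAF = 0 — with a warning, not an error.
* Zero-variance voxels in the voxelwise t map get t = 0 with a warning.
* Ties in threshold matching resolve to the largest (strictest) threshold;
  if even the strictest candidate overshoots the target count, the empty
  map is returned with threshold +inf.
* Effect size is Cohen's d with the pooled sd.  (Printed d values in the
  motivating literature are not always reproducible from the printed t and
  n; the package reports the standard definition.)
* Component indices are 0-based in the Python API and 1-based on the CLI,
  matching the GIS1/SSF1 naming convention of the field.

## Problem sizes in the test suite

The test suite and the acceptance script run entirely on generated data:
recovery experiments use 100 cohorts of 21 subjects × 3 visits on the
default grid, null calibration uses 200 single-visit cohorts, the
random-division bootstrap uses 200 re-divisions, and unit fixtures use
grids of 200–500 voxels.  These sizes give Monte-Carlo error comfortably
inside the asserted tolerances while keeping a full run under a minute.

## Known limitations

* The ICC form is the one-way (BMS−WMS)/(BMS+WMS) only; two-way forms
  (ICC(2,1), ICC(3,1)) are deliberately not offered.
* Inter-scanner and inter-session effects are confounded when visits on
  different scanners are also separated in time; the reliability tables
  label visit pairs but make no attempt to decompose the two.
* The threshold-matching search assumes the target count comes from the
  same mask; matching across masks is not supported.
* Iterative/robust PCA variants, voxel bootstrap, and information-criterion
  component selection are out of scope.
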