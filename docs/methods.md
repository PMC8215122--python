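# Methods

This note documents the model, the numerical choices, and the synthetic
validation design behind `dualale`, in the order the pipeline runs.

## Study table and demographic pooling (`study_io`)

A study record carries a condition label, patient/control counts, mean ± sd
for patient and control age, diabetes duration (years) and HbA1c (%), a
12-item quality checklist, and a list of foci. Missing covariates are
`None` and are excluded from every pooled mean — never imputed. Some
studies report a *median* duration; it is pooled as if it were a mean and
flagged (`duration_is_median`) so the provenance survives round-trips.

Pooling conventions (chosen to match how meta-analysis summary rows are
conventionally built): totals are column sums; a pooled covariate mean is
the **unweighted mean of per-study means** over the studies reporting it;
the pooled "±" is the **unweighted mean of per-study sds**, not the sd of
the study means. Rounding to one decimal happens only at presentation
(`DemographicsSummary.to_frame`), never inside the aggregates.

Cross-condition covariate comparisons use Welch's unequal-variance
two-sample t-test on study-level means (scipy), appropriate for the
unequal group sizes and variances of a 7-vs-13-study split. The quality
checklist scores items in {0, 0.5, 1} — half points are needed because
published totals include values like 8.5 and 9.5 — with inclusion at
total ≥ 8.

The packaged `data/table2_studies.csv` holds the 20-study metadata of the
motivating diabetes corpus. Its item-level checklist scores are a synthetic
decomposition of the published totals (see `data/README.md`); its foci
columns are empty because the source studies' coordinates were never
published — which is exactly why the spatial stages are validated on
synthetic corpora instead.

## Grid and coordinate handling (`stereotax`)

Maps live on an isotropic voxel lattice over the standard MNI152 bounding
box x ∈ [−90, 90], y ∈ [−126, 90], z ∈ [−72, 108] mm; the default analysis
resolution is 2 mm (shape 91×109×91), while tests and the shipped
validation runs use 4 mm for speed. All volume thresholds are expressed in
mm³ so they are resolution-independent.

The brain mask comes from a user NIfTI volume (nearest-neighbour resampled
at our voxel centers) or, by default, from a procedural ellipsoid
(center (0, −18, 18) mm, semi-axes (70, 85, 65) mm) approximating adult
brain extent — adequate for synthetic validation, cruder than a real
tissue mask at the boundary.

Talairach foci are converted to MNI with the Lancaster pooled affine
(`tal2icbm_other`, applied as its inverse), the standard choice in
coordinate-based meta-analysis; the transform is pluggable. Published peaks
often sit at tissue boundaries, so a focus landing outside the mask is
snapped to the nearest masked voxel center if within 5 mm, else dropped
and counted.

## Likelihood maps (`ale_maps`)

* **Kernel.** FWHM defaults to 10 mm (the fixed-width tradition of
  coordinate-based meta-analysis; the validation runs use 12 mm),
  σ = FWHM/√(8 ln 2). Per-focus per-voxel mass is Gaussian density at the
  voxel center × voxel volume (midpoint quadrature), *not* peak-normalized:
  this preserves probability semantics and makes kernel-mass conservation a
  testable invariant (interior mass within 1 % of 1.0 on a 2 mm grid).
* **Truncation.** The kernel is exactly zero beyond 3.5σ. In 3-D a 3σ
  radius keeps only 97.1 % of the mass (the familiar 1-D "99.7 %" does not
  transfer); 3.5σ keeps 99.34 %, comfortably inside the 1 % budget, while
  still confining each focus to a small stamped subcube.
* **Union rule.** Within a study, foci combine as 1 − Π(1 − m_f): the
  probability of at least one effect at the voxel. Monotone in added foci,
  bounded in [0, 1], exactly the dense brute-force evaluation up to the
  deliberate truncation error.
* **Mean and joint.** Condition means are unweighted voxelwise averages
  with empty maps kept in the denominator; the joint statistic is their
  plain sum (no reweighting by study count — the two conditions enter
  symmetrically regardless of 7-vs-13 style imbalances). Reductions and
  increases are analyzed in entirely separate runs.

## Inference (`inference`)

* **Null.** Each permutation relocates every focus independently and
  uniformly over masked voxel centers, preserving per-study focus counts
  and condition membership, and rebuilds study → mean → joint maps with the
  same code path as the observed data. Voxel-center granularity matches map
  construction and keeps the draw reproducible from integer RNG output.
  Joint values at all masked voxels across all permutations are pooled into
  one empirical null (stored as a sorted float32 sample), giving a
  voxel-level p per masked voxel. The default permutation count is 10,000;
  the shipped validation runs use 200–500, which at 4 mm already pools
  5–12.6 million null values.
* **p-values.** p(v) = (1 + #{null ≥ J(v)}) / (1 + N): the add-one
  estimator is a valid (slightly conservative) permutation p and never 0.
  p is monotone non-increasing in J by construction.
* **FDR.** Benjamini–Hochberg step-up at q = 0.05 over masked voxels
  (statsmodels `multipletests`). "FDR (p < 0.05)" is read as BH level
  q = 0.05 rather than a fixed-p lookup — the step-up procedure is the one
  the ALE literature cites.
* **Clusters.** Connected components of the significance map under
  18-connectivity (configurable 6/18/26; unstated in the tradition, 18 is a
  common middle ground), filtered at 100 mm³ minimum volume. The peak is
  the max-joint voxel; exact ties resolve to the smallest flat voxel index
  for determinism. Clusters are sorted by descending volume.
* **Calibration diagnostic.** The production p-values cannot be uniform
  under the null: with truncated kernels most masked voxels have J = 0
  exactly, so p has an atom at 1 (conservative, as a valid p must be).
  `uniformity_pit` therefore computes a *randomized*
  probability-integral-transform (ties broken uniformly) on a spatially
  thinned voxel subsample whose spacing exceeds twice the kernel truncation
  radius — those voxels share no kernel support, so under the
  all-background null the PIT values are iid Uniform(0, 1) and a KS test
  against the uniform is exact. This is a diagnostic only; it never feeds
  thresholding.

## Contribution and meta-regression (`contribution`)

"Intensity ratio" is implemented as the ratio of within-cluster sums of the
condition mean maps to the within-cluster joint sum — the only reading that
guarantees the two percentages are complementary (sum to 100) and lie in
[0, 100]. A study's contribution score is its likelihood mass over all
significant-cluster voxels divided by its condition's study count, so
within a condition the scores sum to the condition mean map's mass over
the clusters (a conservation law the tests check). Meta-regression is
plain study-level OLS (statsmodels), one simple model per covariate plus a
combined model; no weighting, since study size is itself a tested
covariate. Zero-variance covariates and rank-deficient designs raise
errors naming the culprit; studies missing a covariate are dropped per
model.

## Synthetic corpora (`synthetic`)

The generator plants effect centers at fixed MNI coordinates; a study of
condition c expresses a center with probability p_c, an expressed center
emits 3 foci ~ N(center, 5 mm sd) redrawn until inside the mask, and every
study adds Poisson(2) uniform background foci at masked voxel centers.
Covariates are drawn from ranges typical of the diabetes VBM literature
(15–120 per group, durations 1–25 y, HbA1c 6.5–11 %). The standard
validation truth (`default_truth`) uses 10 studies per condition and three
centers chosen near regions the motivating literature implicates: a shared
caudate-like center (0.9/0.9 → expected 50/50 split), a posterior
cingulate-like center exclusive to T2DM (0/0.9 → 0/100), and a cuneus-like
center at 0.3/0.9 (→ 25/75). Because the mean-map amplitude at a center
scales with p_c × foci-per-center and study counts cancel in the average,
the expected contribution split is the ratio of expression probabilities —
an exact analytic oracle for recovery tests.

For regression-recovery tests the covariate link is injected on the score
side (score = α + β·covariate + ε) rather than through foci placement, so
the OLS oracle is exact.

What the generator does **not** emulate: publication bias, anisotropic or
study-size-dependent spatial uncertainty, correlated foci within a study,
real tissue-boundary geometry, or between-study differences in smoothing
and preprocessing. Passing recovery tests therefore demonstrates the
correctness of the estimator under its own assumptions, not robustness to
those real-data complications.

## Validation scale and determinism

The shipped validation runs (tests and `scripts/acceptance.py`) use a 4 mm
grid (~25,000 masked voxels), FWHM 12 mm, 500 permutations for
planted-effect recovery and 20 × 200 permutations for null calibration —
sizes at which the whole battery completes in well under a minute on one
CPU while pooling millions of null values. Every stochastic step
(generation, permutation, PIT tie-breaking) takes an explicit integer seed;
a run's provenance JSON records the config hash and seed, and re-running an
identical configuration reproduces `clusters.csv` byte-for-byte.

## Known limitations

* Fixed-width kernels: no sample-size-adaptive (Eickhoff-style) variant,
  and no random-effects weighting of studies.
* Voxel-level FDR only: no cluster-level FWE or TFCE.
* The ellipsoid default mask is a coarse stand-in for a real brain mask;
  supply a NIfTI mask for serious use.
* Which (if any) Talairach conversion a published corpus underwent before
  analysis is usually unknowable; the transform here is configurable but
  defaults to the Lancaster pooled affine.
* Anatomical labeling of clusters (gyrus / Brodmann area names) is out of
  scope; the cluster table's `location` column is free text left empty.
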