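# dualale

Dual-disorder anatomical likelihood estimation (ALE) for coordinate-based
meta-analysis of voxel-based-morphometry (VBM) findings.

## The problem

VBM studies report their group differences as peak coordinates (foci) in a
stereotactic space (MNI or Talairach), not as full statistical maps.
Coordinate-based meta-analysis asks where such foci converge across
studies. Classic ALE answers that for a single disorder. The *dual-disorder*
variant implemented here pools two related conditions — the motivating case
is type 1 vs type 2 diabetes mellitus (T1DM / T2DM) and their gray-matter
volume (GMV) reductions relative to controls — into **one** analysis, and
then quantifies how much each condition contributes to every convergent
cluster, so that shared and condition-specific anatomy fall out of the same
map.

## The model

For study *s* with foci {x₁ … x_k} (one effect direction at a time,
reductions and increases are never mixed), each focus is a 3-D isotropic
Gaussian probability distribution with FWHM *h* (σ = h / √(8 ln 2)); the
per-voxel mass is the density at the voxel center times the voxel volume.
Foci combine within a study by probabilistic union

&nbsp;&nbsp;&nbsp;&nbsp;L_s(v) = 1 − Π_f (1 − G_σ(‖v − x_f‖) · ΔV),

a study with no findings contributing an all-zero ("empty") map. Study maps
are averaged per condition (empty maps stay in the denominator, which
removes bias toward the condition reporting more foci), and the two
condition means are summed into the joint statistic

&nbsp;&nbsp;&nbsp;&nbsp;J(v) = M_A(v) + M_B(v) ∈ [0, 2].

Significance comes from a spatial-randomness permutation null (foci
relocated uniformly over masked voxels, per-study counts and condition
labels preserved; joint values pooled over voxels and permutations),
voxelwise p-values p(v) = (1 + #{null ≥ J(v)}) / (1 + N), Benjamini–Hochberg
FDR at q = 0.05, and a minimum cluster volume of 100 mm³. For each
surviving cluster the contribution split is the intensity ratio

&nbsp;&nbsp;&nbsp;&nbsp;pct_A = 100 · Σ_{v∈c} M_A(v) / Σ_{v∈c} (M_A + M_B)(v),

and each study receives a scalar contribution score (its likelihood mass
over the significant voxels, normalized by its condition's study count)
which is the response in OLS meta-regression on study size, disease
duration and HbA1c.

Because the source studies' foci tables were never published, the package
ships only their *metadata* (20 studies: sample sizes, ages, durations,
HbA1c, quality-checklist totals) and demonstrates the spatial pipeline on
synthetic corpora with planted, known truth (`dualale.synthetic`).

## Worked example

```bash
dualale simulate --outdir corpus --seed 1 --n-studies 10 --voxel-size 4
dualale run --studies corpus/studies.csv --foci corpus/foci.csv \
    --outdir out --seed 1 --n-perm 500 --voxel-size 4 --fwhm 12
```

The simulated corpus plants three effect centers: one expressed equally by
both conditions (caudate-like, expected split 50/50), one exclusive to
T2DM (posterior-cingulate-like, expected 0/100), and one with expression
probabilities 0.3 vs 0.9 (cuneus-like, expected 25/75). The run prints:

```
run complete in 3.2 s (config hash d5483fcbb62394cb, seed 1)
3 cluster(s) survived FDR q=0.05 and the 100.0 mm3 filter
 cluster  peak_x  peak_y  peak_z location  pct_T1DM  pct_T2DM  volume_mm3  peak_joint  n_voxels
       1    -6.0    18.0     8.0              50.21     49.79     17344.0    0.073430       271
       2    -6.0   -78.0    40.0              28.07     71.93     14144.0    0.034036       221
       3    -2.0   -30.0    40.0               0.20     99.80     11264.0    0.034331       176
```

All three planted centers are recovered with peaks within one voxel of the
truth, and the contribution percentages land close to their analytic
expectations (50/50, 25/75, 0/100) — the exclusive cluster showing the
">99 % one-condition" pattern that motivates the method. `out/` also holds
the NIfTI maps (joint, per-condition means, p, significance), the study
scores, the meta-regression JSON and full provenance.

The pooled demographics of the packaged 20-study table:

```bash
$ dualale demographics
condition  n_studies  total_patients  total_controls  age_mean  age_sd  ...
     T1DM          7             509             351      23.7     3.8  ...
     T2DM         13             666             662      49.8     6.8  ...
overall: 1175 patients, 1013 controls; quality 9.9 +/- 0.7
welch age: t=-3.29, df=12.5, p=0.0061
welch duration: t=1.28, df=6.4, p=0.2457
welch hba1c: t=0.57, df=9.1, p=0.5849
```

T1DM studies are significantly younger than T2DM studies (p < 0.01);
durations (14.7 vs 7.3 y) do not differ significantly given between-study
variance.

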