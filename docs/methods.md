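# Methods

## Problem and model

`normdev` analyzes ROI-level diffusion MRI measures (FA, free-water-corrected
FAt, and free-water fraction FW, each averaged over 17 white-matter tracts
plus a whole-skeleton average) with a normative-modeling approach: instead of
asking whether group means differ, each subject is scored by how far their
value in each ROI deviates from the age- and sex-specific healthy reference.

The normative reference for one (ROI, modality, sex) stratum is the
age-conditional mean and SD of the control group, estimated with the
Nadaraya–Watson (NW) kernel estimator under a Gaussian kernel
K(u) = exp(−u²/2)/√(2π):

    m̂_h(x)  = Σᵢ yᵢ K((x−xᵢ)/h) / Σᵢ K((x−xᵢ)/h)
    σ̂_h²(x) = Σᵢ (yᵢ − m̂_h(x))² K((x−xᵢ)/h) / Σᵢ K((x−xᵢ)/h)

where xᵢ are control ages, yᵢ their ROI values, and h the bandwidth. h is
chosen per stratum by minimizing the leave-one-out cross-validation error
CV(h) = n⁻¹ Σⱼ (yⱼ − m̂_{h,−j}(xⱼ))² over a fixed grid. A subject's deviation
is z = (y − m̂_h(age))/σ̂_h(age), truncated to [−10, 10]. Controls are scored
leave-one-out: each control's reference excludes that control, reusing the
bandwidth selected on the full stratum (per-fold classification contexts
re-select the bandwidth on training controls only).

Deviations feed three downstream analyses:

- **Summary measures** per subject: load (fraction of ROIs with |z| above
  the Bonferroni threshold), severity (signed z of largest magnitude), mean
  and SD of the 18 z-scores, and the fraction of ROIs inside the
  *significant range*. The abnormality threshold is the two-sided
  standard-normal quantile at 1 − α/(2·18) (2.9913 for α = .05); z below
  −threshold is infra-normal, above +threshold supra-normal.
- **Significant range**: each subject's 18 z-scores are turned into a
  Gaussian-kernel-regularized density over 50 equal bins spanning (−10, 10);
  densities are compared bin-wise between groups by one-tailed Welch t-tests
  (patients > controls) and the longest contiguous run of significant bins
  is reported as a z interval.
- **Classification**: L2-penalized (ridge) logistic regression on feature
  sets built from raw values, z-scores (per ROI, all ROIs, FAt+FW
  concatenated), and summary measures; evaluated by the Mann–Whitney AUC
  averaged over 10 group-balanced cross-validation folds. All normative
  estimation — including bandwidth choice and, when used, the significant
  range — happens inside each training fold.

Group comparisons use one-tailed Welch t-tests in fixed directions (FA/FAt
lower, FW higher in patients) with Cohen's d (pooled SD, large-sample CI),
and one-tailed Wilcoxon rank-sum tests with Cliff's delta (Feng–Cliff
consistent variance, asymmetric bounded CI) for the skewed summary measures.
A one-sided paired t-test over the 18 ROIs compares the effect sizes
obtained from z-scores against those from raw values.

## Synthetic cohort

The clinical tables this analysis was designed for are not distributable, so
the package generates cohorts with the statistical structure the method
assumes. Defaults encode the study marginals: 512 controls (age 30.15
[14.26] y, 54.5% male) and 601 patients (31.46 [12.31] y, 63.2% male), ages
truncated to [8, 70].

Controls follow the normative generative model: per-tract quadratic age
trajectories (FA/FAt peaking near age 30, FW rising monotonically), additive
per-tract sex offsets, a per-subject offset shared across tracts
(SD = 0.75·noise_sd), and independent per-tract residual noise (noise_sd
defaults: FA/FAt 0.02, FW 0.015). Values are clipped to (0.01, 0.99), and
the skeleton column is the mean of the 17 tract columns. The shared
per-subject offset models the strong within-subject correlation of ROI means
in real data and gives the skeleton average a realistic, non-degenerate
between-subject variance.

Patients additionally receive a group effect in a per-patient random subset
of tracts: the number of affected tracts is uniform on 1..6 and each
affected tract is shifted by a Cohen's-d-scale amount drawn uniformly from
(0.5, 1.5) times the tract SD — downward for FA/FAt, upward for FW. Affected
tracts are drawn with fixed non-uniform prevalence weights (10:1 linear
decline, first tract highest). The non-uniformity matters: if effect
locations were exchangeable across tracts, the optimal *linear* discriminant
over the 18 z-scores would be the uniform (skeleton) direction, and an
all-ROI classifier could never beat the skeleton column alone; real cohorts
show some tracts implicated far more often than others, and that asymmetry
is what multi-ROI classifiers exploit. With these defaults the per-ROI
group-level effects remain subtle (d ≈ 0.05–0.35), matching the
subtle-but-distributed premise of the analysis.

`oracle_curves` exposes the exact generative mean and SD (assuming the clip
is inactive, true for the defaults), so parameter-recovery and calibration
tests compare the fitted machinery against ground truth without circularity.
`CohortConfig.null()` produces exchangeable groups (zero effects *and*
matched age/sex marginals) for type-I checks.

What the generator does **not** emulate: site/scanner effects (assumed
harmonized upstream), medication and clinical covariates, non-Gaussian
residuals, age-varying effect prevalence, and realistic inter-tract
correlation beyond the single shared offset. Passing tests therefore show
that the estimators are correct and calibrated under the assumed model, not
that the pipeline is robust to those real-data complications.

## Numerical choices

- Bandwidth grid: 40 log-spaced values, 0.5–50 years; exact CV ties break
  toward the smallest h; exhaustive grid search (CV(h) can be multimodal).
- Kernel weights are stabilized by subtracting the smallest squared scaled
  distance per query before exponentiation (cancels in the NW ratios); a
  query where every weight still vanishes raises an extrapolation error
  rather than silently returning a nearest neighbor.
- A CV term whose leave-one-out weights all underflow (isolated age at tiny
  h) falls back to the leave-one-out sample mean, keeping CV(h) finite.
- σ̂ is floored at 10⁻⁶ (modality units) to avoid division by zero in
  degenerate strata; z-scores are truncated to [−10, 10].
- KDE bandwidth for the per-subject z density: Silverman's rule on the 18
  values, floored at one bin width (0.4) — 18 points need strong
  regularization. Per-bin tests are not multiplicity-corrected by default
  (a Bonferroni option exists); a bin with zero variance in both groups
  gets p = 1.
- Ridge penalty λ = 1.0 on train-standardized features (constant columns
  get unit scale); the intercept is unpenalized; classifier score is the
  patient-class probability. Wilcoxon p-values are exact by enumeration for
  combined n ≤ 20 without ties, otherwise continuity-corrected normal.
- Fold design: each fold gets ⌊n/k⌋ subjects per group; remainders go
  one-per-fold to disjoint folds (with 512/601 and k = 10 this yields
  exactly seven (51, 60), two (52, 60) and one (51, 61) folds). Fold
  membership is seeded; subject ids are sorted first so results do not
  depend on row order.
- Tail directions for the summary-measure tests default to: load↑,
  severity↓ (more negative, flipped for FW via mean_z only), mean_z↓
  (↑ for FW), sd_z↑, frac_sig_range↑ in patients; these are package
  defaults, configurable per measure.

## Problem sizes used by the test suite

The statistical tests run at sizes chosen to make their assertions sharp:
calibration at n = 512 controls in one sex stratum; parameter recovery at
1000 controls (≈500 per sex); type-I at 2000 null cohorts of 50 + 50;
classifier-ordering at 20 seeds of 180/210 cohorts with 10-fold CV; the
acceptance script runs the full 512/601 design.

## Known limitations

- At ages where the reference support is sparse (e.g. the oldest control in
  a cohort with a thin age tail), σ̂ is effectively estimated from one or
  two neighbors and can collapse, pushing that subject's truncated z to
  ±10. This is intrinsic to the estimator (the z truncation is its guard);
  it inflates the per-ROI z SD on such cohorts and is why calibration
  checks use full (uniform) age support. Applied work should inspect
  bandwidths and support before interpreting extreme z at age extremes.
- The CV(h) curve is often nearly flat over a wide h range for smooth,
  noisy data; the selected minimum can then be an undersmoothing fluke.
  No one-standard-error rule is applied, to keep the selection rule exactly
  "minimize CV".
- Cohen's d CI uses the large-sample variance, not noncentral-t inversion;
  negligible at the sample sizes used here.
- The paired z-vs-raw effect-size comparison yields a much larger paired d
  on synthetic cohorts than typical clinical data, because the generator's
  age/sex structure is exactly the structure the normative model removes.
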