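# Methods

## Problem and pipeline

At a suspected-progression decision point, the pipeline receives
co-registered volumes on one isotropic grid: tumor label maps
(necrosis = 1, FLAIR-hyperintense = 2, contrast-enhancing = 3) at the
previous and current exam, a GM/WM/CSF tissue map, an FET-PET activity
volume, a 4D DSC perfusion series and a sparse APTw Z-spectrum stack.
Registration and segmentation themselves are out of scope: inputs are
assumed already on the shared grid (the synthetic generator supplies them
there).

Processing order: quantitative maps → longitudinal ROI → per-case features
→ cross-validated Random Forest → statistical evaluation.

## Progressive ROI

`progressive = (seg_curr ∈ {2,3}) ∧ ¬(seg_prev ∈ {1,2,3})`.

The previous exam's *entire* tumor label union is subtracted, not only its
non-necrotic part: any voxel abnormal at the prior exam is not "new", and
removing it is the conservative reading of focusing on progressive tumor
only. No morphological cleanup is applied — raw set algebra keeps the
operation exactly testable and avoids an unmotivated smoothing parameter.
An empty ROI is a valid outcome; the case is flagged (all-missing feature
row) and excluded from modeling with a logged count, never silently
dropped.

The background mask is normal white matter minus all current tumor labels;
it serves as both the DSC reference region and the FET-PET background.

## Leakage-corrected rCBV

* ΔR2\*(t) = −ln(S(t)/S₀)/TE, with S₀ the mean over the pre-bolus baseline
  window (default: first 15 of 80 dynamics; TE = 40 ms, TR = 1.547 s).
  Voxels with non-positive baseline signal are flagged invalid and zeroed.
* The reference curve R(t) is the voxel-mean ΔR2\* over the tumor-excluded
  WM mask.
* Per voxel, ordinary least squares of ΔR2\*(t) on [R(t), −∫₀ᵗR dτ] gives
  K₁ and the leakage coefficient K₂ (positive for T1-dominant
  extravasation, i.e. post-bolus signal overshoot). The corrected CBV is
  K₁·∫R dt; the uncorrected value is the direct trapezoidal integral of
  ΔR2\* from bolus start to the last dynamic. When no leakage is present
  the two agree to float tolerance.
* rCBV = CBV / mean(CBV over the WM mask) × 2.5%, so the WM mean of the
  output equals 2.5 exactly on every run (asserted in tests). Any global
  scaling of the raw signal cancels.

No arterial-input-function deconvolution, smoothing or pharmacokinetic
modeling: only CBV is needed, and the two-regressor reference-curve fit is
the canonical leakage correction for it. Integration uses the trapezoidal
rule throughout (forward and inverse paths share it, so round trips are
exact up to noise).

## APTw (MTR asymmetry)

Z(ω) = S(ω)/S_ref with the reference at −1560 ppm. Each side of the
spectrum is sampled at ±2.7, ±3.5, ±4.3 ppm; per side, the quadratic
Lagrange polynomial through the three samples is evaluated at the B0-shifted
target b₀ ± 3.5 ppm, and APTw = 100·[Z(−3.5) − Z(+3.5)] after the shift.
Three points per side is the minimal scheme that uses every sample; the
B0 field is taken as a provided input (synthetic truth or zeros) — WASSR-
style estimation is out of scope. Voxels whose shifted evaluation point
leaves the sampled range are flagged invalid rather than extrapolated.

## Features

Per modality (TBR, rCBV, APTw) over the progressive ROI: p05, p25, p50,
p75, p95 (linear interpolation between order statistics — the most common
convention, pinned for reproducibility), IQR = p75 − p25, Shannon entropy,
and the hot-spot volume in mm³ — 24 features total. Entropy uses 64
equal-width bins spanning the ROI's own min–max (a constant ROI has
entropy 0 by convention); it is therefore bounded by 6 bits. Hot-spot
thresholds are the literature cutoffs TBR > 2, rCBV > 5.6%, APTw > 1.79%,
with strict inequality (threshold ties excluded) and no minimum cluster
size. The ROI volume itself is deliberately not a feature. Hot-spot
volumes are absolute mm³, not fractions of the ROI.

## Classifier and evaluation

Stratified threefold cross-validation (stratification guards against
minority-free training folds at 17 TRC cases), seed-deterministic. One
Random Forest per fold with pinned hyperparameters: 100 trees, Gini
impurity, √p features per split, unlimited depth. Out-of-fold class-vote
fractions are pooled into a single ROC; AUC equals the Mann–Whitney
statistic with ties counted ½. Impurity importances are averaged over
folds and renormalized to sum to 1.

Evaluation layer: confusion matrix at cutoff 0.5 (a probability exactly at
the cutoff is called TRC, matching the strict ">" convention used for
hot-spots); accuracy/sensitivity/specificity with exact Clopper–Pearson
95% intervals (chosen because Wilson intervals do not reproduce the
reference intervals for 12/17 while Clopper–Pearson does — validated in
tests); a one-sided exact binomial test of accuracy against the
no-information rate (one-sided because the claim is *above* chance; the
two-sided value is also reported); exact two-sided binomial McNemar test
on discordant pairs (appropriate for the small discordant counts expected
at n ≈ 74). Undefined denominators yield missing values, never 0.

## Synthetic cohort: what it emulates and what it does not

Defaults: 57 PD / 17 TRC (so the majority-class no-information rate is
0.77), 64³ grid at 1 mm, seed 0.

* **Geometry** — concentric ellipsoid shells (necrosis ⊂ enhancing ⊂
  FLAIR) with randomized centers and radii; the previous exam uses the
  same shells shrunk by a factor drawn from 0.6–0.8, so the progressive
  ROI is a non-trivial outer shell and necrosis exclusion matters. Tissue
  is a brain ellipsoid with a GM rind, central CSF and WM interior.
* **Planted effects** — inside non-necrotic tumor, case-level levels are
  drawn around class means chosen to straddle the hot-spot thresholds:
  PD (TBR 3.0, rCBV 8%, APTw 3%), TRC (1.5, 3.5%, 1.0%), with
  between-case SDs (0.4, 1.5, 0.8). In standardized units the FET-PET
  contrast is the strongest planted effect, so the generator reproduces a
  PET-led importance ranking. Normal tissue: TBR 1 (WM), 1.2 (GM); CBV
  2.5% (WM), 5% (GM); APTw 0.
* **DSC forward model** — shared gamma-variate bolus (shape α = 3, arrival
  at dynamic 20 of 80, time-to-peak 8 s; baseline = first 15 dynamics; any
  smooth unimodal bolus would do), S(t) = S₀·exp(−TE·ΔR2\*) with
  ΔR2\* = 1000·CBV_fraction·C(t) + leak·∫C; enhancing/FLAIR tumor leaks
  (default rate 1 s⁻¹ per unit integrated bolus). Air voxels carry the
  flat pre-bolus signal.
* **Z-spectrum forward model** — Z = 1 − water line − amide dip, water
  Lorentzian amplitude 0.9 / FWHM 8 ppm (a deliberately broad direct-
  saturation + MT background, consistent with a 2 µT pulse train and
  smooth enough that the 3-point per-side quadratic interpolation of the
  estimator recovers planted values to < 0.2 points for |b₀| ≤ 0.4 ppm),
  amide Lorentzian FWHM 2.5 ppm centered at +3.5 ppm, depth scaled so the
  noise-free asymmetry equals the planted APTw exactly. The B0 field is a
  case-level offset (SD 0.05 ppm) plus a linear gradient (SD 0.1 ppm).
* **Noise** — additive Gaussian per modality (FET SD 0.05 of background,
  DSC SD 1% of S₀, Z-spectrum SD 0.002 of the normalized signal). Rician
  bias, coil profiles, PET reconstruction, motion and registration error
  are *not* simulated; the downstream statistics are histogram summaries
  and are insensitive to the additive/multiplicative distinction at this
  SNR.

Passing tests on this cohort demonstrate that the estimation chain is
mathematically correct (forward–inverse consistency) and that the
pipeline's ranking/classification machinery behaves as designed under
known class structure. They do **not** certify clinical performance: real
PD/TRC intensity distributions overlap far more than the planted defaults,
real segmentations and registrations carry error, and the published
patient-data operating characteristics cannot be reproduced without the
patient images. Accordingly the synthetic cross-validated AUC saturates
near 1.0 and should be read as a pipeline check, not an accuracy claim.

## Numerical choices and degenerate inputs

* Determinism: every random draw goes through
  `numpy.random.default_rng([case_seed, cohort_seed])`; identical configs
  give byte-identical artifacts (CSV outputs use a fixed float format).
* Problem sizes: tests run mostly on 24³–32³ grids with small cohorts; the
  reference conditions (74 cases, 64³) are exercised once in the
  acceptance path, a few minutes on one CPU.
* Flat reference curve → explicit rank-deficiency error; empty reference /
  WM / background masks → explicit errors; tumor covering all WM →
  "background undefined" error; degenerate tumor geometry (radius beyond
  the half-grid) → generation error.
* Float32 storage for volumes; invariance properties (global scaling of
  DSC or Z-spectrum signals) hold to float32 precision.

## Known limitations

Single-timepoint-pair logic (no multi-exam trajectories); B0 handled by
interpolation of a provided shift field only; no B1 correction; leakage
model is the linear two-regressor form (no bidirectional exchange term);
the classifier is intentionally not tuned (pinned defaults, no
hyperparameter search); calibration of the probability scale is not
assessed.
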