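# Methods

## The measurement chain

`dtialps` implements the standard DTI-ALPS measurement of glymphatic
function. Per subject:

1. **Shell selection.** From a multi-shell diffusion acquisition, retain
   measurements with b < 1000 s/mm² (strict, following the convention that
   tensor fits use the low-b regime; an inclusive `--include-b1000` switch
   is provided because "below 1000" is often operationalized as ≤ 1000 when
   a shell sits exactly at 1000). All b=0 volumes are retained and averaged
   into a single reference volume before fitting.
2. **Tensor fit.** Per voxel, weighted linear least squares on
   log-signals: an ordinary least-squares pass on ln S provides predicted
   signals whose squares serve as weights for one refinement pass. WLLS is
   the standard accuracy/cost compromise between plain log-linear OLS and
   full nonlinear fitting; on noise-free data the log-linear system is
   exact, so any symmetric positive-definite tensor is recovered to
   numerical precision. Voxels containing a non-positive signal are flagged
   and excluded; the design matrix is checked for rank 7 (intercept + six
   tensor components), so degenerate direction sets are rejected rather
   than silently pseudo-inverted.
3. **Scalar maps.** Symmetric eigendecomposition per voxel, eigenvalues
   sorted descending; FA = √(3/2)·√(Σ(λi−λ̄)²/Σλi²); MD = trace/3;
   AD = λ1; RD = (λ2+λ3)/2. Negative eigenvalues are clamped to zero
   before map computation and the voxel flagged (full SPD projection was
   rejected as unnecessary at the SNR regimes tested).
4. **ALPS index.** Four 5-mm spherical ROIs at fixed voxel coordinates on
   the 1-mm template grid — left projection (116,109,99), left association
   (126,109,99), right projection (64,109,101), right association
   (54,109,101). Per hemisphere,
   ALPS = mean(Dxproj, Dxassoc)/mean(Dyproj, Dzassoc), where Dx comes from
   the dxx map at both ROIs, Dyproj from dyy at the projection ROI and
   Dzassoc from dzz at the association ROI; the bilateral average is
   reported alongside. The printed coordinates are interpreted as 0-based
   indices in the template's stored orientation with left at the higher x
   index; a `--one-based` switch covers the other convention, which the
   source of the coordinates does not pin down (the printed left/right
   centers are not exactly mirror-symmetric under either reading, so the
   coordinates are used as stated rather than "corrected").
5. **Hippocampal metrics.** Unweighted means of FA/MD/AD/RD over integer
   atlas labels (37/38 = bilateral hippocampi in the conventional
   90-region parcellation), excluding flagged voxels, computed from the
   same b<1000 fit as the ALPS maps for internal consistency (a switch
   allows a different shell set).

Numerical choices that affect bit-stability: sphere membership uses
voxel-center distance ≤ radius (81 voxels for a 5-mm sphere on a 1-mm
grid); ROI values are sorted before averaging so the mean is invariant to
voxel enumeration order — this is what makes the mirrored-phantom
left/right swap exact rather than merely close.

## The phantom generator

The generator exists to give the pipeline inputs whose answers are known.
It emulates a three-group case–control study of glymphatic function in
type 2 diabetes: healthy controls (HC, n=37), diabetes with normal
cognition (DMNC, n=37) and diabetes with mild cognitive impairment
(DMMCI, n=39).

**Geometry.** An ellipsoidal brain mask on a regular grid; four
perivascular ROI spheres with anisotropic tensors (projection fibers along
z, association fibers along y, fiber diffusivity 1.4×10⁻³ mm²/s);
two ellipsoidal hippocampi with mildly anisotropic prolate tensors; an
isotropic background of 0.75×10⁻³ mm²/s. The default grid is the
182×218×182 1-mm template the published ROI coordinates index; a reduced
64×64×32 grid with re-homed ROIs (same left/right layout) runs each
subject in well under a second and is used by the tests and the acceptance
script.

**Acquisition.** 12 b-values (0, 300, 350, 650, 950, 1000, 1350, 1650,
1700, 2000, 2700, 3000 s/mm²) and 99 gradient directions, the size of the
multi-shell protocol being emulated. The 99 directions are one spherical
Fibonacci lattice (seed-rotated) interleaved across the 11 non-zero
shells — 9 per shell — since a 7.5-minute scan holds 99 diffusion-weighted
volumes, not 99 per shell. `make_scheme` also builds dense per-shell
variants; six-direction minimal designs use the classic icosahedral-style
set because the 6-point Fibonacci lattice is rank-deficient for tensor
estimation. Signals follow the monoexponential Stejskal–Tanner model
S = S0·exp(−b·gᵀDg) with S0 = 1000.

**Noise.** Magnitude-MRI (Rician) noise, |S + n₁ + i·n₂| with
n₁,n₂ ~ N(0, σ²) and σ = S0/SNR, default SNR 20 — a typical brain-DWI
operating point; the emulated study reports no noise characteristics, so
this is the package's own choice and the calibration below absorbs it.

**Subject variation and calibration.** Between-subject variation enters at
the ROI-diffusivity level, not the voxel level. Per hemisphere, a subject
draws a mean-one lognormal factor that scales both numerator (x-axis)
diffusivities over a fixed denominator of 0.65×10⁻³ mm²/s, so the
ground-truth ALPS ratio is exactly lognormal with the group's target mean
and, via moment matching (σ² = ln(1+CV²)), the target SD. Targets are the
group summaries the generator is calibrated to: HC 1.76±0.26 (left) and
1.59±0.21 (right); DMNC 1.80±0.25 and 1.58±0.22; DMMCI 1.68±0.23 and
1.48±0.19. The `dtialps calibrate` verb verifies both the ground-truth
moments and the pipeline's measurement-noise contribution, which at SNR 20
on an 81-voxel ROI mean is an order of magnitude below the between-subject
SD — hence analytic moment matching suffices and no iterative SD search
was needed. Hemisphere factors are independent; numerator diffusivities
within a hemisphere are perfectly correlated (a deliberate simplification:
only their mean enters the index).

**Covariates and coupling.** Clinical and cognitive covariates are drawn
per group from normal distributions (matched to reported mean±SD, or to
median/IQR with SD = IQR/1.349) or lognormal distributions (matched to
median and quartiles) for skewed laboratory measures; disease duration is
undefined in HC. Two couplings give the cohort its scientific structure:
in the diabetic groups hippocampal RD is negatively correlated
(ρ = 0.45) with the hemisphere's ALPS factor — reproducing the
ALPS–microstructure association that appears only under disease, with FA
and MD inheriting opposite-signed associations through the tensor — and
immediate-recall memory scores carry a mild positive ALPS coupling
(ρ = 0.2) in all groups. Hippocampal tensor means themselves do not differ
between groups (whole-label averaging washes out subfield effects).

**What the phantom does not emulate.** No susceptibility/eddy distortion,
head motion, partial-volume mixing at tissue boundaries, CSF contamination,
spatially varying noise, or multi-compartment/kurtosis signal behavior.
Passing tests therefore validate the estimator chain and the statistics,
not robustness to real-world artifacts; real data must arrive
pre-corrected and normalized.

## The statistics chain

Every group comparison is assumption-gated: Shapiro–Wilk per group and
Levene across groups (both at α = 0.05, Levene centered on means — the
common defaults where none are specified). Pass → one-way ANOVA with Tukey
HSD post hoc (or pooled-variance t-test for two groups); fail →
Kruskal–Wallis with Dunn's midrank z-tests (tie-corrected variance) or
Mann–Whitney U. Each family of three pairwise post hoc p-values is
Benjamini–Hochberg adjusted within the family, not across analyses; both
raw and adjusted values are reported. Descriptives follow the gate:
mean ± SD when parametric, median (IQR) otherwise.

The roster over a cohort table comprises: per-covariate three-group
comparisons (gender by Pearson chi-square without continuity correction;
disease duration by a two-group Kruskal–Wallis over the diabetic groups);
three-group comparisons of the three ALPS indices; within-group
comparisons across the three ALPS variants; a DMNC-vs-DMMCI general linear
model for each index adjusting for duration, fasting glucose and LDL
(complete-case, with dropped rows counted and collinear designs rejected
by condition-number check); binary logistic regressions for MCI status
within diabetes, with the ALPS index entered in "percentage form"
(predictor × 100, so the odds ratio is per 0.01 of the index — the
natural clinical increment for a ratio near 1.6; Wald 95% CIs, and
separation raises an error rather than returning an absurd OR); two-sample
diabetes-vs-control tests for each hippocampal metric; and partial
correlations (Pearson on least-squares residuals, t-based p with
df = n−2−k, Fisher-z CIs) of ALPS against hippocampal metrics within the
diabetic and control strata (covariates: gender, age, education, BMI) and
against cognitive scores in all participants (the 14-covariate clinical
list). The report is a fixed, documented key schema of uniform records.

## Problem sizes used

Tests and the acceptance script run on the reduced grid with the
99-direction scheme: single subjects for exactness properties, 20-subject
batches for noisy-recovery checks, the calibrated 37/37/39 cohorts for
end-to-end recovery, and a 113-subject combined cohort for the structural
left-greater-than-right pattern. Statistical oracles use 100–2000
replicates (type-I error of the gated omnibus, BH fuzzing, Wald-interval
coverage). The full suite completes in a few minutes on one CPU.

## Known limitations

- **Eigenvalue noise bias.** At finite SNR, per-voxel eigendecomposition
  inflates AD and deflates RD (eigenvalue repulsion) and inflates FA
  markedly in low-anisotropy tissue such as hippocampus — the classic FA
  noise floor. MD, linear in the tensor, is unbiased. The hippocampal
  recovery tests encode exactly this: MD within 3 SEM of the preset,
  AD/RD within 5%, FA bounded above its noise-free value. Group
  *contrasts* of hippocampal metrics are unaffected because the bias is
  common to all groups.
- ALPS measurement error (~0.02 per index at SNR 20) is absorbed into the
  calibrated between-subject SD rather than modeled separately; the
  emulated study reports no SNR, so biological and measurement variance
  cannot be disentangled.
- The ROI coordinate convention (0- vs 1-based, stored x-orientation) is
  exposed as switches, not resolved; the printed centers are not exactly
  mirror-symmetric under any convention.
- Within-group comparisons of the three ALPS variants treat the variants
  as independent samples (matching common practice in the literature this
  emulates) rather than as repeated measures, which overstates the
  residual df.
- No spatial registration is provided; template-space input is the
  caller's responsibility.
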