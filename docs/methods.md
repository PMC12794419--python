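# Methods

This note documents the models, estimators and numerical choices in
`polarisc`, what the synthetic cohorts do and do not emulate, and the
known limitations of the approach.

## 1. The polarization estimator

All analysis operates on per-statement z-scored, concatenated voxel time
series (see §3). For subject *i* with group *g(i)* and voxel *v*:

- within-group ISC: `R_w(i,v) = corr(x_iv, mean_{j∈g(i), j≠i} x_jv)`
  (leave-one-out own-group average);
- between-group ISC: `R_b(i,v) = corr(x_iv, mean_{j∉g(i)} x_jv)` (full
  other-group average);
- polarization difference `d(i,v) = R_w − R_b`; the cohort map averages
  d over subjects.

The whole-sample one-to-average ISC uses the leave-one-out average by
default (including the left-out subject inflates R); an
`leave_one_out=False` variant exists. Cohort maps average raw R values;
a Fisher-z averaging option exists but is off by default, matching the
convention of reporting "average R-value" maps. Reference averages are
plain means of the z-scored series with no re-normalization.
Zero-variance series produce masked (NaN) correlations, never zeros.

**Reference-size asymmetry.** The within reference averages k−1 series
while the between reference averages k. Under a signal common to the
whole cohort the between reference is therefore slightly less noisy and
`E[d] < 0` by a small margin: ≈ −0.014 at k = 5 and ≈ −4·10⁻⁴ at k = 20
(our design size) in simulation. This is a property of the estimator as
defined; at pure-noise voxels `E[d] = 0` exactly by symmetry.

## 2. Inference

**Sign-flip permutation.** The observed statistic is the one-sample t of
the per-subject d values against zero (sample variance). Each
permutation draws one iid ±1 vector over subjects (flip probability ½,
identity and full flip included) applied to all voxels at once, which
preserves the spatial dependence of the null. The one-sided p-value is
`(1 + #{t_null ≥ t_obs}) / (1 + n_perm)`; ties count toward the
numerator and the attainable minimum is `1/(1+n_perm)`, so p = 0 is
impossible. With n ≤ 12 subjects all 2ⁿ flips are enumerated and the
p-value is the exact null proportion (the identity flip guarantees
p > 0); the observed t is taken from the identity row of the enumerated
null so that it ties bit-exactly. Default `n_perm=10000`. A voxel whose
values are all exactly zero is masked; a constant non-zero voxel gets
t = ±∞ with the sign of the mean (it is maximally incompatible with a
zero-centred null, and its permutation p remains well defined).

**Calibration caveat.** The sign-flip test is exactly calibrated when
the per-subject values are independent and symmetric about zero
(measured type-I rate 0.051 at α = 0.05). The ISC differences d(i,v) are
*not* independent across subjects — every subject's map shares reference
averages with every other — with mean inter-subject correlation ≈ 0.03
at k = 20 even for pure noise. The observed t inherits a variance
inflation of roughly 1 + (n−1)·ρ̄ ≈ 2 that the flip-based null does not,
making the voxel-wise test anticonservative at null voxels (empirically
~0.11 at nominal 0.05, independent of series length and of the
denoising). This is inherent to subject-level inference on one-to-others
ISC as published, not to this implementation; the adaptive FDR stage
absorbs much of it in practice (false-rejection proportion on fully null
cohorts stays ≤ 0.05 + Monte-Carlo error in our checks), but voxel-wise
p-values from this design should be read with that inflation in mind.

**Two-stage FDR (BKY).** Stage 1 runs the Benjamini–Hochberg step-up at
`q' = q/(1+q)`; the non-rejections estimate the number of true nulls m0;
stage 2 re-runs the step-up at `q'·m/m0`. Reported q-values are the
BH-adjusted p-values rescaled by `(m0/m)(1+q)` and clipped at 1, so the
mask is exactly `q ≤ q_level`; like any adaptive adjustment they are
specific to the chosen level. Degenerate stages (no or all rejections at
stage 1) fall back to the stage-1 decision. The rejection set matches an
independent reference implementation on randomized fixtures and is a
superset of plain BH whenever stage 1 estimates m0 < m.

## 3. Time-series preparation

Stage order is exclusion → nuisance regression → high-pass →
statement extraction/z-scoring. The order of regression vs filtering vs
extraction is not uniquely determined by the method description we
follow; this order is an assumption, fixed and documented here, and each
stage is idempotent on its own output.

- **Exclusion:** a subject is dropped iff strictly more than 25 % of
  framewise-displacement values exceed 0.5 mm (both configurable).
- **Nuisance regression:** per-voxel OLS residuals on 23 columns —
  6 motion parameters, their backward-difference derivatives (first
  frame 0), global signal, framewise displacement, 6 aCompCor components
  (accepted as input, never recomputed), and polynomial trends of order
  0–2. The order-0 trend is the intercept; an explicit intercept is
  added only if no constant column is present, since adding one
  alongside it would make the design rank-deficient by construction.
  Rank deficiency raises an error naming the dependent columns.
- **High-pass (0.01 Hz):** projection onto the complement of a
  discrete-cosine drift basis (all components with frequency below the
  cutoff, plus the constant). A regression-style filter avoids the edge
  ringing of IIR filters on concatenated designs; the cutoff must lie
  below Nyquist.
- **Extraction:** a frame belongs to a statement iff its midpoint lies
  in `[onset, onset+duration)` — an unbiased rounding rule. Each
  statement window is z-scored per voxel with the sample (n−1) standard
  deviation (zero-SD windows become zeros), then windows are
  concatenated in schedule order; each output frame carries its
  statement's narrative type for the restricted analyses. With the
  default design this yields ≈ 570 concatenated frames
  (44 × 16.3 s / 1.26 s).

Note that global-signal regression and per-statement z-scoring both
attenuate genuinely shared signal (the global mean contains it; short
windows whiten slow components). In simulation, a raw within-group ISC
of ~0.55 at a strongly planted voxel drops to ~0.11 after the full
preparation at small scale. This is the faithful behavior of the
prescribed pipeline and is why planted "variance shares" should not be
read as post-denoising correlation magnitudes.

## 4. Peak analysis

Peaks are local maxima of the cohort-average difference map inside the
FDR mask under 26-connectivity; maxima closer than 10 mm (configurable)
are merged keeping the larger difference; coordinates are reported in mm
through the affine. An empty mask yields an empty table (not an error);
a flat map inside a non-empty mask is an error. Subjects are scored at
the single peak voxel (the strictest reading of "peak voxel"); d at a
peak denotes the cohort-average within − between difference there, and
the group difference of means is reported separately. Peak-level
statistics use Student (pooled-variance) two-sample tests throughout —
reproducing the df pattern of a 20/20 design (one-sample df 19,
two-sample df 38, pooled cross-peak df 78) — with
Cohen's d = t·√(1/n₁+1/n₂). The 2×2 group-by-content interaction uses
the classical mixed-design sums-of-squares decomposition, giving df
(1, n−2); for a two-level within factor it equals the squared two-sample
t on the per-subject content differences.

## 5. Behavioral scoring

IAS = mean pro rating − mean anti rating per subject (ratings 1–5, so
IAS ∈ [−4, 4]). The median split labels subjects strictly above the
median more supportive and strictly below less supportive; subjects
exactly at the median are assigned deterministically in ascending
(IAS, subject id) order so group sizes are ⌊n/2⌋/⌈n/2⌉ and every
more-supportive IAS ≥ every less-supportive IAS. An all-equal score
vector is an error (the split is undefined). Reverse-coded items map
v → min + max − v before averaging; Cronbach's α uses sample variances.
Group comparisons use pooled-variance t (consistent with df = 38
reporting at 20/20), FDR-corrected per family (scales, correlations, and
peak-behavior correlations are separate families; the single-item
political-inclination correlation is reported uncorrected by design).
Minimal detectable effects solve the exact noncentral-t power equation.

## 6. The synthetic cohort

The generator draws, per configuration (defaults in parentheses):

- design: two latent groups of `n_per_group` (20); `grid_shape`
  (12×12×12) voxels of `voxel_size_mm` (3 mm); `tr_s` (1.26 s);
  `n_statements` (44, half pro / half anti, random order with at most
  two consecutive same-type statements); statement durations
  N(16.3 s, 2.0 s) truncated at 5 s; inter-statement breaks of 1.5 s +
  16.5 ± 0.5 s uniform jitter (the jitter bound is exposed because the
  protocol specifies only a 16–17 s randomized break).
- signal: voxel classes {common, polarized, null}. A common voxel is
  `√c·c(t) + √(1−c)·ε_i(t)` with `c = common_share` (0.3); a polarized
  voxel is `√g·w(r)·s_g(i)(t) + noise` with `g = group_share` (0.3),
  noise scaled so total variance is 1; null voxels are pure ε. Shared
  processes c, s₁, s₂ are unit-variance Gaussian noise smoothed with a
  6 s-FWHM Gaussian kernel — the correlation-based analysis needs only
  band-limited shared structure, not hemodynamics. ε_i is stationary
  unit-variance AR(1) (`ar1_coef` 0.3), independent across voxels and
  subjects. `group_signal_corr` sets corr(s₁, s₂) (0; −1 gives
  anti-correlated group responses and hence negative between-group ISC
  at planted voxels). A region planted with narrative type pro or anti
  has its group component zeroed outside that type's statement frames,
  mirroring the narrative-restricted analyses.
- **radial taper** `w(r)`: amplitude weight falling linearly from 1 at a
  region's center to `region_edge_weight` (0.8) at its radius. A flat
  share would make the planted difference map constant across the region
  and the peak location noise-determined; the taper makes "one planted
  sphere → one peak at its center" a well-posed recovery target. Set
  `region_edge_weight=1` for flat regions. Sample-moment tests account
  for the taper analytically (the cross-subject covariance at a voxel
  equals the planted share times w²).
- behavior: ratings are discretized Gaussians around per-group pro/anti
  means ((4.5, 1.2) and (3.5, 1.9), SD 0.7), clipped to 1–5 — the
  simplest model giving a median-splittable IAS with group means near
  3.3 and 1.6. Questionnaire items load on a single latent attitude
  (+1/−1 by group plus noise) with per-scale loadings and bounds; FD
  traces stay below threshold except for designated high-motion
  subjects, who get exactly `round(frac_high·n_frames)` frames above it
  so the strict-inequality exclusion rule is exercised at its boundary.
- confounds: random-walk motion parameters with derivatives, the
  volume's actual global mean, white-noise aCompCor stand-ins, Legendre
  trends.

Everything is drawn from one seeded generator: identical configs give
byte-identical cohorts. Ground truth (group labels, voxel classes,
per-voxel expected shares) is carried alongside and consumed only by
tests.

**What the generator does not emulate:** hemodynamic response shapes,
physiological noise, spatial autocorrelation of real fMRI, realistic
head-motion artifacts coupled into the data, non-Gaussian rating
behavior, or missing questionnaire items. Passing recovery tests
therefore demonstrates correctness of the estimators and inference
machinery under the assumed signal model, not performance on real
scanner data.

## 7. Problem sizes and caches

Test and demonstration runs use reduced scales chosen as the smallest
designs that exercise each property: a 6³-grid, 5-per-group cohort for
smoke paths (where the ≤12-subject exhaustive permutation also gets
coverage), an 8³ 20/20 null cohort (512 voxels) for calibration, and the
full default design (20/20, 12³, ≈570 frames, 2000 flips) for
planted-signal recovery. The pipeline caches the permutation stage on
disk keyed by a hash of the scientific configuration (output paths and
cache switches excluded from the hash); cached reruns are byte-identical
to fresh ones.

## 8. Known limitations

- Voxel-wise permutation p-values are anticonservative for this
  estimator (§2); group-level and FDR-level conclusions are the robust
  outputs.
- The whole-sample ISC definition (self included or excluded in the
  average) is ambiguous in the tradition this follows; both variants are
  implemented, leave-one-out is the default.
- Anatomical labels are pass-through text; no atlas lookup or surface
  projection.
- The interaction ANOVA supports exactly the 2 (group) × 2 (content)
  mixed design used here, not general factorial layouts.
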