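# polarisc

**Within- vs between-group inter-subject correlation ("neural
polarization") analysis for naturalistic fMRI.**

When people with opposing attitudes listen to the same charged narrative
— here, spoken pro- and anti-immigration statements — their brain
activity can synchronize more strongly with like-minded listeners than
with the opposing group. `polarisc` implements the full statistical
pipeline for measuring this effect, together with a synthetic-cohort
generator so every stage can be exercised and validated without access
to protected neuroimaging data.

## The method

For subject *i* and voxel *v*, the one-to-average inter-subject
correlation (ISC) is the Pearson correlation between the subject's time
course and the average time course of the other subjects at the same
voxel. The grouped analysis computes, per subject:

- **within-group ISC** `R_w(i,v)` — correlation with the leave-one-out
  average of the subject's own attitude group;
- **between-group ISC** `R_b(i,v)` — correlation with the full average
  of the other group;
- the **polarization difference** `d(i,v) = R_w − R_b`.

The cohort-average difference map is tested voxel-wise with a one-sample
sign-flip permutation test (default 10 000 random ±1 flips of the
per-subject values, one-sided "more positive", add-one p estimator;
exhaustive enumeration of all 2^n flips when n ≤ 12) and thresholded at
q < 0.05 with the two-stage adaptive FDR step-up of Benjamini, Krieger &
Yekutieli. Peaks of the significant difference map are local maxima
under 26-connectivity with a minimum separation of 10 mm, reported in mm
via the image affine.

Around this core the package provides:

- **Behavioral scoring** — the Immigration Attitude Score
  (IAS = mean agreement with pro statements − mean agreement with anti
  statements, range −4..+4), the median split into more/less supportive
  groups, Likert scale scoring with reverse-coded items, Cronbach's α,
  pooled-variance group comparisons with Cohen's
  d = t·√(1/n₁ + 1/n₂), correlations, an OLS linkage model, and
  minimal-detectable-effect power analysis (exact noncentral t).
- **Time-series preparation** — motion-based exclusion (> 25 % of
  framewise-displacement values > 0.5 mm), nuisance regression (6 motion
  parameters + derivatives, global signal, framewise displacement,
  6 aCompCor components, polynomial trends to order 2), 0.01 Hz
  high-pass filtering, and concatenation of per-statement windows with
  per-statement z-scoring.
- **Peak-level statistics** — per-group one-sample tests, group
  contrasts, pooled peak scores, cross-narrative (pro vs anti) paired
  contrasts, the 2×2 mixed-design interaction, and between-group-ISC
  sign comparisons.
- **A synthetic cohort generator** — 40 subjects in two latent attitude
  groups of 20, 44 statements (22 pro / 22 anti, ~16.3 s each) at
  TR = 1.26 s, voxels mixing a cohort-common component, a group-specific
  component (the planted polarization, optionally active only during one
  narrative type), and subject-specific AR(1) noise, plus ratings,
  multi-item questionnaires, motion confounds and FD traces. Ground
  truth is stored alongside the data and never read by analysis stages.

## Worked example

```python
from polarisc import (SimulationConfig, RunConfig, generate_cohort,
                      prepare_cohort, compute_ias, median_split,
                      grouped_isc, run_inference)
from polarisc.peaks import extract_peaks, score_peaks, pooled_peak_contrast

cfg = SimulationConfig(seed=11)            # 20/20 subjects, 12^3 grid
cohort = generate_cohort(cfg)
rc = RunConfig(simulation=cfg, n_perm=2000, seed=1)
prepared, kept, excluded = prepare_cohort(cohort, rc)

assignment = median_split(compute_ias(cohort.ratings))
maps = grouped_isc(prepared, assignment)
report = run_inference(maps, n_perm=2000, seed=1)
peaks = extract_peaks(maps.average_diff, report.fdr.mask,
                      prepared[0].grid, p_values=report.permutation.p)
pooled = pooled_peak_contrast(score_peaks(maps, peaks))
```

This prints (via the obvious `print` statements):

```
median IAS: 2.27 | group sizes: {'more_supportive': 20, 'less_supportive': 20}
FDR-significant voxels (q<0.05): 87 of 1728
 x_mm  y_mm  z_mm     d     p
  9.0   9.0   9.0 0.273 0.000
 21.0  27.0  24.0 0.188 0.000
pooled peak contrast: t(38) = -0.938, p = 0.354, d = -0.297
```

Reading the output: the synthetic raters split 20/20 at a median IAS of
2.27; the permutation + FDR stage flags 87 voxels where within-group
synchrony exceeds between-group synchrony; the two strongest peaks sit
at the centers of the two planted regions (d is the average within −
between R difference at the peak voxel); and the pooled peak score does
not differ between the groups — as expected, since this cohort's planted
polarization is symmetric across groups.

The same run is available from the shell:

```bash
polarisc run-all --out results/demo --seed 11
```

which writes average-R/difference/p/q maps (NIfTI), peak tables (TSV),
behavioral reports (CSV/JSON) and a checksummed `manifest.json`; reruns
with the same configuration are byte-identical.

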