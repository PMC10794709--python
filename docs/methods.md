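# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the study conditions used by the validation
tests. It is the package's own account of its science; empirical
statements here are exactly those the test suite computes.

## Experimental design

Ten conditions arise from crossing sample numerosities {6, 12, 24, 48}
with operations {multiply, divide} and operands {2, 4}, keeping only
combinations whose exact result is again in the numerosity set (the
"closure rule"). This enumeration is validated by its consequences:
it yields exactly 10 conditions (5 multiplications, 5 divisions), and
the log-scale sample- and result-distance predictors built on it
correlate at r = −0.34 and are *exactly* equally correlated with the
operation predictor — the design symmetry the paradigm exploits.

Trials last 20 s: dot sample at 0 s, operation cue at 2 s, probe at
12 s on standard trials; 20 % catch trials draw the probe SOA
uniformly from [5.4, 9.6] s to force immediate computation and are
modeled but never analyzed. Each run holds 2 standard trials per
condition plus 4 catch trials; 6 runs per subject (configurable 6–8);
TR = 2 s. Runs end with a 10 s rest period. The rest period is a
deliberate design element: with back-to-back 20 s trials and a 20 s
FIR window the condition × bin stick regressors would tile every
volume and sum exactly to the run constant, making the GLM singular;
a short rest restores full rank (and is what the slack in a "~8 min"
run provides in practice).

Predictor matrices: sample/result hold |log(a) − log(b)| (base 2 by
default; all downstream quantities are invariant to the base because
every vector is z-transformed), operation/operand hold 0/1 category
mismatch (any positive constant is equivalent after the z-transform).

## Synthetic BOLD generator

Each attribute a ∈ {sample, operation, operand, result} has a
unit-norm voxel weight vector w_a, a trapezoidal neural envelope
e_a(t) over post-sample seconds, and an amplitude A_a. Trial signal:

    s(t, v) = Σ_a A_a · w_a(v) · x_a(condition) · [e_a ⊛ h](t − onset)

where h is a canonical double-gamma HRF (peak 5 s, undershoot 15 s,
ratio 6) and x_a is the attribute value: z-scored log numerosity for
sample/result (so coded magnitude is monotone in log numerosity, the
same scale the decoder uses as labels) and ±0.5 contrasts for
operation/operand. The convolved response is truncated at the trial
boundary, so the injected ground truth lies exactly in the span of
the FIR sticks; this is what makes the noiseless-identity contract
("the GLM recovers injected bin amplitudes to numerical precision")
exact rather than approximate. Probe-evoked responses are not
simulated: all analysis windows precede the standard-trial probe.

The result-code direction is constructed as
w_res = s·w_samp + √(1−s²)·w⊥ with s = `subspace_share`, so the
cosine between sample and result codes equals the share exactly;
s = 1 is a fully shared representational space, s = 0 fully separate
subspaces. Noise is stationary AR(1) (ρ = 0.3, marginal σ = 1) plus
random slow cosine drift (3 components, σ = 0.5).

**Envelope and amplitude defaults.** The envelopes are chosen so that
the *BOLD-level* code (envelope ⊛ HRF) peaks where the analysis
expects it: the sample envelope is a brief bump over 0–2 s (BOLD peak
in FIR bins 3–4, the middle window), the result envelope a sustained
ramp from 3.5–9 s after the cue (BOLD peak in bins 5–6, the late
window). Default amplitudes are 0.40 (sample) and 0.16 (result) in
noise-σ units — per-voxel signal-to-noise below 0.5, and group-level
effect sizes at n = 17 of t ≈ 5–9 for the sample and t ≈ 4–8 for the
result code, i.e. a strong stimulus-evoked code and a weaker internal
one, matching the qualitative pattern such experiments report.
`calcmvpa.scenarios` freezes the variants used by the validation
studies (matched-SNR decoding scenario; brain–behavior cohort).

**What the generator does not emulate:** spatially correlated and
physiological noise, trial-to-trial pattern variability, motion,
nonlinear BOLD summation, subject anatomy. Passing recovery tests
therefore demonstrates the *correctness of the estimators under the
stated model*, not performance on real 7T data.

## FIR GLM

One 0/1 stick per condition × bin (10 + catch conditions × 10 bins of
2 s), a constant per run, a discrete-cosine drift basis with 244 s
cutoff per run (the standard implementation of the stated cutoff),
and optional confound columns. Estimation is OLS per voxel
(`numpy.linalg.lstsq`); rank deficiency raises an error naming the
collinear columns. Optional AR(1) prewhitening (single pooled ρ,
Cochrane–Orcutt within run) is off by default: OLS is unbiased, and
the downstream representational analyses are invariant to whitening;
the flag exists for fidelity experiments. Modes: `concatenated` (one
estimate set per subject, input to RSA) and `per_run` (input to the
leave-one-run-out decoder).

## RSA regression

Per bin and voxel set: subtract each voxel's mean across the 10
conditions, distance = 1 − Pearson correlation across voxels,
vectorize the 45 strict-upper-triangle entries, z-transform the
neural vector and each predictor vector, OLS with intercept. The
intercept is included (with both sides z-scored it is ≈ 0, so the
choice is immaterial, but it makes the fit invariant to the neural
vector's mean). Degenerate patterns (zero variance after centering)
propagate as missing entries; searchlight centers with missing
entries or fewer than 2 in-mask voxels are skipped and logged, never
imputed. The searchlight sphere uses Euclidean offsets ≤ radius
(boundary and center included; 123 voxels at radius 3). Windows:
early = mean(bins 1–2), middle = mean(bins 3–4), late = mean(bins
5–6), bins 1-based with bin k covering (k−1)·2 s to k·2 s.

**A structural property worth knowing.** In the noise-dominated
regime the expected neural RDM is approximately a negative Gram
matrix of the coded values (−x_i·x_j), not a linear |Δlog| distance
matrix. Regressing that structure on the four predictors puts a
deterministic loading on the *operation* predictor of about 0.18 per
0.80 on the own-attribute predictor, because operation is partially
confounded with numerosity magnitude (multiplications produce large
results, divisions small ones) — the design can reduce but not remove
this. Consequently, whenever an embedded numeric code is strongly
detected, a small positive operation beta (≈ 0.2× the main effect) is
*expected* even though no operation code exists. The validation
suite's specificity check documents this honestly: the operand
predictor (nearly orthogonal to the numeric predictors) stays at the
nominal false-positive rate, while the operation predictor exceeds it
in proportion to the embedded-code SNR. On truly null cohorts all
four predictors are calibrated.

## Cross-decoding

Linear SVR (C = 1, ε = 0.1; ε is a conventional default, the analysis
is insensitive to it) trained on run-wise patterns voxel-wise z-scored
across conditions *within each set* (train and test scaled
independently; a flag applies train statistics to the test set
instead). Labels: z-scored log numerosity of sample or result.
Leave-one-run-out CV; fold score = Fisher-z(Pearson(true, predicted)),
clipped away from |r| = 1; folds with constant predictions score 0 so
subject averages stay defined. The sample↔result score averages the
6 cells per direction with sample bin ∈ {2,3,4}, result bin ∈ {4,5,6},
non-overlapping, ≥ 1 intervening bin — and both train directions.

## Psychophysics

P(larger) = λ + (1−2λ)·Φ((log ratio − PSE)/σ), ML fit under a
binomial likelihood with a deterministic 3-start L-BFGS-B scheme
(σ bounded in [10⁻³, 20]; boundary estimates are flagged and warned
about). λ is fixed at 0 by default (free behind a flag). JND =
σ·Φ⁻¹(0.75) on the log-ratio scale and is identified with the Weber
fraction. Operational momentum: paired two-tailed t-test of
division-PSE vs multiplication-PSE with Cohen's d.

## Group statistics

Two-tailed one-sample t-tests (df = n−1); BH-FDR step-up with the
family being all inputs (e.g. ROIs × windows); cluster correction by
sign-flip permutation on the voxel grid: 6-connected components of
|t| above the two-tailed p < 0.01 forming threshold, separate
positive/negative searches against a shared null of the maximum
cluster *extent* over both signs, p_FWE = (1+#{null ≥ obs})/(n_perm+1)
(never 0, lower-bounded by 1/(n_perm+1)). Extent is used as the
cluster statistic as the volumetric analog of reported cluster sizes.
Brain–behavior: per-ROI Pearson r between subject cross-decoding
scores and Weber fractions, p from the exact t transform of r,
BH-FDR across ROIs.

## Validation study conditions

Chosen once, as the package's study design:

* **RSA recovery:** 17 subjects, 80-voxel ROI, 6 runs, default
  amplitudes, subspace_share 0; canonical cohort plus 10 replicate
  cohorts; null calibration on 200 zero-amplitude cohorts (40 voxels)
  with a 99 % binomial interval (four simultaneous per-predictor
  checks).
* **Decoding:** matched sample/result amplitudes (0.5/0.5) with a
  sharpened sample envelope (0–1.2 s) so little stimulus-evoked
  signal persists into the result test bins; 60-voxel ROI; 5 subspace
  levels × 20 seeds with common random numbers.
* **Brain–behavior:** subspace_share 1, base amplitudes 1.0, 150-voxel
  ROI; per-subject SNR factor uniform on [0.25, 2.2] scaling the
  result amplitude and scaling the Weber fraction as 0.29·f^−0.8 with
  2 % lognormal jitter; 500 comparison trials per subject.
* **Psychometrics:** 20 observers × 10,000 trials for recovery;
  100 equal-shift cohorts (17 × 160 trials) for momentum type-I with
  a 95 % binomial interval.
* **Cluster permutation:** 150 null cohorts of 17 spatially smoothed
  maps (Gaussian σ = 1.5 voxels on a 12³ grid — searchlight maps are
  intrinsically smooth, and on unsmoothed white noise the extent null
  is so discrete that the test becomes extremely conservative) at 200
  permutations, 95 % binomial interval around 0.05.
* **Full pipeline defaults:** 17 subjects, 20×20×20 grid, 7³-voxel
  coding and control ROIs, 6 runs, searchlight radius 3, 200
  permutations. The end-to-end run completes on a single CPU well
  within ordinary desk-scale budgets; tests exercise a scaled-down
  configuration (3–6 subjects, 8³ grids) for speed.

## Known limitations

* The operation-predictor leakage described above is a property of
  correlation-distance RSA on this design, not of the implementation;
  analyses of real data carry the same caveat.
* The simulator's noise model is white across voxels; spatial
  smoothness enters only through the searchlight's overlapping
  spheres.
* SPM's exact drift/whitening internals are not reproduced; the GLM
  contracts are asserted at the level of OLS identities and high-pass
  attenuation (a > 244 s sinusoid is ≥ 90 % removed).
* The psychometric model has no lapse by default; strongly lapsing
  observers would bias the JND downward-weighted fits.
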