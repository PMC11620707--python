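# Methods

`semdecode` implements, on fully synthetic data, the analysis chain used to
ask whether word semantic categories (tool nouns vs. animal nouns) can be
decoded from voxel activity patterns in brain regions engaged by tool-use
planning. This note documents the generative model, the analysis procedure,
the numerical choices, and what the synthetic validation does and does not
show about real data.

## Experimental designs being simulated

**Semantic priming / lexical decision.** Five target conditions — Tool
Primed, Tool Unprimed, Animal Primed, Animal Unprimed, Pseudoword — over 84
trials (14 prime–target pairs per word condition, 28 pseudoword pairs). A
trial is fixation (0.5 s), prime (0.3 s), target (0.5 s), with a 2 s
response deadline from target onset and an inter-trial interval drawn
uniformly from 5–7 s. The GLM models 0.8 s from prime onset per condition;
the remaining 1.5 s response window is a nuisance regressor. Primed pairs
use two different words of the same category; unprimed pairs cross
categories; pseudoword primes alternate between tool and animal nouns.

**Lexicon.** 70 tool and 70 animal nouns are drawn with imageability and
(for tools) manipulability ratings of at least 5 on a 7-point scale.
Psycholinguistic covariates are synthetic: written frequency is lognormal
(log-mean 1.0, log-SD 0.8), letter/syllable/neighbor counts are shifted
Poisson — only the matching constraint matters to the analysis, not the
marginals. Each category is split into 5 lists of 14 (2 target lists, 3
prime lists). Lists are matched on log frequency, letters, syllables and
neighbors: a serpentine deal over a composite score followed by hill-climbed
item swaps, accepted when the spread of the 10 list means is below 0.25
pooled SD per variable. Smaller lexicons cannot be balanced as finely — a
single item moves a 5-item list mean by ~0.2 SD — so the bound scales as
14/(items per list). Matching failure after 20 redraws raises an error
naming the worst variable.

**Motor task.** Per run: 4 s planning – 4 s execution – 4 s planning – 4 s
execution – 10 s rest, repeated 15 times (390 s), one effector (tool or
free hand) per run. Planning and execution get regressors; rest is the
implicit baseline (modeling all three phases would tile the run and be
exactly collinear with the intercept).

## Generative model of the BOLD signal

Voxel time series are

    y(v, t) = baseline + sum_c a_c(v) * (boxcar_c * h)(t) + e(v, t)

with `h` the canonical double-gamma HRF (peak delay 6 s, undershoot delay
16 s, unit dispersions, peak:undershoot ratio 6, 32 s support,
peak-normalized), the same forward model the GLM assumes, and `e` AR(1)
Gaussian noise (coefficient 0.3, marginal SD 1.0 by default; real fMRI
noise is not described by the source protocol, so this is a deliberately
simple stand-in). TR is 2.4 s; regressors are built on a 0.1 s micro-time
grid and sampled at frame times. Run length is the design duration rounded
up to whole volumes.

Amplitudes `a_c(v)` are zero outside the configured ROIs. Inside an ROI:

- **Semantic conditions.** Each *subject* receives its own four voxel
  templates drawn from the matrix square root of the 4x4 target correlation
  matrix (within-category pairs `rho_within`, across-category pairs
  `rho_across`; infeasible, non-PSD combinations are rejected), scaled by
  `amplitude_scale` (default 1.5, i.e. 1.5x the noise SD — a strong but
  plausible per-condition response after 14-trial averaging) and shifted by
  per-condition `mean_offsets`. Templates are drawn per subject because
  subjects' fine-grained voxel patterns are not aligned across brains at
  this scale; sharing one template set across subjects would also make the
  sign-flip null miscalibrated (a shared sample-correlation fluctuation of
  order 1/sqrt(V) would shift every subject's score identically). Templates
  are de-meaned across voxels so ROI-mean condition differences are
  controlled solely by `mean_offsets`.
- **Motor conditions.** Scalar amplitudes per phase x effector regressor
  (defaults 1.5/0.75 planning tool/hand, 1.0/1.0 execution), i.e. a planted
  tool-planning interaction of 0.75 amplitude units.

Two further sources of between-subject variability make the group-level
geometry realistic rather than degenerate:

- **ROI position jitter** (default ±1 voxel per axis, per subject, clamped
  to the grid): functional anatomy varies across subjects.
- **Background motor amplitude fields**: each subject gets a smooth
  (8 mm FWHM) zero-mean amplitude field, SD 0.15, added grid-wide to every
  motor regressor. Without this variance floor, the only between-subject
  variability at task-free voxels is first-level estimation noise
  (~0.002 after smoothing), and the deterministic smoothing tail of the
  planted signal stays "significant" for several voxels beyond every ROI,
  merging all clusters into one. The floor caps the attainable group t and
  keeps clusters compact, which is how real second-level maps behave.

**Behavior.** RTs are lognormal with subject random intercepts (log-SD
0.195, chosen so between-subject SEMs at n=20 match the reported 37–43 ms)
and trial noise (log-SD 0.15), mean-parameterized so condition means equal
their targets (945/1017/901/962 ms for TP/TU/AP/AU; 1050 ms pseudowords) in
expectation. Responses beyond the 2 s deadline are omissions (missing RT,
accuracy 0). Errors are Bernoulli (3.7% tool, 0.9% animal, 5% pseudoword).
Mixed-model fitting of behavior is out of scope; the package computes
descriptive summaries and within-subject paired contrasts.

## Analysis chain

1. **First level.** Voxelwise OLS on the condition design (plus nuisance
   and optional cosine drift columns; no prewhitening — the AR(1) noise
   model is simulation-side only). Motor runs are smoothed at 8 mm FWHM;
   the semantic run is fit twice conceptually, but only the non-smoothed
   fit is used downstream (patterns must not be spatially mixed).
   Zero-residual-variance voxels are flagged and given t = 0 rather than
   dropped, preserving voxel alignment across subjects.
2. **Second level.** The subject-level tool-planning interaction contrast
   (planning tool − planning hand) − (execution tool − execution hand) is
   tested with a voxelwise one-sample t (right-tailed p). This is exact for
   1-df within-subject contrasts, which is all the chain reports.
3. **Clusters and ROIs.** Suprathreshold voxels (p < 0.001) minus voxels
   significant in the exclusive mask (execution hand > execution tool at
   p < 0.05) are grouped by 18-connectivity (6/26 available); components
   with strictly more than 10 voxels become ROI masks, named by their
   overlap with the configured layout. No random-field-theory correction is
   applied; the report is cluster-forming threshold + extent only.
4. **MVPA.** For each subject the condition-vs-baseline t values at the ROI
   voxels (fixed lexicographic order) form the patterns. Cosine
   similarities of the six condition pairs are reduced to three contrasts:
   (1) mean within-category minus mean across-category similarity;
   (2) tool within-pair minus the mean of the five other pairs;
   (3) animal within-pair minus the five other pairs.
   Patterns enter cosine similarity raw (no demeaning beyond cosine's own
   scale invariance).
5. **Inference.** The group mean contrast score is tested right-tailed by
   sign-flipping subject scores (default 10,000 draws; exhaustive 2^n
   enumeration available for n ≤ 20), with
   p = (1 + #{null ≥ observed}) / (1 + N) so p ∈ (0, 1] and ties count
   conservatively. Benjamini–Hochberg FDR is applied across the ROIs tested
   within each contrast family (the family is configurable).
6. **Follow-up.** Wherever contrast (1) survives FDR, ROI-mean signal per
   condition enters a 2x2 within-subject ANOVA computed from per-subject
   1-df contrasts (F = t², df (1, n−1) — exact for this design), with
   BH-corrected paired post hocs over the four simple effects.

## Design choices made where the design was open

- **Contrast (3)** as commonly printed subtracts four pairs but divides by
  5, so its weights do not sum to zero; the default here includes the fifth
  pair (AnimalPrimed/ToolUnprimed), mirroring contrast (2)'s symmetric
  structure. The literal four-pair form is available via
  `literal_three=True`.
- **P-value rule.** The raw proportion of null values above the observed
  score can be 0; the (1+k)/(1+N) correction guarantees a valid p.
- **FDR family** defaults to the ROIs tested within one contrast.
- **Trial order** is unconstrained uniform shuffling (no repetition
  limits), per subject.
- **Cluster connectivity** defaults to 18 (faces + edges).
- **High-pass filtering / autocorrelation handling** at first level: off by
  default, cosine drift columns available.

## Problem sizes used in validation

The repeated end-to-end recovery study (`pipeline.validation_config`) uses
a 16x16x8 voxel grid with a 76-voxel planted ROI (rho_within 0.6,
rho_across 0, unprimed-tool offset 0.5) and a 48-voxel structure-free ROI,
2,000 permutations, and otherwise the full study conditions (20 subjects,
84 trials, 15 motor repetitions). One hundred such runs make up the
recovery study; the default configuration (22x22x12 grid, ROI sizes 150/76/28,
10,000 permutations) is used for single worked examples. Calibration
checks run at the pattern level (20 subjects x 76 voxels, 999 or 2,000
permutations, ≥1,000 replicates), where the null is exactly the generator's.

## What passing tests do and do not show

The generator reproduces the design structure, the forward model the GLM
assumes, and controllable pattern-similarity structure — so the tests
demonstrate that the chain is *correct* (oracle equivalence), *calibrated*
(type-I error of the permutation test and of the voxelwise second level),
and *sensitive* (planted structure is recovered end-to-end). They do not
show that real fMRI data satisfy the model: real noise is not AR(1) with
white spatial structure, real pattern similarity is far weaker (reported
similarity differences are of order 0.006, two orders below the planted
effects here), preprocessing (motion, distortion, normalization) is not
modeled, and anatomical variability is reduced to integer ROI jitter.
Effect magnitudes printed by this package are therefore not comparable to
published values; only the procedure and its operating characteristics are.

## Known limitations

- No FWE/RFT cluster correction, searchlight mapping, or cross-validated
  decoding.
- OLS without prewhitening slightly misstates first-level SEs under AR(1)
  noise; downstream inference is permutation-based or second-level, so
  group calibration is unaffected (verified empirically).
- The behavioral generator omits sequential effects, fatigue and
  speed–accuracy trade-offs.
- `simulate_behavior`'s truncation at the 2 s deadline biases observed
  condition means downward by a few milliseconds for the slowest condition.
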