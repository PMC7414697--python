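# Methods

## Problem setting

Diabetic retinopathy (DR) grading assigns each fundus photograph one of
five ordered severity stages (0 = no DR … 4 = proliferative DR). Unlike
generic multiclass classification, the classes carry a distance: predicting
grade 3 for a grade-4 eye is a far smaller error than predicting grade 0.
Expert annotations reflect the same structure — when two graders disagree,
they almost always disagree by a single grade. Hard one-hot training
targets discard this structure, and the standard cross-entropy penalizes
all wrong classes identically.

`ordsmooth` implements and evaluates a label-encoding remedy: replace the
one-hot target with a discretized Gaussian centered on the annotated grade.

## Label encodings

For a K-grade scale and annotated grade g:

* **hard** — the one-hot vector `e_g`.
* **uniform (ULS)** — classic label smoothing,
  `q_j = (1 − α)·[j = g] + α/K`. The redistribution term divides by the
  number of classes K so the target sums to exactly 1.
* **gaussian (N-ULS)** — `q_j` is the mass of `Normal(g, σ²)` in the unit
  bin `[j − 0.5, j + 0.5]`. Unit-bin integration (rather than sampling the
  density) is used because it makes the neighbor-mass statement below exact
  and produces the expected missing probability at the scale ends.

The decay factor σ is chosen so that a target fraction m (default 0.95) of
the Gaussian's mass falls within ±1.5 grade units — the three bins covering
the annotated grade and its two immediate neighbors. This has the closed
form σ = 1.5 / Φ⁻¹((1 + m)/2) ≈ 0.7653 for m = 0.95 (the implementation
uses `scipy.special.ndtri`, exact to machine precision; the tests verify it
against an independent `brentq` root-find on the normal CDF).

At the corner grades (0 and K−1) part of the Gaussian extends past the
scale. By default that mass is dropped — the label sums to < 1 — so the
mass kept on the annotated grade itself is identical for every grade. A
`renormalize` flag rescales corner labels to unit sum instead; it is off by
default because renormalization would give corner grades a larger "degree
of truth" than interior ones. Note the unnormalized corner labels retain
*less* than m total mass (≈ 0.74 at the default m = 0.95), because the
truncated region includes part of the neighbor interval; interior labels
always retain at least m.

## Loss

Training minimizes the soft-target cross-entropy
`L(p, q) = −Σ_k q_k log p_k` with p the softmax output. The loss is linear
in q, so unnormalized Gaussian targets are consumed without rescaling; the
gradient with respect to the logits is `p·(Σ_k q_k) − q`, which the NumPy
trainer implements directly (verified against central finite differences
to 1e-5). Probabilities are clamped at 1e-12 before the log.

## Evaluation protocol

All statistics are computed from a per-sample score table; the predicted
grade is the arg-max of the score vector, with ties resolving to the
lowest (least severe) grade for determinism.

* **Quadratic-weighted κ** — chance-corrected agreement with penalties
  `w_ij = (i−j)²/(K−1)²`; the headline metric, since it rewards errors that
  stay close to the true grade. Degenerate tables (zero expected
  disagreement) raise an explicit error rather than returning a number.
* **Pairwise-averaged multiclass AUROC** (Hand–Till): for every unordered
  class pair present in the data, the Mann–Whitney AUROC of each class's
  score within the pair, averaged both ways, then averaged over pairs; ties
  count ½. Only pairs with both classes present are used (the stratified
  bootstrap guarantees presence in the main protocol).
* **Support-weighted precision / recall / F1** — per-class scores averaged
  with weights proportional to true-class support; a class never predicted
  contributes 0 to its precision term (with a warning) so the average stays
  defined on degenerate resamples.
* **Multiclass MCC** — the R_K correlation statistic of the confusion
  matrix; defined as 0 when a marginal variance vanishes.

Every metric is tested to 1e-12 against a brute-force definitional
implementation (explicit double loops, exhaustive pair counting) on 200+
random instances, and cross-checked against scikit-learn.

## Significance testing

Two models scored on the same test set are compared by a paired stratified
bootstrap: each of n = 1000 replicates resamples indices with replacement
*within each true-grade stratum* (per-grade counts are preserved exactly —
essential when the rarest grade is ~0.6% of the data) and applies the same
index set to both models. The per-replicate metric differences Δ* give a
two-sided percentile p-value with add-one smoothing,
`p = min(1, 2·min(#{Δ* ≤ 0}+1, #{Δ* ≥ 0}+1)/(n+1))`, so p is never 0 and
equals 1 for identical models. Decisions use the Bonferroni-corrected
level α/n_comparisons = 0.05/2 = 0.025 for the standard design of two
comparisons (gaussian vs hard, gaussian vs uniform). Each replicate draws
from its own spawned seed stream, making reports bit-reproducible.

The paired construction (one index set for both models) is a design choice:
independent resamples per model would inflate the variance of Δ* and no
longer test the models' difference on common data.

## Synthetic cohort generator

The generator emulates the statistical structure of a large DR screening
cohort at desk scale:

* **Prevalence.** Grades are drawn i.i.d. from the gradable-image census of
  a 46,865-image screening cohort: counts 31447 / 1264 / 6822 / 230 / 683
  for grades 0–4, i.e. prevalences ≈ 0.778 / 0.031 / 0.169 / 0.006 / 0.017.
  Ungradable images (13.7% of the cohort) are excluded, mirroring the
  grading task. The imbalance is severe: the majority grade outnumbers the
  rarest by ~137:1.
* **Features.** Vector mode (default): each of `feature_dim = 4` dimensions
  equals the clean grade plus independent `Normal(0, severity_noise_sd²)`
  noise. `severity_noise_sd = 1.4` grade units is calibrated so that a
  hard-label baseline classifier reaches a test quadratic-weighted κ in the
  low 0.7s against clean grades — the agreement level typical of automated
  fundus grading — rather than an unrealistically clean separation. Image
  mode: a 32×32 circular fundus-like field with Poisson(1 + 3·grade)
  small bright lesion-like blobs plus pixel noise, clipped to [0, 1]; the
  small_net consumes these after a fixed 4×4 average-pooling downsample
  (a deliberate simplification of a convolutional stack — at this image
  size pooled intensities already carry the lesion-load signal).
* **Annotator noise.** Each training label is perturbed with probability
  `annotator_noise_rate = 0.3`; a perturbation moves ±1 grade with
  probability `neighbor_bias = 0.9` (direction uniform, reflected at the
  scale ends) and otherwise jumps to a uniform non-neighbor grade. This is
  the neighbor-concentrated disagreement structure observed between human
  graders.
* **Splits.** Stratified by clean grade into 75/10/15% train/validation/
  test via floor allocation with remainders assigned train-first; every
  grade must have ≥ 3 samples.

What the generator does **not** emulate: photorealistic retinal texture,
camera and illumination artifacts, grader-specific bias, multi-grader
panels, or the ungradability category. Passing the end-to-end tests
therefore shows that the label-smoothing machinery behaves as designed on
data with the assumed ordinal-noise structure — not that the same effect
sizes would be observed on real fundus photographs.

## Trainer

A deliberately small, dependency-free NumPy harness stands in for the large
pretrained convolutional networks used in production systems: a linear
softmax model (default) or a one-hidden-layer (32-unit tanh) perceptron,
optimized by plain mini-batch SGD with learning rate 0.001 and batch size
8. Smoothing applies to the (noisy) training targets only; the validation
monitor and all test evaluation use hard labels. Early stopping monitors
the validation cross-entropy with patience 5 and restores the best-epoch
parameters; `max_epochs = 200` is sized so that, at desk scale, training
runs to convergence and the patience rule — not the epoch cap — is the
intended stopping criterion. Initialization is seeded Gaussian
(1/√fan-in); no momentum or weight decay by default. Fixed seeds make
histories bit-identical across runs.

## The three-arm experiment

`run_experiment` draws one cohort, trains the hard (CE), uniform (LS,
α = 0.1) and gaussian (N-ULS) arms on the identical splits and seed,
evaluates all six metrics on the test split against the *clean* grades
(the synthetic generator makes the ground truth available — the analogue
of an adjudicated reference standard), and runs the paired bootstrap for
N-ULS vs CE and N-ULS vs LS. α = 0.1 for the uniform arm is the
conventional smoothing amount in the image-classification literature; it
is exposed in the config. At the defaults (n ≈ 2000 training samples) the
desk-scale mechanism is visible directly in the confusion matrices:
hard-label training collapses the rare grades (they are never predicted),
while Gaussian targets recover them with errors concentrated on adjacent
grades — which is exactly what the quadratic-weighted κ rewards. Across
10 seeds at the defaults, N-ULS matches or beats CE on test quad-κ in
10/10 runs (means ≈ 0.80 vs 0.73); uniform smoothing does not help
(mean ≈ 0.73). Desk-scale N-ULS trades some support-weighted recall/F1/MCC
for this consistency gain (the rare-grade predictions introduce
majority-class errors); the κ and AUROC gains dominate in the headline
comparison.

## Numerical conventions

* σ solver: closed-form inverse normal CDF (no iteration, exact).
* Arg-max ties → lowest grade; deterministic.
* Zero-division in per-class precision/recall → 0 with a warning.
* Degenerate κ / AUROC inputs raise `UndefinedMetricError`; degenerate MCC
  returns 0 by convention.
* Score CSVs serialize at 17 significant digits and are read back with
  round-trip float parsing, so write→read is lossless.
* Seeds: every stochastic component (grades, features, noise, splits, SGD
  shuffling, bootstrap replicates) draws from its own `SeedSequence`
  stream derived from the user-facing seed.

## Problem sizes

Default desk-scale settings — 2,667 samples (≈ 2,000 train), linear arms,
1000 bootstrap replicates — run the complete three-arm experiment in under
half a minute on one CPU core, and the 10-seed directional study in about
two minutes.
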