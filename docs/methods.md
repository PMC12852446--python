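# Methods

`ssmboost` trains binary clinical-risk classifiers as boosting ensembles
whose weak learner is a gated state-space block over the feature sequence of
a tabular row, with ensemble paradigm and hyperparameters chosen by
Gaussian-process Bayesian optimization, SMOTE class balancing inside
training folds, stratified k-fold evaluation, and Shapley-value explanation.
This note records the model, the numerical choices, and what the synthetic
study design does and does not establish.

## The weak learner

A row of d features is read as a length-d sequence, one feature per position,
in the column order fixed at fit time. Each scalar x_k is embedded by a
per-position affine map into c channels. The embedded sequence E passes
through a gated block

    M(E) = LayerNorm( SSM(E W_proj) + GELU(E W_gate) ),

is mean-pooled over positions, and read out to a single logit. The SSM is the
linear dynamical system h' = A h + B x, y = C h, run independently per channel
along the feature axis so the scan mixes information across columns — the
mechanism intended to capture long-range dependencies among features.

Numerical choices:

* **Stability.** A is diagonal with entries −softplus(a_raw), so every
  eigenvalue is strictly negative without constrained optimization. Raw
  entries are initialized so the diagonal starts in [−2, −0.5].
* **Discretization.** Zero-order hold: Ā = exp(ΔA),
  B̄ = expm1(Δa)/a · B elementwise for diagonal A (limit Δ·B as a → 0);
  for full A the augmented matrix exponential exp(Δ·[[A,B],[0,0]]) yields
  both blocks without inverting A, so singular A is handled exactly.
* **Step sizes.** Δ is per-channel, parameterized softplus(δ_raw) and
  initialized log-spaced in [0.01, 0.1].
* **Selectivity is not implemented.** The dynamics are time-invariant; the
  input-dependent Δ/B/C of the full selective-scan architecture is omitted.
  The gating branch provides the input-dependent modulation here. This is a
  deliberate simplification: the printed model equations specify only the
  time-invariant system plus gating.
* **Training.** Weighted binary cross-entropy, full-batch Adam
  (default learning rate 0.02, 200 epochs, early stop after 20 epochs
  without improving the running-best loss), gradients derived by hand and
  verified against central finite differences to 1e-4 relative error in the
  test suite. Fits are deterministic per seed. Single-class folds yield a
  flagged constant-logit learner.
* Features are standardized inside the learner on its own training data
  (floor 1e-8 on the scale), so the learner composes safely outside the CV
  harness too.

## The boosting engine

Labels are {0,1} at every public boundary and mapped to {−1,+1} internally.
Three paradigms share one registry of base learners:

* **ada** — discrete AdaBoost. Round t fits a learner under weights w (a
  probability vector), computes the weighted error ε_t of its hard ±1
  predictions, sets α_t = ½ ln((1−ε_t)/ε_t), and updates
  w_i ∝ w_i exp(−α_t y_i ŷ_i). Misclassified samples gain weight. A round
  with ε ≥ 0.5 is retried up to 3 times with fresh learner seeds, then the
  loop stops early. ε ∈ {0,1} caps α at ±½ ln((1−1e−10)/1e−10) and ends the
  run (a perfect round leaves nothing to reweight).
* **gbm** — stagewise additive modeling of the logistic loss. Each round
  fits the sign of the pseudo-residuals (weights ∝ |residual|), line-searches
  a scalar step by bounded minimization, and adds η_lr · step · h_t(x). The
  training loss is non-increasing because the step is a convex combination of
  0 and the per-round optimum.
* **rf** — bagging: B learners on bootstrap resamples (per-learner seeds by
  fixed offsets from the master seed), scores averaged on the probability
  scale and reported as logits.

Base learners pass through an adapter layer: the native gated-SSM learner
and a deterministic decision stump (threshold sweep over strictly increasing
gaps, both polarities, ties to the lowest feature index and threshold), plus
XGBoost, LightGBM, randomized and depth-limited CART trees, and a logistic
model backed by scikit-learn. Sample weights are handed to base learners
scaled to mean one: tree libraries compare hessian sums against
`min_child_weight`-style constants, and simplex-normalized weights would
prune every split.

## Hyperparameter and mode selection

A Matérn-5/2 Gaussian process with fitted noise models Perf(configuration),
where Perf is the mean inner-CV AUC. Continuous dimensions are rescaled to
the unit cube (log scale where declared); categoricals are one-hot encoded
with per-dimension length scales. Expected improvement is maximized over 256
random candidates plus local Gaussian refinement. The initial design uses
quasi-random (Sobol) draws for continuous dimensions and cycles the
categorical product deterministically, so a budget of 6–8 evaluations still
touches every (mode × base learner) cell — with uniformly random categoricals
at these budgets, whole grid cells would often go unexplored. Histories from
earlier runs can warm-start the surrogate; already-observed configurations
are skipped in the design.

Mode selection uses the softmax rule P(mode) ∝ exp(η_sens · Perf) with
η_sens ∈ [1e−5, 0.1] (near-uniform at the lower bound). During search the
mode is one categorical dimension of the GP space; the softmax probabilities
over per-mode best Perf are computed and reported with each run, and the
final model uses the argmax configuration — consistent, since the argmax of
the softmax is the argmax of Perf. The two η symbols are kept apart
everywhere as `eta_lr` (gbm shrinkage) and `eta_sens` (softmax sensitivity).

## Class imbalance

SMOTE with k = 8 neighbors oversamples the minority class to exact parity:
synthetic points are uniform draws on segments between a minority point and
one of its k nearest minority neighbors (Euclidean metric on features
standardized to the input's own scale; interpolation in the original space).
Generation cycles minority points in index order, so counts are exact and
runs are deterministic per seed. Original rows are preserved verbatim and
synthetic rows flagged. The CV harness applies SMOTE to training folds only;
validation folds keep the original distribution, and the flags make leakage
checkable.

## Evaluation

Stratified k-fold CV (default k = 10) deals shuffled class members
round-robin to folds, so per-fold class counts deviate from proportionality
by at most one sample. Per fold: standardize on the training rows, optionally
SMOTE the training rows, fit, score the untouched validation fold. AUC is the
Mann–Whitney statistic with ties counted one half (average ranks); the
threshold for the confusion-matrix metrics (accuracy, precision, recall, F1)
is fixed at probability 0.5. Summaries are mean ± sample SD (ddof = 1) across
folds; the SD convention is recorded in every report.

## Explanation

Shapley values are computed on the continuous ensemble score. The coalition
value v(x, S) is the mean model score over background rows with features in
S replaced by x's values. For d ≤ 12 all 2^d coalitions are enumerated
(efficiency, symmetry and dummy hold exactly); otherwise a kernel
weighted-least-squares estimator enumerates complete coalition-size groups
from the outside in while the budget allows, samples the remainder with the
residual kernel mass, and solves the WLS system with the efficiency
constraint imposed exactly through a KKT system (ridge 1e-10 on the normal
matrix). Pairwise interaction values are not computed; interactions are
presented through dependence-table coloring by a secondary feature.

## The synthetic cohort generator

The generator emulates a sepsis early-warning dataset: 49 per-stay aggregate
features (vitals, chemistry, hematology panels) with plausible adult-ICU
ranges, correlated within panels (ρ = 0.3 block-diagonal Gaussian copula on
the latent scale), and a binary label from a logistic model on the latent
scores. The default signal carries five named features — low platelet_min,
high creatinine_max, low mbp_min, high lactate_max, low spo2_min — with main
effects of magnitude 1.0–1.3 and two pairwise interactions
(creatinine_max × mbp_min at −1.4, platelet_min × lactate_max at −1.2) plus
Gaussian noise (SD 0.5). The interactions are sized on par with the main
effects deliberately: simultaneous renal failure and hypotension is a
super-additive clinical risk, and the nonlinear share of the signal is what
distinguishes ensemble learners from a purely linear baseline. The intercept
is solved by bisection on [−20, 20] to hit the target prevalence to 1e-3
(default 0.41, the 7-day window's positive fraction). `table1_cohort`
truncates an oversized draw to the exact published pre-balancing class
counts per window (7-day 534:378, 14-day 531:336, 28-day 501:319).

What the generator does not model: longitudinal trajectories (rows are
per-stay aggregates), informative missingness, unit heterogeneity, label
noise from imperfect phenotyping, or covariate shift between sites. Passing
tests therefore demonstrate correctness of the machinery and recoverability
of a known signal under clean conditions, not clinical performance.

## Study sizes in the shipped tests and acceptance script

The end-to-end study uses the default cohort (n = 912, d = 49), tuning
budget 8 over (mode, base learner, rounds 1–4, shrinkage, learning rate)
with the objective evaluated by 3-fold CV on a 420-sample stratified
subsample and 25-epoch learner fits; the selected configuration is refit
with 40-epoch fits and evaluated by 10-fold CV; Shapley attributions use
128 coalitions, 60 explained samples and 30 background rows. These sizes
are the package's chosen defaults for a desk-scale study; all of them are
parameters a user can raise.

## Known limitations

* The gated-SSM learner is a time-invariant simplification of selective
  state-space architectures; no GPU path, no associative-scan
  parallelization.
* gbm/ada modes combine hard ±1 member outputs, so their scores are coarse
  (2^T levels) at small round counts; rf mode averages probabilities and
  typically dominates AUC at desk scale.
* Serialization covers native learners only; library-backed members use
  their own persistence formats.
* Probability outputs are uncalibrated; the package reports ranking and
  threshold metrics, not risk estimates.
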