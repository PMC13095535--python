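# Methods

## The prediction problem

Postoperative sepsis is rare (~5% of surgical admissions in the cohort
shape we target) and its antecedents are heterogeneous across patients.
`sepselect` implements an interpretable risk model built from two views of
a perioperative record:

* **static preoperative indicators** `X_s` — 20 laboratory and demographic
  values per patient (5'-NT, Cl, GFR, ..., PLT#; see
  `sepselect.cohort.STATIC_FEATURE_NAMES`);
* **intraoperative monitoring series** `X_v` — heart rate, systolic and
  diastolic pressure, SPO2 and CVP sampled over the operation.

Each monitoring signal is summarised by its mean and *population* standard
deviation (divisor `N`, not `N−1`):

    x_M = (1/N) Σ x_i,        σ = sqrt((1/N) Σ (x_i − x_M)²)

giving a statistical block `X_m` (10 values) whose dispersion half carries
the clinical premise that strongly fluctuating vitals flag risk. The
combined feature vector is `X_d = (X_s, X_m)`, d = 30.

## Model

Three networks are trained jointly.

**Actor (selector).** A simple self-attention network maps `X_d` to
per-feature selection probabilities `S_d ∈ (0,1)^30`. During training a
binary mask `M ~ Bernoulli(S_d)` is drawn per instance and the Hadamard
product `X_d* = X_d ⊙ M` zeroes the unselected features; at evaluation the
mask is the deterministic threshold `S_d ≥ 0.5`.

**Critic (predictor).** An input linear layer 30→64, three blocks of
{self-attention, SiLU, linear 64→64, dropout 0.5}, and a sigmoid output:
`p = N_prediction(X_d*)`, the sepsis risk from the masked features only.

**Baseline.** A ten-layer temporal convolutional network — five residual
blocks of two causal dilated convolutions (kernel 3; dilations 1, 2, 4, 8,
16; 32 channels), average-pooled (window 2) after the first three blocks
and globally average-pooled at the end — embeds the raw monitoring series;
the embedding is concatenated with `X_d` and passed through a fully
connected head. The baseline sees everything the Critic does plus the raw
time series, so its loss is the benchmark the reinforcement reward is
measured against. An HSIC penalty (below) discourages the TCN embedding
from merely re-encoding the summary statistics.

### Self-attention detail

The design fixes only the ingredients: Q/K/V linear maps, a softmax and a
residual connection at widths 30 (Actor) and 64 (Critic). Treating the
width-w representation as w scalar tokens admits two single-head
realisations: a w×w mixing matrix `softmax(q kᵀ/√w)` applied to `v`, or an
element-wise gate `a = softmax(q ⊙ k / √w)`, `out = a ⊙ v + x`. The mixing
matrix built from scalar tokens has rank-1 attention logits and, under
stochastically masked inputs, trains erratically (a supervised control on
masked inputs stays at chance, AUC ≈ 0.5, while an MLP reaches 0.96). The
gated form is stable under masking (supervised control AUC 0.97) and is
what the package uses.

### Losses and reward

With `L_fcl` the baseline head's cross-entropy, `L_hsic` the HSIC penalty,
`L_prediction` the Critic's cross-entropy and `L_fs` the cross-entropy
between `S_d` and the sampled mask (the mask's negative log-likelihood):

    L_baseline = L_fcl + L_hsic
    R          = −(L_prediction − L_baseline)        (detached)
    L_critic   = L_baseline + L_prediction
    L_actor    = R·L_fs − λ·mean(S_d)
    L_total    = L_actor + L_critic

`R·L_fs` is a REINFORCE score-function objective: masks under which the
Critic beats the baseline have their log-likelihood increased. `R` is
treated as a constant so Critic gradients never leak into the Actor; the
package asserts all five identities to 1e-9 on every step and verifies by
parameter-gradient inspection that `L_prediction` alone touches no Actor
parameter. A `reward_sign` switch (+1 default) lets the reward be negated
for sensitivity analyses.

HSIC uses the standard biased estimator `(m−1)^{-2} tr(KHLH)` with
Gaussian kernels and per-batch median-heuristic bandwidths (treated as
constants under differentiation). Batches below two samples return a zero
penalty with a warning.

## Training protocol

100 epochs, batch size 32, Adam at initial learning rate 0.01 multiplied
by 0.95 per epoch from epoch 50 on, single optimizer step per batch for
all three networks, fully seeded. The optimizer itself is a design choice:
Adam is used because plain SGD at these gradient scales leaves the
selector essentially at its initialisation. Numerical safeguards, each
adopted after observing the failure it prevents: cross-entropies are
computed from logits in the `log1p` form (a clipped-probability form has
exactly zero gradient for saturated-wrong predictions, which makes
collapse irreversible — this applies to the mask likelihood too);
monitoring signals are z-scored per channel with training-set moments
before entering the TCN (raw vitals live on scales of 10–100 units);
convolution stacks use He initialisation; and gradients are clipped to a
global L2 norm of 5 (`max_grad_norm`, disable with `None`).

Class weighting for the ~18:1 imbalance and stratified mini-batches exist
as flags, both off by default.

### Known limitation: selector saturation

The printed Actor objective *rewards* selection (−λ·S̄ with λ ≥ 0), and
once both predictors fit the training data the reward converges to
`+L_hsic > 0`. A positive reward with near-certain masks reinforces
whatever is sampled, so the selection probabilities saturate toward 1
(select everything) within ~10 epochs at the default λ = 0.1; the
informative-vs-noise contrast that builds during the early exploratory
phase survives only as an ordering at the 1e-5 probability scale and is
not reliable at epoch 100. The mirrored sparsity reading (+λ·S̄ penalty)
collapses symmetrically to select-nothing: with a batch-scalar reward, the
per-feature REINFORCE covariance signal is orders of magnitude weaker than
any consistent λ drift. We therefore do not claim stable per-feature
recovery under the default protocol; the Critic's discrimination (held-out
AUC ≈ 0.95 on planted cohorts) is unaffected, because the saturated
selector passes all features through. Per-instance rewards (as in
INVASE-style selectors) would strengthen the selection signal but are a
different objective from the one implemented here.

## Synthetic cohorts

The real cohort this design targets (1,538 surgical patients, 82 sepsis
cases, private) cannot be redistributed, so `generate_synthetic_cohort`
emulates its shape with planted, known structure:

* static indicators are Gaussian on clinically plausible scales (their
  z-scores are the latent signal carriers);
* monitoring signals are AR(1) fluctuations (coefficient 0.8) around
  physiologic set-points (HR 80, SBP 120, DBP 70, SPO2 98, CVP 8), sampled
  at T = 32 steps by default — roughly five-minute readings over a
  ~2.5-hour operation; T is configurable since no sampling protocol is
  canonical;
* each patient draws a lognormal (σ = 0.5) volatility multiplier on the
  informative signal, so heart-rate variability varies across the cohort;
* the latent risk is `effect_size` times the mean z-score of the
  informative static indicators plus `effect_size` times the standardized
  realized dispersion of the informative signal, plus Gaussian noise
  (`noise_sd`, default 1); the `positive_count` highest-risk patients are
  the cases, making class counts exact by construction.

Defaults plant five informative features among the 30: static indices
{0, 7, 8, 12} (5'-NT, Age, Na, Fbg) and the standard deviation of signal 0
(HR_S). What these cohorts do *not* emulate: missingness patterns, mixed
measurement units, label noise from chart review, non-stationary
intraoperative events (induction, blood loss), or correlated laboratory
panels. Passing tests on them demonstrates mechanical and statistical
correctness of the pipeline, not clinical validity.

## Evaluation and explanations

`compute_metrics` reports the thresholded confusion counts (threshold 0.5
by default), accuracy, F1, sensitivity, specificity, trapezoidal ROC AUC
and step-wise average precision; single-class truth vectors flag the
ranking metrics as undefined instead of crashing. scikit-learn's
implementations serve as the independent cross-check in the test suite.

Integrated gradients attribute a prediction to its inputs along the
straight path from a baseline `x′` (default: the all-zero vector in
standardized space, i.e. the cohort-mean patient) with a right-Riemann
approximation (trapezoid optional), 128 steps by default; attributions are
exact on linear models for any step count and the completeness gap shrinks
as steps grow. Both the Critic (through the thresholded mask) and the
baseline model can be attributed. Cohort-level rankings are the
column-means of `S_d`, sorted descending with alphabetical tie-break.

## Problem sizes used in the checks

The full verification suite trains three 2,000-patient cohorts for the
full 100 epochs (the study-scale experiment) and uses smaller smoke
cohorts (n = 120–240, 2–5 epochs, 8 TCN channels) for contract tests;
HSIC permutation checks run 50 replicates at m = 100 with 99 permutations
each. All randomness flows from explicit seeds; single-threaded runs are
bit-reproducible.
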