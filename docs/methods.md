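# Methods

## Problem and model

`bifuse` classifies cancer patients into shorter-term (death within 5 years
of diagnosis; label 1, poor prognosis) and longer-term survivors (label 0)
from two per-patient feature vectors: a genomic profile `g` and a
pathological-image profile `p`, each reduced to `L = 32` selected features.
Most fusion approaches concatenate the two vectors and let a dense network
mix them; that representation contains no explicit product terms, so
multiplicative interactions — a gene effect that only matters in a
particular morphological context, or co-expression within a modality — must
be rediscovered by the hidden layers from limited data. The model instead
encodes those products directly with bilinear (outer-product) encoders:

- **cross-modality encoder**: `f_inter_k = ReLU( Σ_i Σ_j w_ijk g_i p_j + b_k )`,
  a dense ReLU layer over the flattened outer product `vec(g pᵀ)`,
  `k = 1..K`, `K = 20`;
- **within-modality encoders**: the same construction over `vec(g gᵀ)` and
  `vec(p pᵀ)`, `M = 20` outputs each. The Gram matrix `x xᵀ` is symmetric,
  so half of each weight slice is redundant; the slices are deliberately left
  unconstrained (the full `L x L` matrix is trained), and the invariance of
  the output under symmetrization of the slices is kept as a property test.

The classifier consumes the fused vector

    h = (g ⊕ f_intra_g) ⊕ f_inter ⊕ (p ⊕ f_intra_p),  |h| = 2L + K + 2M = 124,

through `S = 4` fully connected ReLU layers of widths 500/256/128/32 with
dropout 0.3/0.3/0.1/0.1 after each, into a two-unit softmax giving
`P(y=1 | g, p)`. The two-unit softmax head is kept as such rather than being
collapsed to an equivalent single-logit sigmoid. Training minimizes binary
cross-entropy with Adam (learning rate 4e-4, moments 0.9/0.999, eps 1e-8)
over shuffled mini-batches of 16 for 150 epochs; the final epoch's weights
are used (no early stopping, weight decay or schedule). Probabilities are
clipped at 1e-12 inside the loss.

Seven wiring variants support ablation: `baseline_g` / `baseline_p` (one raw
modality), `intra_g` / `intra_p` (one modality plus its within-modality
encoder, input width 52), `baseline_gp` (direct concatenation, width 64),
`inter_only` (cross-modality features alone, width 20) and `full_fusion`
(width 124). All variants share the classifier hyperparameters.

### Numerical implementation

The network — encoders, classifier, backpropagation and Adam — is
implemented directly in numpy. Every encoder is a dense map over a fixed
transform of the inputs (identity or a flattened outer product), so training
precomputes those transforms once per dataset and then performs pure
dense-layer passes. Parameters are initialized Glorot-uniform from a seeded
generator; `vec(·)` is fixed as row-major (index over the first argument
outermost), an arbitrary but frozen convention required for reproducible
serialization. Training arithmetic runs in single precision with all
parameters in one contiguous buffer (the per-tensor views alias it), which
makes the Adam update a handful of whole-buffer operations; runs are
bit-reproducible for a fixed seed, and inference with dropout disabled is a
pure function. A literal double-sum implementation of each encoder is kept
solely as a testing oracle; the vectorized and naive paths must agree to
1e-9.

## Preprocessing

Applied independently per modality, fitted on training folds only by
default (`fit_scope="train_fold"`; `"full_cohort"` reproduces protocols
that preprocess before splitting):

1. **Label derivation** — label 1 if death observed before the 60-month
   horizon, 0 if follow-up reaches 60 months; patients censored earlier have
   indeterminable 5-year status and are excluded, explicitly and countably,
   never silently.
2. **Missingness filter** — features missing (`NA`) in strictly more than
   10% of samples are deleted; surviving `NA` cells are imputed with the
   training-fold feature mean (the simplest unbiased filler, applied before
   standardization).
3. **z-score** — per-feature standardization with the population standard
   deviation; zero-variance features map to zero with a warning.
4. **Ternary discretization** — under-expression (-1) below z = -1,
   over-expression (+1) above z = +1, baseline (0) otherwise; boundary
   values are baseline (strict inequalities throughout, matching the
   "more than 10%" / "below 200" / "threshold of -1 and 1" readings).
5. **Feature ranking** — information gain of the label given each ternary
   feature (natural-log entropy), descending, ties broken lexicographically
   by feature id so the ranking is deterministic; the top 32 features per
   modality are kept in ranking order.

For histology inputs the package also scores image tiles by **tissue
density** — the fraction of pixels whose R, G and B values are all strictly
below 200 — and keeps the 10 densest tiles of a series. Whole-slide tiling
and morphology-feature extraction are out of scope; the pipeline consumes
precomputed feature tables, and the density stage accepts rasters of any
size.

## Evaluation

Cross-validation is stratified 5-fold on the binary label (stratification is
a package default; unstratified folds are available). Out-of-fold scores
are pooled — each patient scored exactly once — and all metrics are computed
on the pooled set; per-fold metrics and their means are reported alongside.

- Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc, Pre = TP/(TP+FP), F1 = harmonic
  mean of Pre and Sn. Zero-denominator ratios are reported as undefined
  (JSON null), never as 0.
- ROC by threshold sweep with trapezoidal AUC (equal to the Mann-Whitney
  pair-counting probability with ties at 1/2).
- Operating points at stringent specificity (0.90, 0.95): the smallest
  threshold achieving at least the target specificity, reporting the
  achieved specificity rather than interpolating.
- Harrell's C-index against survival time and event status (not the binary
  label): a pair is admissible when the shorter observed time carries an
  event; concordant when that patient has the higher risk score; score ties
  count 1/2.
- Kaplan-Meier curves and the two-group log-rank test (via lifelines) on
  risk groups split at the pooled median score. The median split is a
  convention, flagged as such; any monotone regrouping of the scores changes
  it.

## Synthetic cohorts

The generator emulates the statistical structure the encoders are built to
detect, not any real data distribution. Features are i.i.d. standard normal
per modality; the true risk is

    r = β_g·g + β_p·p + γ_intra ( Σ g_i g_j + Σ p_i p_j ) + γ_inter Σ g_i p_j + ε,

with interaction index pairs drawn once per seed and stored, together with
every coefficient and the realized risk, in a truth sidecar so oracle tests
can recompute each risk score exactly. Survival is proportional-hazards:
`T ~ Exponential(r0 · exp(r))` with baseline hazard `r0 = ln 2 / 60` per
month (median survival 60 months at r = 0), so higher risk means
stochastically shorter survival — exactly the ordering the C-index measures.
Censoring is an independent exponential whose rate is solved (by root
finding on `E[λ_c/(λ_i+λ_c)]`) so the expected censored fraction equals
`censor_rate` (default 0.2, a moderate follow-up loss).

Defaults: n = 600 (large enough that seed-averaged ablation comparisons are
stable at desk scale), L = 32 per modality, 4 linear effects per modality at
β = 0.3, 8 index pairs per interaction term, noise σ = 0.3. The
strong-signal preset used for ablation studies sets γ_intra = 0.3 and
γ_inter = 0.5: total risk variance ≈ 4.3 (sd ≈ 2, a hazard ratio ≈ 7 per
risk sd — strong-biomarker territory), with the cross-modality term carrying
the largest single share, so a method that captures cross-modal products has
a real advantage while single-modality models still see their own linear and
within-modality share. What the generator does **not** emulate: expression
covariance structure, batch effects, realistic censoring mechanisms
(informative censoring in particular), or histology texture. Passing tests
therefore demonstrate that the machinery recovers the signal class it
targets under its own assumptions, not clinical performance.

## Design choices and limitations

- The ablation ordering check (full fusion ≥ direct concatenation > either
  single modality on mean pooled AUC) is a statistical, seed-averaged
  assertion over 5 seeds at n = 600; it is not a per-run guarantee, since a
  dense network given concatenated inputs can in principle learn the same
  products. In practice the multimodal-over-unimodal half of the ordering is
  robust under the strong-signal preset, but the fusion-over-concatenation
  half runs into an identifiability wall of the generator itself: after
  ternary discretization each cross-modal product is non-zero in only ~10%
  of samples, and the handful of true product terms hide among L² = 1024
  candidates, so with a few hundred training samples the product features
  carry no extractable out-of-sample signal for *any* learner — the bilinear
  encoders then contribute capacity (and overfitting) without usable signal,
  and full fusion ties with direct concatenation instead of beating it.
  Real expression/morphology features, whose informative interactions are
  denser and not i.i.d., are exactly where the explicit product encoding is
  expected to pay off; the corresponding test documents the synthetic limit
  rather than hiding it.
- Specificity is computed as TN/(TN+FP) throughout.
- Sample order in matrices is file order; all joins are by patient id.
- Folds default to stratified even though the literal protocol does not
  require it; with a few hundred patients unstratified folds can be
  degenerate. `stratified=False` restores the plain shuffled partition.
- Degenerate inputs are contracts, not crashes: single-class labels warn
  (rankings go to zero; training proceeds), an unattainable specificity
  target raises, a cohort with no admissible survival pairs raises.
- Test and example problem sizes (n of a few hundred, 150-epoch training)
  are chosen so the whole suite runs on a laptop-class single CPU; the
  pipeline itself has no size-dependent switches.
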