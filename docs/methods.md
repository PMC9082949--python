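# Methods

## The model

`staplr` implements stacked penalized logistic regression for multi-view
binary classification, generalized to tree-structured view hierarchies.
A *view* is a named block of feature columns (for instance one derived MRI
measure); views may nest inside higher-level views (scan types), giving a
rooted tree whose leaves own the features and whose root is the meta level.

Fitting proceeds bottom-up through the tree:

1. **Leaves.** On each leaf view X⁽ᵛ⁾ a logistic ridge regression f^v is
   fitted, with its penalty strength λ chosen by internal k-fold
   cross-validation. Ridge is the default at this level because the goal is
   to weigh entire views, not to select individual features. Each leaf also
   produces a vector of *cross-validated* predictions z⁽ᵛ⁾: subjects are
   split into prediction folds, and each subject's value comes from a model
   trained — including its internal λ-selection loop — without that
   subject's fold. This is the standard stacking device preventing the next
   level from learning on optimistically-fitted values.
2. **Internal nodes.** The children's cross-validated prediction vectors
   are collected column-wise into a matrix Z⁽ˢ⁾, and a logistic
   *nonnegative lasso* combiner f^inter(s) is fitted on (Z⁽ˢ⁾, y) — L1
   penalization performs view selection, the nonnegativity constraint keeps
   each selected view's contribution positively oriented and improves
   selection behaviour. Every non-root node then produces its own
   cross-validated predictions for its parent, using a fresh fold
   partition for that level.
3. **Root.** The meta learner f^meta (again a nonnegative lasso) combines
   the top-level branches. The final classifier is the nested composition
   f^meta(f^inter(1)(f^1, …), …), each stage applying
   ψ(intercept + weighted inputs) with ψ the logistic function.

A flat hierarchy (all leaves directly under the root) reduces exactly to
the original two-level stacked model with a single combiner; deeper and
mixed-depth trees are handled by the same recursion, a leaf attached
directly to the root skipping intermediate combination.

## Penalized logistic regression core

All levels use one solver family for the objective

    J(b0, β) = (1/n) Σᵢ [log(1 + exp(ηᵢ)) − yᵢηᵢ]
               + λ (α‖β‖₁ + (1−α)/2 ‖β‖₂²),

with unpenalized intercept and optional slope nonnegativity. The λ path
follows the usual convention: 100 log-equispaced values from λ_max (the
smallest λ at which every slope is zero, computed from the null-model
score) down to ε·λ_max with ε = 0.01. For pure ridge, λ_max is infinite and
the standard surrogate of flooring α at 0.001 in the λ_max formula is used.
Under nonnegativity only positive score components can activate a slope;
when none is positive the null model is optimal everywhere and the path
collapses to a single value (logged).

λ is selected by k-fold cross-validation minimizing mean out-of-fold
binomial deviance, with ties broken toward the larger penalty (sparser
model). Deviance rather than misclassification loss was chosen because it
is smooth and favours probability calibration; the choice is configurable.

Numerics:

- **Unconstrained ridge paths** are solved by blocked Newton/IRLS: blocks
  of λ values iterate simultaneously, each with its own weights and an
  exact penalized weighted-least-squares solve; the Hessian is refreshed
  lazily between cheap gradient steps whose common fixed point is the exact
  stationary point. The dual (Gram) form is used when p > n.
- **L1-containing and constrained fits** use iteratively reweighted least
  squares whose weighted subproblems are solved exactly by an active-set
  method in covariance form (solve on the signed support, step back to the
  first sign crossing when a coordinate leaves, admit the worst violator of
  the subgradient conditions until none remains). Cyclic coordinate descent
  with soft-thresholding — with nonnegativity enforced by clipping each
  coordinate update at zero, which is exact for the coordinate subproblem —
  remains as the fallback and the solver for very wide problems (p > 400).
- IRLS working probabilities are clipped to [1e−5, 1−1e−5]; convergence is
  declared at a relative maximum coefficient change below 1e−8 (default);
  warm-started path fits agree with cold fits to well below 1e−6.
- With internal standardization on (default for feature-level fits), the
  penalty applies on the unit-variance scale and coefficients are reported
  back on the original scale. Combiner levels default to no
  standardization: their inputs are probabilities already on a common
  scale. Both are configurable; whether reference implementations
  standardize prediction matrices is not documented anywhere we know of,
  so the choice is exposed rather than hidden.

The test suite checks the solver against an independent generic convex
optimizer (L-BFGS-B on the split formulation β = β⁺ − β⁻) across all six
penalty configurations.

## Minority report measure (MRM)

Because every level is a logistic model, coefficients are interpretable
within a combiner but *not* comparable across combiners: the composed
classifier is not a product of weights. The MRM makes leaf views comparable
across branches by probing the composed model directly:

    MRM(view; a, b, c) = g(view, b, c) − g(view, a, c),

where g sets the probed leaf's prediction to the given value, clamps every
other leaf at c, and evaluates the composition from the stored coefficients
alone — no resampling or refitting. Defaults are a = 0, b = 1 (theoretical
extremes) and c = ȳ, the training class-1 proportion stored in the model
(not recomputed at prediction time). An empirical mode instead uses each
view's own cross-validated predictions' observed minimum and maximum as
(a, b). With nonnegative combiner weights and b ≥ a, every MRM lies in
[0, 1), and MRM = 0 exactly when a = b or when any coefficient on the
leaf's path to the root is zero.

For trees deeper than three levels the same definition applies recursively;
on depth-3 trees it reduces to the closed-form expression with the meta
weights ω̂ and intermediate coefficients β̂. Probing an *internal* node's
prediction (`mrm_node`) is provided as an experimental extension; its
interpretation is less settled and it is not part of the default report.
The degenerate configuration a = b is accepted (returning 0) rather than
rejected, since it is the natural boundary of the definition.

## Evaluation protocol

Generalization is estimated by repeated double (nested) cross-validation:
in each repeat, subjects are split into `outer_folds` stratified folds; the
*entire* training pipeline — base fits, combiner fits, every internal
cross-validation — runs on the training portion only, and the held-out fold
contributes nothing but AUC (rank/Mann–Whitney form, ties credited ½) and
accuracy (threshold 0.5, scores at the threshold predicting class 1).
Defaults are 10 outer folds, 10 inner folds and 10 repeats, i.e. 100 fitted
models; repeats redraw only the fold allocation. Per-fit combiner
coefficients are snapshotted, yielding *selection proportions* — the
fraction of fits in which a view's coefficient was nonzero.

The flat elastic-net benchmark ignores the view structure: one logistic
elastic net over all features, with the mixing weight α selected from
{0, 0.1, …, 1} and λ from the usual 100-value path, jointly minimizing
inner-CV deviance (shared inner folds across α; ties toward the larger α,
then the larger λ). Each fitted model is summarized per view by its count
of nonzero coefficients and the L2 norm of the view's coefficient
sub-vector.

Fold assignment is stratified by class (falling back to unstratified, with
a warning, when a class is smaller than the fold count): with imbalanced
case–control data, unstratified 10-fold splits risk folds without cases.
The fold mechanism is seeded and deterministic; one global seed is expanded
into per-level, per-node, per-repeat sub-seeds via a stable hash, so runs
are bitwise reproducible while components remain independently
perturbable. Whether fold partitions are re-used across stacking levels is
configurable (`reuse_level_folds`); the default draws a fresh partition per
level, reading the prediction loops at different levels as separate
cross-validations.

## Synthetic data generator

The generator emulates the *shape* of a multimodal neuroimaging study: a
handful of top-level branches, leaf views of wildly unequal width, features
correlated within a view, an imbalanced binary outcome, and signal
concentrated in a minority of leaf views.

- Features follow an exchangeable-correlation Gaussian factor model
  x = √ρ·u_view + √(1−ρ)·ε, so the within-view correlation is exactly ρ
  (default 0.3, a mid-range value typical of features derived from a common
  image).
- The outcome comes from a latent logistic model whose nonzero coefficients
  live only in the designated signal views. Each signal view's contribution
  to the linear predictor is scaled to variance `effect_size`², so views of
  very different widths carry comparable signal — without this, recovery
  experiments would confound width with signal strength. The intercept is
  solved numerically so the expected prevalence matches the configured
  class balance (default 0.305, mirroring a ~76:173 case–control
  imbalance at the default n = 249).
- Matching the fitted model family makes recovery well-posed; for
  robustness checks a misspecified variant exists (probit link,
  heavy-tailed t₃ feature noise).

Two presets: `three_scan_type_preset` reproduces the 3-branch,
5/4/31-leaf hierarchy with widths spanning 5 to 191 — the voxel-wise views
that would have ~190,000 features are scaled down by three orders of
magnitude so the 40-leaf pipeline runs end-to-end at desk scale — and
`flat_eight_view_preset` gives 8 leaf views of widths 5–80 under the root
with signal in two of them (n = 300, effect size 3.0), the configuration
used by the recovery experiments.

What passing tests on these data do **not** show: real imaging features are
not Gaussian, not exchangeable within a view, and carry spatial and
cross-view dependence the generator omits; absolute performance numbers on
synthetic data say nothing about clinical data. The tests establish the
*mechanics* — correct optimization, leakage-free stacking, calibrated null
behaviour, and the method's qualitative selection properties.

## Problem sizes used by the test suite and acceptance script

Simulations are scaled to desk size as the package's own choice of study
conditions: the recovery experiment uses the flat 8-view preset (n = 300,
25 seeds in the test suite, 10 in the acceptance script) with the full
default fitting configuration (10 prediction folds, 10 λ folds, 100 λ
values); nested-CV comparisons run 5×5 folds with 2 repeats and a 50-value
path; null calibrations use 3×3 folds, 5 repeats, n = 150. The protocol
*shape* check keeps the full 10 repeats × 10 outer folds.

## Known limitations

- Binary outcomes only; no imputation (missing values are a hard error);
  no grouped or fused penalties; no non-logistic base learners.
- The λ-selection rule is the deviance minimum, not the one-standard-error
  rule; on very small folds the CV curve is noisy and selection can be
  unstable (the repeats of the evaluation protocol are the intended remedy).
- The MRM clamps all non-probed views at a single value c; it measures a
  view's marginal leverage in the fitted composition, not a causal or
  distributional attribution (permutation importance and SHAP-style
  methods answer different questions and are deliberately out of scope).
- The active-set subproblem solver assumes the weighted Gram matrix is
  numerically nonsingular on the active set; degenerate cases fall back to
  coordinate descent.
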