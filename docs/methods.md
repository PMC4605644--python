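# Methods

This note records the statistical models, the numerical choices, and the
places where the design was genuinely open, in the order the pipeline runs.

## Synthetic data model

The generator emulates background-subtracted microarray intensities. For
sample *i* in group *g* and batch *b*, feature *j*:

    x_ij = a_b + s_b · exp(μ_j + δ_jg · effect + ε_mult) + ε_add

with baseline log-means μ_j ~ N(5, 1), multiplicative noise
ε_mult ~ N(0, σ_mult²), additive noise ε_add ~ N(0, σ_add²), per-batch
offset/scale (a_b, s_b), and δ_jg ∈ {−1, 0, +1}. Deregulation is a
symmetric shift of ±`effect_size` on the log scale, the sign alternating
across the ⌊frac·p⌋ chosen features of each case group, so both up- and
down-regulated markers occur. Outlier samples are produced by multiplying
a whole sample by `outlier_scale` (≥ 4), which places its median intensity
far outside the Tukey fences of the per-sample median distribution — the QC
rule is therefore testable end to end.

Defaults: 863 features (the chip's consistently annotated miRNA count),
two batches (scale 1.0/1.3, offset 0/50), σ_mult = 0.3, σ_add = 20,
effect 1.5, 5% of features deregulated per case group, 20 samples per
group. The noise scales were fixed once so that a feature of median
baseline expression carries a clearly detectable effect while features at
low baseline are partially masked by additive noise — the regime a real
background-subtracted array sits in.

What the generator does **not** model: probe-sequence affinity, spatial
chip artifacts, correlated feature blocks, and library/annotation drift.
Tests passing on this generator therefore certify the pipeline's logic and
statistics, not its behavior under correlated real-array noise.

## Preprocessing

The order is fixed: QC on raw data → batch centering → normalization.

1. **QC**: a sample is flagged when its median raw intensity falls outside
   [Q1 − 1.5·IQR, Q3 + 1.5·IQR] of the per-sample medians. Fences are
   two-sided (dim and inflated arrays are both unusable); quartiles use
   linear interpolation between order statistics — both conventions are
   fixed so the rule is exactly testable.
2. **Batch centering**: per batch and per feature, the median over that
   batch's healthy controls is subtracted, so control medians are 0 in every
   batch. Centering is feature-wise, not a scalar per batch: a single scalar
   cannot align feature-level batch distortions.
3. **Normalization**: per-sample affine arsinh calibration
   h_ij = arsinh(a_i + b_i·x_ij), the generalized-log transform. The
   calibration is estimated by minimizing the profile negative
   log-likelihood of the model arsinh(a_i + b_i x_ij) = μ_j + N(0, c²)
   (feature means and variance profiled out analytically), which contains a
   log-Jacobian term −Σ log h′; that term both forbids the degenerate
   constant transform and drives b_i toward the variance-stabilizing scale
   σ_mult/σ_add. Optimization is L-BFGS over all 2n calibration parameters
   with analytic gradients, followed by one least-trimmed-squares refit with
   the worst 10% of features excluded from the residual sum (the Jacobian
   keeps all features, so trimming does not bias the scale). Convergence
   tolerance 1e-6, iteration cap 50·20; non-convergence warns and returns
   the best iterate.

   On generator data the mean–sd Spearman correlation across features drops
   from ≈ 0.98 (raw) to ≈ −0.27 after calibration: the residual slightly
   negative trend comes from the additive component still dominating at the
   lowest intensities. Because centering removes the intensity location
   information that stabilization needs, the stabilization *property* is
   assessed on raw matrices; inside the pipeline the transform's role is
   robust cross-sample calibration on the glog scale.

MDS for visual QC is classical (Torgerson) scaling on the distance
1 − Spearman ρ between sample columns.

## Penalized hinge-loss classifiers

The objective is the sum-form soft-margin problem
Σ_i max(0, 1 − y_i(β·x_i − β0)) + p(β) with penalties ridge, LASSO,
elastic net, SCAD and elastic SCAD. The SCAD spline is

    p(β) = λ|β|                                |β| ≤ λ
         = (2aλ|β| − β² − λ²) / (2(a−1))       λ < |β| ≤ aλ
         = (a+1)λ²/2                           |β| > aλ

with a = 3.7 (the canonical shape constant); the middle piece is the one
continuity forces given the inner and outer pieces (value λ² at the first
knot and (a+1)λ²/2 at the second).

Solver: convex kinds by FISTA on a Huber-smoothed hinge (smoothing δ =
0.01), the ridge term in the smooth part and the L1 part handled by the
soft-threshold prox; the step size comes from the explicit Lipschitz bound
σ_max([X, −1])²/δ + 2λ₂ (power iteration). Because smoothing biases the
optimum by up to n·δ/2, each solve continues at δ/10 and δ/100 from the
warm start, which brings the objective within ~1e-4 relative of the exact
non-smooth optimum (verified against LP/QP oracles in the tests).
Convergence: relative objective change ≤ 1e-6, iteration cap 10 000 per
stage (doubling at the smaller smoothings), restart-on-increase
acceleration. The inner loop is numba-compiled when numba is importable.

SCAD kinds run a local linear approximation (LLA) outer loop: reweighted-L1
subproblems with weights p′_SCAD(|β|), at most 20 outer iterations, started
from the elastic-net solution (plain SCAD uses a tiny ridge 1e-4 in the
start only). The iterate with the lowest true SCAD objective is kept, so
the outer loop can never end above its convex start.

Features are standardized (training mean 0, sd 1) inside `fit`; penalties
are scale-sensitive and the standardization parameters travel with the
model. Selected features are those with |β| above 1e-8 on the standardized
scale — soft-thresholding makes zeros exact, so this is a numerical-noise
guard only.

Tuning is stratified 5-fold cross-validated grid search minimizing
misclassification error, ties broken toward sparser models (larger λ1,
then larger λ2). The package-default grid is λ ∈ {2^k, k = −10..4} (both
axes for two-parameter kinds). The desk-scale experiments in the tests and
the acceptance script use a reduced two-parameter grid
λ1 ∈ {2, 4, 8, 16} × λ2 ∈ {2^-4, 1}: on standardized features with the
sum-form loss, the informative part of the path lies in that upper range,
and the reduction keeps the 50-holdout experiments at single-CPU desk
scale. Holdout counts are likewise configurable (500 at study scale, 50 in
the desk experiments).

## Holdout evaluation and signatures

Splits are stratified 5:3 without replacement: per group,
round(5/8·n_g) training samples with at least one sample guaranteed on
each side. Metrics come from the test-split confusion matrix and the
rank-statistic AUC (ties half-credited); ratios with empty denominators are
reported missing rather than 0.

The final model per problem is the **sparsest median performing** one. The
median is the lower median (⌈k/2⌉-th order statistic), which is always
attained by an actual model — an interpolated median would be attained by
none. Among models attaining it, fewest selected features wins; remaining
ties go to the smallest holdout index. The "top" signature ranks all
ever-selected features by selection count and keeps the top half,
boundary ties included.

Recovery behavior worth knowing: when the signal is strong enough that many
holdout models reach AUC 1.0, the selected model is a *minimal* perfect
model — typically a small subset of the true markers with few or no false
ones. The composition of the signature (fraction of members that are truly
deregulated) is therefore the meaningful recovery metric; demanding that
the minimal model contain most of the redundant true markers would
contradict the selection rule itself.

## Combined diagnosis and the permutation test

Atomic binary models vote: a prediction contributes one vote to every class
on the predicted side of its contrast. Ties go to the class with the
largest mean |decision value| among the models that voted for it. The
default 3-class set uses the three pairwise contrasts CD/HC, UC/HC, CD/UC;
compositions are fully configurable.

The permutation test compares the observed combined error on the complete
dataset with the error under label permutation. Two nulls are available:

- **fixed models** (default): predictions stay put, labels shuffle. Cheap,
  and appropriate when judging a *given* fixed rule — but optimistic when
  the models were fitted to the same labels, since the observed error is
  then an in-sample quantity.
- **retrained** (`retrain_fn`): the atomic models are refitted (at their
  tuned penalties) on each permuted labeling. This calibrates the null
  against the selection optimism; on effect-free data the test is then
  non-significant at the nominal rate, which is how the calibration
  experiment runs it. A degenerate null (constant predictions, zero sd)
  is reported as an error by the test itself and treated by callers as
  "no evidence".

Z = (observed − null mean)/null sd and the p-value is one-sided, p = Φ(Z):
small error rates are the extreme of interest.

## Random-forest validation

Forests use 500 trees, terminal node size 10% of the training-split size
(recomputed per split), mtry = ⌊√p⌋, and scores for ROC are the fraction of
trees voting positive. r2VIM: permutation importances from `n_runs = 10`
independently seeded forests are divided by |min importance| of that run
(the magnitude of the most negative importance estimates the noise floor;
if the minimum is exactly 0 the smallest nonzero magnitude substitutes);
a feature is selected only with relative importance ≥ 1 in every run.
Importances are evaluated on the training data via sklearn's
permutation_importance; on saturated (perfectly separable, redundant)
training data all importances can be exactly zero, which the caller treats
as "nothing selectable" for that split. The forest learner itself is
scikit-learn's RandomForestClassifier — the contract (bootstrap per tree,
random feature subsets, permutation importance) is what is asserted, not a
specific implementation.

## Marker statistics

Differential expression is the pooled-variance (Student's) two-sample
t-test per feature, two-sided, with Holm's step-down adjustment; the fold
change is the group mean difference on the glog scale (≈ log-ratio). A zero
pooled variance is flagged and mapped to p = 1 (equal means) or p = 0
(unequal). Direction concordance against literature tables compares only
the sign of the fold change. Enrichment uses the two-sided Fisher exact
test on the 2×2 table (signature targets vs remaining targets) ×
(risk-locus genes vs not), Haldane-corrected odds ratios when a cell is
zero, and Bonferroni adjustment over all tests performed; gene→locus and
miRNA→target annotations are user-supplied files, keeping the package free
of database-version dependence.

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` run: marker recovery at
200 features / 60 samples / 50 holdouts per problem; calibration at
100 features / 36 samples / 20 runs / 100 retrained permutations; sparsity
at the full 863-feature shape; solver oracles at ≤ 20×10. These sizes are
the package's desk-scale defaults; every routine accepts study-scale
settings (500 holdouts, 1000 permutations, full grids) through its
parameters.

## Known limitations

- Features are generated independently; correlated miRNA blocks (the rule
  in real arrays) would make signatures less stable than the tests suggest.
- The LLA solver guarantees non-increase of the SCAD objective from its
  convex start, not global optimality — the standard state of affairs for
  non-convex penalties.
- The retrained permutation null refits at fixed tuned penalties rather
  than re-running the full grid search per permutation; the residual
  optimism from tuning is small but not zero.
- vsn-style calibration slightly over-compresses the highest intensities
  (mean–sd correlation mildly negative after transform).
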