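# Methods

This note documents the models and procedures implemented in `eegoat`,
the defaults chosen where the method left the design open, and what the
synthetic data can and cannot demonstrate.

## Sampling design

A class recording is the N × C matrix of one set's time points (rows) by
channels. The sampling unit is a row; the per-class sample size comes from
the standard proportion-based formula `n₀ = z²p(1−p)/d²` with a finite
population correction `n = n₀/(1 + (n₀−1)/N)`, rounded half-up and clamped
to [1, N].

Defaults: z = 1.96 (95% confidence), p = 0.5 (the variance-maximising,
assumption-free choice), d = 0.0076. The margin of error d is the one free
knob; 0.0076 was picked so that a 4097-point recording yields n ≈ 3287,
i.e. roughly 80% of the rows are retained — a regime in which the sample
is still genuinely a subsample but feature estimates are stable. All three
parameters are configuration, not constants: published analyses of the
Bonn corpus report per-set totals of 3288 without stating z, p or d, so
that exact total cannot be re-derived and is not hard-coded anywhere.

Segmentation cuts [0, N) into k contiguous segments, the first k−1 of
length ⌊N/k⌋ and the last absorbing the remainder (4097 with k = 4 →
1024/1024/1024/1025). k = 4 is the default.

### Allocation

Optimum allocation weights segment i by `w_i = N_i·sqrt(Σ_j S_ij²)` with
sample variances (divisor n−1; conventional — nothing downstream is
sensitive to the divisor). Real-valued shares `n·w_i/Σw` are converted to
integers by the **largest-remainder method**, which is what makes the
conservation invariant Σn(i) = n exact. Two degenerate cases are handled
explicitly:

* a share exceeding its segment's size is capped at `N_i` and the excess
  is redistributed proportionally among uncapped segments (water-filling);
* if every weight is zero (all-constant signals) the allocation falls back
  to proportional-to-size and the plan's `method` field records it.

Within a segment, rows are drawn by simple random sampling without
replacement from a seeded generator; any scheme consistent with "a sample
is drawn" would do, and SRS is the least structured choice.

## Features

Per channel, over its sampled amplitudes: mean, median, mode, SD (n−1),
Q1, Q3, IQR, skewness β₁ = m₃/m₂^{3/2}, kurtosis β₂ = m₄/m₂² (non-excess,
normal → 3, biased central moments — the default convention of the
numerical environments these pipelines historically ran in; excess and
unbiased variants are switchable), min, max. Quartiles use linear
interpolation of order statistics with plotting position (i−1)/(n−1); the
convention is configurable but frozen to this default for all tests.

Two choices were genuinely open:

* **Mode** on real-valued data is ill-defined, so amplitudes are rounded
  to the nearest integer first (Bonn files are integer µV) and ties take
  the smallest value.
* **Zero-variance input** would make β₁/β₂ 0/0; both are returned as 0
  with a `degenerate` flag rather than NaN, keeping feature matrices
  complete. The same path catches variance underflow on numerically
  constant data.

## Logistic model trees

The LMT implementation follows the classical induction algorithm:

* **Base model.** LogitBoost for J classes with *simple* base learners —
  at each iteration, for each class, a weighted one-feature linear
  regression on the working response (clipped at |z| ≤ 3), the best
  feature chosen by weighted SSE. Because the base learners are linear,
  a node's committee collapses to one (J × p+1) linear model, which is
  how it is stored and evaluated.
* **Iteration count.** Chosen once at the root by stratified 5-fold
  cross-validation over up to 200 iterations (first minimum of the summed
  validation error). Each tree node then performs that many warm-started
  iterations on its own data — the standard fast heuristic that avoids
  re-running CV at every node.
* **Splitting.** Binary splits on midpoint thresholds maximising Shannon
  information gain; nodes with fewer than 15 instances, pure nodes, and
  zero-gain nodes become leaves; children need ≥ 2 instances.
* **Warm starts.** A child's committee continues from its parent's, so
  leaf models refine rather than restart — this is what lets small leaves
  carry sensible logistic models.
* **Pruning.** CART-style cost-complexity pruning: candidate α values from
  the weakest-link sequence of the full tree (geometric midpoints), scored
  by 5-fold cross-validation (fold trees grown with the same iteration
  count), ties resolved toward the larger α (smaller tree).
* `max_depth = 0` yields the pure boosted additive logistic model, used
  as the linear baseline in the XOR separation tests.

Determinism: all internal randomness (CV folds) derives from the fit seed.

A practical consequence of CV-selected iteration counts: on cleanly
separable data very few boosting iterations are chosen, so predicted
probabilities stay soft (high probability MAE) even at 100% accuracy.
MAE should be read as a calibration measure, not an error rate.

## Ridge multinomial logistic regression

Reference-class parameterisation ((J−1) × (p+1) coefficients, last class
in canonical order as reference), fitted by damped Newton iterations on
the penalised negative log-likelihood `−ℓ + λΣβ²` (intercepts
unpenalised), features standardised internally, default λ = 1e−8,
convergence at gradient sup-norm < 1e−8, iteration cap 200 with a
diagnostic-carrying error on failure. The exact Hessian is assembled
blockwise — with J = 3 and p = 11 it is 24 × 24, so direct solves are
cheap and quadratic convergence is reached in a handful of steps.

## SVM adapter

Deliberately a wrapper over scikit-learn's libsvm backend (RBF kernel,
C = 1, γ = 1/p, one-against-one decomposition, Platt-scaled probability
outputs), standardising features and remapping probability columns to the
canonical class order. `predict` is the argmax of `predict_proba` with
ties to the lowest class index, matching the native models' contract
(libsvm's own vote-based `predict` can disagree with its Platt
probabilities).

## Evaluation

Stratified k-fold plans deal each class's shuffled indices round-robin,
so per-class fold counts differ by at most one. Metrics are computed on
the **pooled** out-of-fold predictions rather than averaged per fold: with
k = 10 on 300 rows this yields one whole-dataset confusion matrix, the
form in which per-class results for this problem are conventionally
printed (pooled accuracy equals the instance-weighted mean of per-fold
accuracies; a test asserts this identity).

Per class, one-vs-rest: sensitivity, specificity, precision, F-measure,
each returning 0 with a flag on 0/0. Cohen's κ from the pooled matrix
marginals. Probability MAE is the mean of |p̂ᵢc − 1{yᵢ = c}| over
instances *and* classes. ROC areas are one-vs-rest, trapezoidal over all
thresholds of the class-probability scores; the multiclass reduction for
the overall row is the class-frequency-weighted mean of the per-class
areas (the reduction is not uniquely standard; this one is documented and
frozen). All metric implementations are self-contained and cross-checked
against scikit-learn to 1e−9 in the test suite.

Repetition: the experiment default is 10-fold CV repeated 20 times with
seeds fanned out from one base seed; means, standard deviations and
per-repeat values are all retained.

A note on split sizes: descriptions of 10-fold CV on 300 rows sometimes
quote a 250/50 train/test split, which is internally inconsistent (10-fold
gives 270/30). Standard stratified 10-fold is implemented; a fixed
stratified holdout of any size can be emulated by `make_stratified_folds`
with k chosen accordingly, but no attempt is made to guess which of the
two protocols such a description intended.

## Synthetic data

The generator emulates the *shape* and the qualitative class contrasts of
the benchmark corpus: five sets of 100 channels × 4097 samples at 23.6 s;
healthy = moderate 10 Hz (alpha-band) oscillation over AR(2) background;
seizure-free = irregular background with sparse ~40 ms spike transients;
seizure = large-amplitude 3 Hz rhythmic activity, amplitude several-fold
the healthy scale. Channels get independent RNG streams spawned from
(seed, set, channel) plus a log-normal per-channel gain, so sets have
between-channel variability. The profiles were fixed once so that the
full pipeline with the LMT clears 90% accuracy, then frozen as the
package defaults.

What this does **not** emulate: real EEG spectra, artifacts, electrode
correlations, or the actual Bonn class statistics. Passing tests
demonstrate that the pipeline's machinery is correct and that it separates
classes whose amplitude/variability structure differs in the advertised
way — not that the published accuracy on the real corpus is reproduced.
Real-data runs require the external download and are supported through the
same `data_dir` interface.

## Problem sizes and numerical choices

* Test and acceptance runs use the full benchmark shape (5 × 100 × 4097)
  for data generation and feature extraction, and 300 × 11 matrices for
  evaluation; classifier unit tests use 24–400-instance fixtures.
* Sample-size rounding is half-up (not banker's); allocation rounding is
  largest-remainder; argmax ties break to the lowest class index
  (healthy < seizure-free < seizure).
* LogitBoost clips working responses at ±3 and floors weights at 1e−10;
  the Newton solver adds 1e−12 ridge to the Hessian diagonal before
  solving and halves the step while the objective increases.
* Probability rows are renormalised on output and asserted to sum to 1
  within 1e−9.

## Known limitations

* The published per-set totals (3288) and per-segment allocations cannot
  be re-derived exactly because the confidence parameters behind them are
  not stated; the design is configuration instead.
* LMT probability calibration is coarse when few boosting iterations are
  selected (see above).
* The SVM path inherits scikit-learn's Platt scaling, whose internal CV
  makes probabilities (not accuracy) mildly seed-sensitive.
* No artifact rejection, filtering or resampling: recordings are consumed
  as stored, matching the plain-text corpus format.
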