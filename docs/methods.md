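# Methods

## Importance model

Both importance methods measure the drop in a fixed fitted model's
validation score when one feature is decoupled from the rest of its row.
Scores are the coefficient of determination r² for regression and
exact-match accuracy for classification (labels must be integer-coded; no
classification estimators are shipped, but any fit/predict object works).

**PFI** fits once on a train split (default 75/25, drawn with the run seed)
and, per feature i and repetition j, shuffles validation column i in place.
The importance is `rs − (1/J)Σ s_{i,j}`. A single-row validation set makes
shuffling a no-op; the implementation warns and returns all-zero
importances with reference score 0, since a one-point r² is undefined.

**CVPFI** replaces the split with an N-fold plan, fits one model per fold,
and pools out-of-fold predictions into one length-m vector scored once.
Corruption resamples validation column i from the *full* original column at
row positions drawn without replacement — distinct source rows, though
values may tie. Companion features with gated correlation ρ > 0 are
resampled likewise with probability ρ (one Bernoulli draw per companion per
fold). The target column itself is always resampled; the diagonal of the
gated matrix is never consulted.

Sampling from the full dataset (rather than only from non-validation rows)
follows the procedure's definition of drawing from "the original dataset";
since draws are marginal (row identity is discarded), the overlap with
validation rows carries no label information.

Companion draws are independent of the target's row draw by default. The
alternative — companions reuse the target's rows, preserving the empirical
target-companion pairing inside the corrupted block — is available as
`joint_rows=True`. Both are defensible readings of "when one changes, the
other changes according to its correlation"; the independent version is the
default because it only requires the marginal distribution, not joint row
alignment.

## Chance-correlation gate

Co-sampling probabilities are the absolute Pearson correlations of the full
dataset, computed once before the CV loop (never per fold). An entry is
kept only when the central interval with coverage α around the population
correlation excludes zero. The interval is built on the Fisher transform
z = ½ ln((1+r)/(1−r)) (natural log; the inverse maps back exactly), using
the normal approximation z ~ N(·, 1/(m−3)) and the two-sided normal
quantile for coverage α.

Design choices here, made where the procedure's definition was open:

* **α is a coverage probability** (default 0.999), i.e. the central
  interval containing 99.9% of the z-distribution; under the null this
  passes a truly uncorrelated pair with probability ≈ 0.001. Note that in
  some descriptions this quantity is called a "significance level"; here it
  is always the coverage.
* **The transform is applied to |r|**, matching the use of absolute
  correlations as probabilities. The straddle test `L < 0 < U` is
  unaffected: the interval around |r| straddles zero iff |z| < c/√(m−3),
  exactly the two-sided null test on signed r.
* **Perfectly collinear columns** (|r| = 1) are clamped to 1 − 10⁻¹² before
  transforming, so duplicated features gate to probability 1.0 instead of
  overflowing.
* **Constant columns** have undefined correlations; they are gated to 0
  everywhere with a warning — a constant carries no co-movement information
  (its own importance is exactly 0, since resampling a constant changes
  nothing).
* The association measure is pluggable in principle (any statistic in
  [−1, 1] with a straddle decision); only Pearson is implemented. No
  multiple-testing correction is applied across the p(p−1)/2 pairs — the
  stringent α is the only guard.

## Fold rules and estimators

Fold counts follow the sample-size rules: m < 30 → leave-one-out,
30 ≤ m < 100 → 10-fold, m ≥ 100 → 5-fold (the boundary cases m = 30 and
m = 100 are assigned to the larger-m regime), overridable explicitly. Folds
are formed by seeded shuffling then contiguous splitting; no stratification
for regression.

The estimator suite wraps scikit-learn: PLS (latent-variable count by inner
5-fold CV, up to 10 components), RBF-kernel SVR (C ∈ {0.1, 1, 10, 100},
γ ∈ {0.01, 0.1, 1, scale}, ε ∈ {0.01, 0.1, 1} by inner grid-search CV, with
the response standardised internally around train statistics), and GPR with
kernel θ₀·exp(−θ₁/2·‖xᵢ−xⱼ‖²) + θ₂ plus a white-noise term, tuned by
marginal-likelihood maximisation. All families autoscale features inside
`fit` using train-row statistics only. Hyperparameters are selected once on
the full data (`select_hyperparameters`, invoked automatically by the
importance drivers) and then held fixed across folds — re-tuning inside
every training fold would be slightly more correct but J·N·p times more
expensive; the approximation is documented rather than hidden. The
importance machinery passes *raw* features to the estimator so that
corruption draws come from the original measurement scale; scaling is the
estimator's business.

SVR at very small n can fail to beat the mean predictor after
hyperparameter search; the suite still returns the fit and lets the
importances go to ≈ 0, which is the honest answer for a model that learned
nothing.

## Randomness and reproducibility

A single run seed drives everything: the fold plan, the PFI split, and one
child RNG stream per (feature, repetition) spawned from the master seed via
`SeedSequence(seed, spawn_key=(tag, i, j))`. Adding features or repetitions
therefore never perturbs the draws of earlier ones, and identical
configurations give bit-identical results objects and byte-identical CSV
artefacts. The importance identity
`importance = reference − mean(corrupted scores)` holds exactly; the row
mean is evaluated exactly in the degenerate case where all J scores
coincide, so an untouched feature reports exactly 0. Negative importances
are reported unclipped.

## Synthetic designs

Four seeded generators cover the study conditions; each returns
(X, y, ground-truth roles) and is a pure function of its seed.

1. **Small-n linear**: 20 × 15 uniform[0,1]; features 1–10 have unit
   weights, 11–15 none.
2. **Mixed**: 60 × 15 uniform; features 1–5 enter via
   3(x₁−1.5)² + 2(x₂−1)³ + exp(x₃−0.5) + 2 ln(x₄+1) + 1.5 sin(x₅),
   features 6–10 linearly with unit weights, 11–15 not at all.
3. **Correlated block**: 100 × 10; features 1–5 independent uniform plus
   N(0, 0.1²) jitter, features 6–10 share a per-sample latent u ~ U[0,1]
   with x = u + 0.1·N(0,1), giving within-block population correlation
   (1/12)/(1/12 + 0.01) ≈ 0.893. All columns standardised (population sd),
   unit weights.
4. **Quantised**: 100 × 10; features 1–5 uniform, 6–10 binary with a 10%
   rate of ones (degenerate all-equal columns are redrawn so
   standardisation is defined); standardised, unit weights.

Response noise is Gaussian with sd = 0.1 × sd(noiseless response) in every
design — the natural reading of "noise with a standard deviation of 10%"
when no absolute reference is given. The feature jitter in design 3 is an
absolute sd of 0.1, as its construction states explicitly.

These generators emulate clean, low-dimensional, homoscedastic tabular
data. They do not emulate heavy tails, missingness, heteroscedastic noise,
mixed scales, or the dense descriptor-descriptor correlation networks of
real chemistry data, so passing the desk-scale checks shows the machinery
is correct under the stated designs, not that importance rankings on real
descriptors are beyond question.

## What co-permutation means for correlated groups — a limitation

Co-sampling makes the corruption of any member of a tightly correlated
group corrupt, with high probability, the whole group. The resulting
importance of each member is therefore close to the *group's* collective
importance, not a per-feature share of it. On the correlated-block design
this is visible and large: the block's five features each receive roughly
the whole block's score drop, an order of magnitude above an equally
weighted independent feature (the acceptance script reports this ratio,
≈ 12 with PLS). Plain PFI on the same design scores block and independent
features nearly equally (ratio ≈ 0.9), because a well-fitted model with
unit weights on standardised features loses the same amount whichever
single column is permuted. Readers comparing bars within a correlated
group can rely on their near-equality; comparing a correlated group
against independent features, the group's bars must be read as grouped
importance. This semantics is inherent to co-permutation and is reported,
not corrected, by this package.

## Problem sizes

Desk-scale defaults keep every check cheap: 10 seeds per stochastic claim,
J = 5, the four designs at their native sizes (20–100 samples, 10–15
features), 10⁴ replicates for gate calibration. The full test suite runs in
about a minute on one CPU; the acceptance script in about one minute.
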