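# Methods

## Scope

`fusebench` benchmarks combinations of fusion topology × dimensionality
reduction (DR) × classifier for predicting a three-level dementia diagnosis
(HC / MCI / AD) from tabular multimodal data, under a repeated random-split
protocol with confidence-interval comparisons, voting ensembles and
permutation feature importance. Real clinical registry data of this shape is
access-restricted, so the package pairs the benchmarking machinery with a
synthetic cohort generator whose Bayes-optimal performance is computable;
all validation runs against that generator.

## Synthetic cohort model

Per subject `i` and modality block `m` (default blocks: "clinical" with 90
features and "imaging" with 157, 1,419 subjects, emulating a merged
clinical + volumetric-MRI cohort):

```
z_i ~ N(0, 1)                                    latent disease severity
label_i = bin(z_i + eta_i; t1, t2),  eta_i ~ N(0, s_lab^2)
X_m[i,:] = z_i * w_m + F_m[i,:] B_m' + eps,      eps ~ N(0, sigma^2)
```

* `w_m` is nonzero (magnitude `signal_weights[m]`, random sign) on the first
  `n_informative[m]` features of the block.
* `F_m` are `nuisance_factors[m]` standard-normal factors shared within a
  block but independent across blocks, with loadings
  `B_m ~ N(0, nuisance_scale^2)` on every feature. They induce within-block
  multicollinearity, and — because they are block-independent — create the
  regime in which denoising each modality *before* concatenation
  (intermediate fusion) genuinely pays off.
* Missing entries are injected completely at random at `missing_rate`.
* Labels use a probit-style mechanism: thresholding `z + eta` against two
  cut-points. The marginal class masses are `Phi(t_k / sqrt(1 + s_lab^2))`
  differences; the default cut-points (0.355, 0.977) with `s_lab = 0.3`
  give roughly 63% HC / 19% MCI / 18% AD, matching the emulated cohort's
  mix.
* One global seed drives independent per-stage substreams (structure,
  latent, label noise, nuisance, noise, missingness), so changing e.g.
  `missing_rate` never perturbs the latent draw.

**Bayes reference.** The model is linear-Gaussian: with
`S = blockdiag(B_m B_m' + sigma^2 I)` and stacked loadings `w`, the posterior
of `z` given a complete feature vector `x` is Normal with variance
`v = 1/(1 + w'S^-1 w)` and mean `v·w'S^-1 x`; the class posterior integrates
the label-noise Gaussian over the threshold bins in closed form.
`bayes_reference_accuracy` Monte-Carlo-integrates the accuracy of the
argmax-posterior classifier (default 10^5–2·10^5 draws; binomial standard
error ≈ 0.001–0.002). A tiny diagonal jitter (1e-12) keeps the noise-free
limit invertible. The reference ignores missingness — it is an upper bound
for complete-data classifiers.

**What the generator does not emulate:** real clinical item semantics and
their marginal distributions, heavy-tailed or categorical features, real MRI
covariance, informative (non-MCAR) missingness, and site/batch effects.
Passing tests therefore demonstrate correctness of the machinery and the
qualitative fusion phenomena under a controlled model, not clinical
performance on registry data.

**Presets.** `nacc_like_config` fixes the emulated shape above.
`complementary_config` (two 24-feature blocks, signal 0.55 on 8 informative
features each, 5 nuisance factors per block, n = 900) was calibrated with
the Bayes oracle so that each block alone is weak (binary Bayes ≈ 0.79) but
their fusion is decisively better (≈ 0.84) — the designed ~5-point gap that
the protocol is expected to resolve. `noise_modality_config` makes the
second block pure structured noise, the regime where naive concatenation
can only dilute. `se_recovery_config` is a single 50-feature block used for
representation probes.

## Preprocessing

Filters are literal readings of standard cohort-construction rules:
per-subject earliest-visit ("baseline") selection; exclusion of features
with *more than* a threshold fraction missing (keep ≤ 0.10 by default, i.e.
the boundary is kept); removal of rows with any missing entry (no
imputation); a strict age floor (keep age > 65); and an inner merge keeping
subjects whose two modality dates are within a window. "18 months" is
interpreted as 548 days (365.25 × 1.5, rounded) with an inclusive boundary.
When a subject has several eligible visit/scan pairs, the minimal date gap
wins, remaining ties going to the earliest dates. The fixed composition
order is baseline → feature-missingness filter → record drop → age filter →
merge; each stage is recorded in a JSON report, and no stage can increase
row or column counts.

## Dimensionality reduction

All four methods share one contract: z-scoring moments, model parameters and
any tuned hyperparameters are functions of the *training* rows only;
`transform` of held-out data reuses them and never refits. Constant training
columns receive a unit divisor. Uniform pre-DR standardization is stated
policy (classically required for PCA; applied to all methods for network
stability and comparability).

* **PCA** — full SVD of the standardized training matrix; deterministic sign
  convention (largest-magnitude loading positive); explained-variance ratios
  exposed. The scree knee is the maximum perpendicular distance from the
  cumulative explained-variance curve to the chord anchored at the origin
  (zero components explain zero variance); exactly flat curves return 1 by
  convention. Default q = 8.
* **LASSO selection** — objective `(1/2n)‖y − Xw‖² + λ‖w‖₁`; λ chosen from a
  log-spaced grid by 5-fold cross-validation on the training split
  (single-value grids skip CV; λ = 0 degenerates to OLS). The transform
  *selects* the raw columns with nonzero coefficients — selection, not the
  coefficients, is what flows downstream, which also limits the influence of
  the target coding. For the 3-class task the target is coded ordinally
  (HC = 0, MCI = 1, AD = 2), respecting disease ordering. An empty active
  set raises an error advising a smaller λ.
* **Denoising autoencoder** — node layers input → 32 → 4 → 32 → output
  (two weight layers each for encoder and decoder); inputs corrupted with
  additive N(0, 0.1²) noise; target is the clean standardized matrix;
  transform = bottleneck activations. Entirely unsupervised.
* **Supervised encoder** — dense ReLU layers 64 → 32 → 10 (the 10-node
  bottleneck) → softmax head; after training the head is discarded and the
  bottleneck activations are the representation. The hidden widths are
  configurable; 64/32 is a default choice, as is the bottleneck of 10
  (read as a 10-node code by parallel with the autoencoder's 4-node
  bottleneck).

Networks are trained with Adam (learning rate 1e-3, up to 200 epochs,
optional early stopping on a 10% validation carve-out of the training rows),
implemented on scikit-learn's multilayer perceptrons; bottleneck activations
are extracted by an explicit ReLU forward pass through the fitted weight
stack. All randomness derives from the spec's seed, so repeated fits are
bit-identical, and fitted reducers serialize to a versioned JSON file that
reloads to bit-identical transforms.

## Fusion pipelines

`simple` concatenates raw blocks; `early` concatenates then fits one reducer
on the concatenation; `intermediate` fits one reducer per modality and
concatenates the reduced blocks; `single` is the per-modality baseline
(internally the singleton case of the intermediate path, so the two are
exactly equivalent). The classifier input is always re-standardized jointly
on the training rows so no block's scale dominates — a design choice, made
uniform across topologies so that identity reducers (an all-features LASSO
at λ = 0) collapse early and intermediate fusion onto simple fusion exactly.

Classifier defaults (all exposed): logistic regression with ridge penalty
(C = 1) for the binary task; random forest with 500 trees and a 64/32 ReLU
network with softmax head for the multiclass task. Per-repeat refits derive
reducer and classifier seeds deterministically from (pipeline seed, repeat).

## Evaluation protocol

50 random 75/25 train/test partitions (stratified by the 3-class label by
default, so binary and multiclass models share identical splits; at n ≈ 1400
with three classes, stratification also precludes empty-class training
sets). Split seeds derive from (base seed, repeat), making the full grid
bit-for-bit reproducible. Every pipeline and every ensemble member evaluated
under one plan shares the identical partitions, so model comparisons are
paired and ensemble votes are well defined.

The 95% CI on the mean split accuracy is `mean ± 1.96·sd/√R` (sample sd);
a percentile bootstrap is available as an alternative. The normal interval's
empirical coverage at R = 50 is ~95% (verified by simulation). Two models
differ significantly (p < 0.05 convention) iff their CIs do not overlap.
Ranking is by mean accuracy, ties broken by narrower CI, then name.

**Ensembles.** Per pipeline group, a binary ensemble votes over the 4 DR
variants and a multiclass ensemble over the 8 DR × classifier variants;
simple fusion, having a single binary model, contributes only its 2-member
multiclass ensemble. Vote ties break by training-set class prevalence, then
by label order (HC < MCI < AD).

**Permutation importance.** Mean test-accuracy drop over `n_perm`
within-column shuffles, applied to the *raw pre-standardization* features so
importances attach to original named variables grouped by modality; a
feature the fitted model never consumes scores exactly zero.

## Problem sizes used in the shipped checks

The test-bench exercises the full 51-model grid (12 per single-modality
group, 3 simple-fusion, 12 early, 12 intermediate) with its 9 ensembles on a
600-subject cohort at 10 repeats — sizes chosen to make the double
(determinism) run of the complete grid comfortably tractable on one CPU
while preserving every model family. The headline fusion comparison and the
acceptance script use the 900-subject complementary preset; the script runs
the protocol at its 50-repeat default.

## Known limitations

* Networks are multilayer perceptrons without architecture search; the AE
  and SE widths are defaults, not tuned optima.
* LASSO's multi-value grids must be strictly positive (λ = 0 is supported
  only as an explicit single-value grid).
* CI non-overlap is a conservative significance criterion; no further
  p-value machinery is provided by design.
* The Bayes reference assumes complete data and the exact generative model;
  it is not meaningful for externally loaded cohorts.
* Late (decision-level) fusion is out of scope.
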