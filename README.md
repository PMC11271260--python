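# fusebench

Benchmarking **multimodal data fusion** and **dimensionality reduction (DR)**
for dementia diagnosis prediction.

## The problem

Clinical dementia cohorts collect several modalities per subject — e.g. a
battery of clinical/neuropsychological features and volumetric measures from
structural MRI — and a three-class diagnosis (cognitively unimpaired **HC**,
mild cognitive impairment **MCI**, dementia due to Alzheimer's disease
**AD**). Concatenating modalities ("simple fusion") inflates dimensionality
and can drown informative signal in noise from a weaker modality. This
package provides the machinery to answer, on any tabular multimodal dataset:
*which combination of fusion topology and DR method predicts diagnosis best,
and is the difference statistically meaningful?*

It compares, under one protocol:

* **Fusion topologies** — single-modality baselines; *simple* (concatenate,
  classify); *early* (concatenate, reduce, classify); *intermediate* (reduce
  each modality separately, concatenate the reduced blocks, classify).
* **DR methods** — PCA (top-*q* scores of max `Var(Xw)` s.t. `‖w‖₂ = 1`,
  loadings orthonormal); a denoising autoencoder (4-node bottleneck trained
  to reconstruct clean inputs from Gaussian-corrupted ones); LASSO feature
  selection (minimize `(1/2n)‖y − Xw‖₂² + λ‖w‖₁`, keep the nonzero-coefficient
  columns, λ tuned by 5-fold CV on the training split); and a **supervised
  encoder (SE)** — a feed-forward classifier whose last hidden layer is a
  narrow 10-node bottleneck whose activations become the learned
  low-dimensional representation.
* **Classifiers** — ridge-penalized logistic regression (binary task:
  HC vs. impaired), random forest and a feed-forward network (multiclass
  task: HC/MCI/AD).
* **Protocol** — 50 random 75/25 train/test splits; mean test accuracy with a
  95% CI (`mean ± 1.96·sd/√R`); two models differ significantly (p < 0.05)
  when their CIs do not overlap; majority-vote ensembles per pipeline;
  permutation feature importance on the raw, named features.

Because real clinical registry data is access-restricted, the package ships a
**synthetic multimodal cohort generator** with a known latent structure: every
block loads on one latent disease-severity score `z ~ N(0,1)`, labels are cut
from `z` plus Gaussian label noise, within-block multicollinearity comes from
shared nuisance factors, and missingness is injected completely at random.
The model is linear-Gaussian, so the **Bayes-optimal accuracy is computable**
and every pipeline can be validated against a known upper bound.

## Worked example

```python
import fusebench as fb

# a 900-subject two-block cohort where fusing the blocks genuinely helps
cohort = fb.generate_cohort(fb.complementary_config(seed=0)).cohort
plan = fb.SplitPlan(n_repeats=25, base_seed=0)
splits = fb.make_splits(plan, cohort.labels)

se = fb.ReducerSpec.se(seed=0)          # 10-node supervised bottleneck
mods = tuple(cohort.modality_names())   # ("clinical", "imaging")

fused = fb.repeated_split_evaluate(
    fb.PipelineSpec("intermediate", mods, "logistic", "binary", reducers=se),
    cohort, plan, splits=splits)
single = fb.repeated_split_evaluate(
    fb.PipelineSpec("single", mods[:1], "logistic", "binary", reducers=se),
    cohort, plan, splits=splits)

print(fused.summary())
print(single.summary())
print("significant:", fb.significantly_different(fused, single))
```

Output:

```
intermediate[clinical+imaging]|se|logistic|binary: mean accuracy 0.796 (95% CI 0.785, 0.807; 25 splits)
single[clinical]|se|logistic|binary: mean accuracy 0.740 (95% CI 0.727, 0.753; 25 splits)
significant: True
```

Intermediate fusion with the supervised encoder classifies at 79.6% mean test
accuracy versus 74.0% for the clinical modality alone; the
non-overlapping confidence intervals mark the ~6-point gain as significant at
the protocol's p < 0.05 convention. The generator's Bayes-optimal binary
accuracy for this configuration is ≈ 0.84, so the fitted pipeline captures
most of the attainable signal.

The full 51-model benchmark grid (4 DR × 3 classifiers per single-modality
and fusion group, plus 3 no-DR simple-fusion models) and its 9 voting
ensembles run from the command line:

```bash
fusebench simulate -c config.yaml -o cohort/      # write cohort CSVs + sidecar
fusebench bench -c config.yaml -o out/            # results.csv, comparisons.csv, ranked.csv
fusebench importance -c config.yaml --pipeline-id "intermediate|se|logistic|binary" -o out/
```

Every output directory contains a `manifest.json` (config + seed + library
versions) sufficient to reproduce it bit-for-bit.

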