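# dualrisk

Explainable deep-learning analysis of **dual healthcare-system use and
opioid use disorder (OUD) risk** on synthetic EHR-like cohorts.

Patients enrolled in two healthcare systems at once (e.g. VA care plus
VA-paid community care) face fragmented records, uncoordinated opioid
prescribing, and — in several observational studies — elevated OUD risk.
Analysing *which* patients are most vulnerable requires more than a main-effects
regression: the question is how individual characteristics **interact** with
dual-system use. `dualrisk` implements that analysis end to end for
methodologists and health-services researchers who want to study, validate or
extend the approach without access to restricted clinical data:

- a **synthetic cohort generator** with the statistical structure of a large
  outpatient population — a rare outcome observed through two noisy channels
  (note-derived documentation with sensitivity 0.884 / specificity 0.966, and a
  much rarer diagnosis-code label), a binary dual-system exposure, correlated
  comorbidities, and *planted* interactions that serve as ground truth;
- a **residual feed-forward classifier** (linear stem → two residual blocks
  with layer normalisation, ReLU and dropout 0.25 → sigmoid head) trained with
  minibatch SGD on binary cross-entropy, under a 64/16/20 split with random
  under-sampling (RUS) of the majority class and early stopping on validation
  F1;
- **finite-difference attribution**: impact scores and pairwise interaction
  scores of the fitted black box, with percentile-bootstrap confidence
  intervals over the *whole* pipeline;
- a **multivariate logistic-regression benchmark** with odds ratios, Wald CIs
  and the impact-score/coefficient correlation.

## The scores

For a fitted probability model $f$ and transform $g$ (identity on the
probability scale, $\operatorname{logit}$ on the log-odds scale), the
**impact score** of feature $j$ is the population mean of the first finite
difference

$$s_j = \frac1n\sum_i\; g\!\left(f(x_i \mid x_j{=}1)\right) - g\!\left(f(x_i \mid x_j{=}0)\right),$$

with the $0\to1$ toggle replaced by a one-unit increase for continuous
features. On the logit scale the impact score of a logistic model *is* its
coefficient. The **interaction score** of features $j,k$ is the mean second
finite difference

$$s_{jk} = \frac1n\sum_i\; g(f_{11}) - g(f_{10}) - g(f_{01}) + g(f_{00}),$$

the residual effect of changing both features beyond the sum of the individual
changes; it vanishes identically for any model additive on the $g$ scale and
equals $\gamma$ exactly for $f=\sigma(\gamma x_j x_k)$. Confidence intervals
come from resampling the cohort with replacement, re-running
split → RUS → train → score per replicate, and taking the 2.5th/97.5th
percentiles (default B = 200). The AUC carries the analytic Hanley–McNeil
interval based only on the AUC and the positive/negative counts.

## Worked example

```python
from dualrisk import PipelineConfig, default_scenario, run_pipeline

cfg = PipelineConfig(generative=default_scenario(), n=20_000, scale="logit", seed=0)
results = run_pipeline(cfg)          # or run_pipeline(cfg, out_dir="report/")
print(results.summary())
```

This generates a 20,000-instance cohort (17% latent outcome prevalence, ~9%
dual-system exposure), trains the classifier and prints, among other sections:

```
== Classifier metrics ==
     split       f1  accuracy  precision   recall      auc  auc_ci_low  auc_ci_high
  Training 0.660761  0.670997   0.681980 0.640821 0.725295    0.711011     0.739578
Validation 0.419101  0.676875   0.315834 0.622705 0.698626    0.673575     0.723677
      Test 0.394615  0.674000   0.296995 0.587828 0.694827    0.672021     0.717633

== Impact scores ==                       == Interaction scores (with dual_system_use) ==
 other_drug_disorder   1.194                 age                     +0.006
alcohol_use_disorder   0.635                 ptsd                    -0.166
     prior_opioid_rx   0.619                 other_drug_disorder     -0.426
     dual_system_use   0.311                 ...
                 age  -0.009

  benchmark AUC: 0.7119
  impact-score vs coefficient Pearson r: 0.9887
```

Reading the output: training metrics are computed on the RUS-balanced set, so
precision ≈ recall there, while on the untouched (imbalanced) validation/test
sets precision is much lower than recall at the same threshold — the expected
signature of a rebalanced-training protocol. Impact scores on the logit scale
sit next to the logistic-regression coefficients (Pearson r = 0.989 here);
substance-use history dominates risk and age is mildly protective. The
interaction column recovers the planted pattern: age × dual-system use is
positive (older dual-system users are at *disproportionate* risk), while
PTSD × dual-system use and other-drug × dual-system use are negative.

The same pipeline is scriptable from the shell:

```bash
dualrisk simulate --n 20000 --seed 0 --out cohort.csv
dualrisk describe --cohort cohort.csv --out baseline.csv
dualrisk run-all --seed 0 --n 20000 --out report/
```

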