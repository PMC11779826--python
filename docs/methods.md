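# Methods

## The synthetic cohort model

Every downstream stage is exercised against cohorts drawn from a fully
specified generative model, so planted ground truth is always available.

**Latent outcome.** The true outcome is Bernoulli with

    logit P(y_true = 1 | x) = β0 + Σ_j β_j x̃_j + Σ_{j<k} γ_jk x̃_j x̃_k,

where x̃ centres continuous features at a configurable value (age at 61
years) so main effects read as effects at the centre and the planted
interaction γ_jk is exactly the population-level second difference of the
latent logit — the quantity the attribution module is later asked to recover.
The intercept β0 is not set directly: `calibrate_intercept` bisects it until
the *expected* prevalence mean(σ(η)) over a fixed probe sample matches the
target (default 0.17) — smooth, monotone, and deterministic given the probe
seed.

**Observed labels.** The analysis outcome is deliberately an error-prone
measurement of the latent status, mirroring how OUD is ascertained in
practice:

- `y_documented` — a note-derived label with sensitivity 0.884 and
  specificity 0.966 (the operating characteristics of a published clinical-NLP
  classifier for problematic opioid use);
- `y_coded` — a diagnosis-code label drawn only among true cases with
  P(coded | true) = 0.113, reproducing the roughly eight-fold under-coding of
  the outcome relative to note documentation;
- `y = y_documented OR y_coded` — the combined analysis outcome.

Coded labels are drawn independently of the documented channel given the true
status, which makes the corroboration rate (fraction of coded cases also
documented) approximately equal the documented sensitivity (~88%).

**Covariates.** Age is truncated-normal(61, 16) on [18, 100]. Binary
comorbidities use a probit-threshold latent-factor model: feature j fires when
λ_j L + √(1−λ_j²) ε_j falls below Φ⁻¹(p_j), with one shared liability factor
L. Marginal prevalences are exact by construction and the loadings
(0.45–0.65 for the substance-use and mental-health features) induce the
co-occurrence visible in real baseline tables. The dual-system exposure has
its own logistic sub-model on the covariates (younger, female and more
comorbid patients are more likely exposed; intercept fixed at −2.59, chosen
once by simulation to give ≈9% exposure prevalence).

**Default effect sizes.** Main effects: strong positive log-odds for
substance-use features (other drug 1.40, alcohol 0.75, tobacco 0.65, prior
opioid prescription 0.85), moderate for mental-health features, −0.022 per
year of age, +0.70 for exposure. Planted interactions, the sign pattern the
analysis is designed to detect: γ(age, exposure) = +0.020 per year,
γ(PTSD, exposure) = −0.55, γ(other-drug, exposure) = −0.45.

**What the generator does not emulate.** One cross-sectional cohort per call:
no multi-year instance replication and no within-patient correlation (no
downstream computation uses it). No clinical text, no diagnosis-code lists,
no missing data. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted structure under clean conditions —
not robustness to the messiness of real EHR extracts. An
`exclude_prior_outcome` option drops a configurable fraction of prevalent
cases, mirroring a sensitivity-analysis mechanism, but is off by default.

## Baseline characterisation

Group balance uses the standard (Austin) absolute standardized differences:
100·|p1−p2| / √((p1(1−p1)+p2(1−p2))/2) for proportions and
100·|m1−m2| / √((s1²+s2²)/2) for means, with >10% flagging imbalance.
Display rounding is to integer percent; internal values keep full precision.
Degenerate inputs: equal degenerate proportions give 0; unequal values with
zero pooled variance raise (the standardisation is undefined — this includes
the binary corner p1=0, p2=1).

## The classifier and training protocol

Architecture: linear stem into width h, then two residual blocks
(feed-forward → layer norm → ReLU → dropout → feed-forward → layer norm, plus
the skip connection, then ReLU), then a linear head with sigmoid. Forward and
backward passes are hand-written in numpy; gradient correctness is pinned to
finite differences in the test suite, and the parameter count to closed-form
layer arithmetic.

Protocol: 64/16/20 simple-random split; random under-sampling of the majority
class *on the training set only* (all minority indices kept, an equal-size
uniform majority subset drawn); validation and test stay at natural
prevalence. Binary cross-entropy, SGD with momentum 0.9, batch 256. After
each epoch validation F1 is computed at threshold 0.5; training halts when F1
has not strictly improved its running maximum for 10 epochs (patience).

Numerical/design choices that were genuinely open:

- **Hidden width 128.** With width 64 under dropout 0.25 the network's
  effective capacity is too small to reliably represent weak pairwise
  interactions: on some seeds an interaction cleanly identified by a logistic
  oracle (|z| > 4) was never learned at any epoch. Width 128 learns it
  reliably at desk scale; the cost is ~2× per epoch.
- **Plateau annealing + final weights.** The learning rate is halved after 3
  epochs without an F1 improvement. Because the validation-F1 surface is flat
  and noisy after the first few epochs, restoring the single best-F1 epoch
  selects an essentially arbitrary — often early, under-converged — iterate;
  by default the final (annealed) halt-time weights are kept instead, which
  stabilises the attribution scores markedly. `TrainConfig(restore_best=True)`
  switches to best-epoch restoration.
- Threshold 0.5 for F1: RUS-balanced training makes it the natural operating
  point and reproduces the precision ≪ recall signature on imbalanced
  hold-outs.
- Inputs are standardised to training-set statistics inside the classifier;
  `predict_proba` consumes raw-space feature tables, so attribution is
  unaffected.
- Dropout is placed after the first activation in each block and is always
  disabled at inference, making prediction deterministic.

Metrics: precision/recall/F1/accuracy at the threshold; AUC by the rank
statistic with mid-rank ties; the Hanley–McNeil interval
SE² = [A(1−A) + (n₊−1)(Q1−A²) + (n₋−1)(Q2−A²)]/(n₊n₋), Q1 = A/(2−A),
Q2 = 2A²/(1+A), interval A ± z·SE clipped to [0,1]. With one outcome class
the AUC is reported as not available rather than raised.

## Attribution

Both counterfactual states are imposed on **every** instance and the
difference averaged — the "coefficient-like" reading of the score; no
restriction to observed subgroups. Continuous features step by their declared
perturbation unit (age: 1 year) from the observed value; the "neither" corner
of the second difference sets binary features to 0 and leaves continuous
features at their observed values. Categorical features are contrasted per
non-reference level. Scores are available on the probability scale (the raw
sigmoid output) and the logit scale (comparable to regression coefficients;
outputs at exactly 0/1 are clipped at 1e−12 with a warning). Population
scores are exactly the mean of per-instance scores, and interaction scores
are symmetric in their arguments by construction.

The bootstrap resamples the full cohort with replacement *before* splitting,
so split, RUS and training variability are all inside the interval; each
replicate re-runs the entire pipeline with seeds derived from the replicate
index. Intervals use order-statistic percentiles (so B = 2 yields exactly
(min, max)); replicates that draw a single outcome class are redrawn a
bounded number of times. Default B = 200 at the 95% level; the point estimate
always comes from the un-resampled pipeline and is independent of the
bootstrap seed.

## Logistic benchmark

Maximum-likelihood fit (statsmodels) on the same RUS-balanced training rows
the network sees — rebalancing shifts the intercept, not the slopes — with
Wald CIs exp(β ± z·SE) and AUC on the untouched test split; a flag allows
fitting on the unbalanced data. The comparison statistic is the Pearson
correlation between logit-scale population impact scores and fitted
coefficients across features.

## Orchestration and determinism

One global seed fans out via `SeedSequence.spawn` to named stage seeds
(cohort, split, RUS, initialisation, training, bootstrap, benchmark); the
full report is reproducible bit-for-bit given the configuration, and changing
only the bootstrap seed leaves every point estimate unchanged. Reports are
versioned JSON plus CSV tables, an aligned-text rendering and forest plots.

## Problem sizes

The package's reference experiments run at desk scale, chosen so the full
pipeline remains a few minutes on one CPU: cohorts of 50,000 instances for
score-recovery experiments (interaction-sign recovery is checked over 10
seeded end-to-end runs), 100,000 for marginal/calibration checks, and
20,000-and-below for integration tests. Convergence-with-n comparisons use
2,000 vs 20,000 instances averaged over 5 seeds.

## Known limitations

- The generator's clean, fully-specified structure cannot surface issues
  arising from missingness, measurement drift, or within-patient correlation.
- Attribution assumes features can be counterfactually set independently;
  with strongly dependent features the imposed corners may be off-manifold,
  and scores inherit the usual caveats of off-distribution evaluation.
- The unnormalised finite difference is implemented; variants that normalise
  by baseline output exist in the literature and will differ on the
  probability scale.
- Only pairwise (not higher-order) interactions are scored.
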