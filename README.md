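# bchgee

Bias-adjusted 3-step **BCH-GEE** estimation of associations between
*time-varying latent classes* and *multilevel distal outcomes* in repeated
cross-sectional designs.

## The problem

Suppose clusters (the motivating example: schools and the food environment
around them) are observed at `T` time points through `J` count indicators
`U_t = (U_t1, ..., U_tJ)` with many excess zeros, and at each time point a
fresh cross-section of individuals inside each cluster contributes a
continuous outcome `Y_itk` (children's BMI in the motivating setting).
A latent class analysis with zero-inflated Poisson (ZIP) indicators
summarises the exposure as `L` classes `S_t`; the scientific question is the
marginal association between the class a cluster occupies and the outcome,

```
Y_t = beta_1 I(S_t = 1) + ... + beta_L I(S_t = L) + G_t gamma_g + Z_t gamma_z + eps_t .
```

The naive "classify-analyze" route — assign each cluster its highest-
posterior (modal) class and regress — is biased toward zero because modal
assignments carry classification error.  The classical BCH correction fixes
this, but its joint expansion needs `L^T` weight patterns per cluster
(`3^8 = 6561` in the motivating application), which is impractical with many
time points or multilevel outcomes.

## The method

`bchgee` implements a three-step estimator that needs only `L·T` weights
(24 in the same application):

1. **Step 1** (`bchgee.zip_lca`) — joint maximum-likelihood ZIP latent class
   models for all time points, with time-specific class prevalences and
   measurement parameters shared across time (measurement invariance), via
   EM.  Model selection by BIC, adjusted BIC, AIC, entropy and
   smallest-class share.
2. **Step 2** (`bchgee.classify`) — posterior class probabilities, modal
   assignment, the pooled classification-error matrix
   `D[r, s] = P(C = r | S = s)` and the BCH weight matrix `D* = D^{-1}`.
3. **Step 3a** (`bchgee.lta`) — latent transition analysis of the assigned
   classes: a hidden Markov model whose emission matrix is fixed at `D`,
   estimating initial-class and transition probabilities.
4. **Step 3b** (`bchgee.gee`) — the distal-outcome model.  Each individual's
   record is replicated `L` times (one copy per candidate class), weighted
   by the `D*` column of the cluster's assigned class, and a weighted GEE

   ```
   S(beta) = sum_i X~_i' V~_i^{-1} W~_i (Y~_i - X~_i beta) = 0
   ```

   is solved under working independence or a two-parameter exchangeable
   structure (`alpha_w` within cluster-time, `alpha_b` between time points),
   with a sandwich covariance and an optional cluster bootstrap.

`bchgee.datagen` generates synthetic study data (Markov classes, ZIP
indicators calibrated to a target class-separation entropy, two-level Normal
outcomes), and `bchgee.simstudy` runs the Monte-Carlo comparison of BCH-GEE
against the naive GEE (percent bias, MSE, empirical and sandwich variances,
Type-I error).

## Worked example

```python
import numpy as np
from bchgee import (make_scenario, simulate_dataset, fit_zip_lca,
                    posterior_probs, modal_assign, classification_error,
                    bch_weights, fit_lta, expand_data, fit_weighted_gee,
                    fit_naive_gee, wald_test)

cfg = make_scenario(entropy="low", effect_size=0.25, n_schools=600,
                    children_range=(20, 40), seed=7)
panel, children, paths = simulate_dataset(cfg)

model = fit_zip_lca(panel, L=3, n_starts=5, seed=1)      # Step 1
post = posterior_probs(model, panel)                     # Step 2
assign = modal_assign(post)
D = classification_error(post, assign)
weights = bch_weights(D, assign)
lta = fit_lta(assign, D)                                 # Step 3a
design = expand_data(children, assign, weights)          # Step 3b
fit = fit_weighted_gee(design, structure="independence")
naive = fit_naive_gee(children, assign, L=3)

c = np.array([1.0, -1.0, 0.0, 0.0])                      # beta1 - beta2
print("true contrast     :", cfg.betas[0] - cfg.betas[1])
print("BCH-GEE contrast  :", round(wald_test(fit, c).estimate, 3))
print("naive GEE contrast:", round(wald_test(naive, c).estimate, 3))
print("transition diag   :", np.round(np.diag(lta.transition), 3))
```

Output from this exact script:

```
true contrast     : 0.6499999999999986
BCH-GEE contrast  : 0.75
naive GEE contrast: 0.594
transition diag   : [0.906 0.952 0.934]
```

The generating contrast is 0.65.  On any single dataset both estimates
carry sampling noise (about ±0.1 at this size); the difference between the
estimators is systematic, not per-dataset: across replications the naive
estimate is attenuated toward zero by the classification error while the
BCH-weighted estimate is unbiased — this is what `bchgee.simstudy` and
`scripts/acceptance.py` quantify.  The recovered transition diagonal
reflects the sticky generating chain (0.93 per step).

A command-line interface mirrors the library
(`bchgee simulate | fit-lca | select-classes | classify | fit-lta |
fit-gee | bootstrap | sim-study`); every run writes a JSON provenance
record alongside its outputs.

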