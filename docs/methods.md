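# Methods

This note documents the statistical model behind `bchgee`, the synthetic
data generator used to validate it, and the numerical choices made in the
implementation.

## 1. Model and estimand

Clusters ("schools") `i = 1..N_s` are observed at time points `t = 1..T`.
At each time the cluster occupies one of `L` latent classes `S_it`; the
chain `S_i1..S_iT` is first-order Markov with initial probabilities
`pi_s` and transition matrix `tau`.  The class is measured by `J`
conditionally independent zero-inflated Poisson (ZIP) count indicators,

    P(U = u | S = s) = prod_j ZIP(u_j; p_{j|s}, lambda_{j|s}),
    ZIP(0) = p + (1-p) e^{-lambda},   ZIP(u>=1) = (1-p) Pois(u; lambda),

with *measurement invariance*: `p_{j|s}` and `lambda_{j|s}` do not depend
on `t`.  At each time a fresh cross-section of `n_it` individuals per
cluster contributes a continuous outcome; its marginal model is a
cell-means regression on the concurrent class plus covariates.  The
estimand is the set of class-mean contrasts `beta_r - beta_s`.

Because individuals are not followed over time, within-cluster dependence
is a two-level exchangeable pattern: correlation `alpha_w` between
outcomes in the same cluster-time, `alpha_b` between outcomes of the same
cluster at different times.

## 2. The three steps

**Step 1 — pooled ZIP latent class model.**  EM over cluster-time
observations with time-specific prevalences `pi_{t,s}` and shared ZIP
parameters.  The Markov structure is deliberately ignored here (it is
recovered in Step 3a); pooling under measurement invariance is what makes
one classification-error matrix meaningful for all time points.
Free parameters: `T(L-1) + 2JL`.

**Step 2 — classification error and BCH weights.**  Posteriors by Bayes
rule, modal assignment `C_it` (ties to the lowest class index), and the
pooled error matrix

    D[r, s] = q_{r|s} = sum_{i,t} P(S=s | U_it) 1{C_it = r} / (N_s T P(S=s)),

with `P(S=s)` the pooled mean posterior.  Columns of `D` sum to one.
A cluster-time assigned to class `r` receives as its weight vector over
the `L` expanded copies the **r-th column of `D* = D^{-1}`** — the unique
vector with `sum_r q_{r|s} w_r = e_s`, so the weighted copies are
conditionally unbiased for the true-class cells.  (In the convention that
indexes the error matrix true-by-assigned, this is the familiar "row r of
the inverse".)  Weights may be negative and are never truncated; the share
of negative entries is reported as a diagnostic.  A near-singular `D`
(condition number above `1e8`, typically a vanishing class) is an error:
the correction is then unavailable and a model with fewer classes should
be considered.

**Step 3a — latent transition analysis.**  The assigned classes are
treated as noisy emissions of the true chain with emission matrix fixed at
`D` (stored as baseline-category logits `log(q_{l|s}/q_{L|s})`, zero cells
clipped at `1e-12`).  EM with forward-backward recursions estimates `pi`
and `tau` only; transitions are time-homogeneous by default with a
per-interval option.  With `D = I` the estimates reduce exactly to the
empirical initial-share and transition-frequency MLEs.

**Step 3b — weighted GEE.**  Outcomes, covariates and weights are expanded
`L`-fold; the class-indicator block of each individual is `I_L`.  The
estimating equation is solved by iterating: residuals; scale
`phi = sum_i e_i' W_i e_i / (N_total - p)` with `N_total` the number of
*individuals* (not expanded rows); moment estimators of `alpha_w`,
`alpha_b`; and a generalized-least-squares update of `beta`.  The
working correlation of the expanded data sets copy pairs within a
time point to zero but applies `alpha_b` across *all* copy pairs between
time points.  The sandwich covariance uses
`bread = sum_i X_i' V_i^{-1} W_i X_i` and per-cluster score outer
products.  The naive comparison estimator is the same machinery with a
single copy, modal class indicators, and unit weights.

Inference per contrast is a two-sided Wald test on the sandwich variance.
A cluster bootstrap (resampling clusters with replacement, Step-1 model
held fixed so class meanings cannot drift or label-switch across
replicates) provides an alternative standard error.

## 3. Synthetic data generator

`datagen` emulates the validation design: `N_s` clusters, `T = 4` time
points, `L = 3` classes, `J = 3` ZIP indicators; initial probabilities
exactly `(1/3, 1/3, 1/3)`; "sticky" transitions (diagonal 0.93, the
remaining mass on adjacent classes) or a "mobile" alternative (diagonals
0.63–0.74).  Outcomes follow

    Ybar_it = beta_{S_it} + b_i + b_it,   Y_itk = Ybar_it + beta_z z_itk + eps_itk

with `b_i ~ N(0, sigma_b^2)`, `b_it ~ N(0, sigma_w^2)`,
`eps ~ N(0, sigma^2)`, `z_itk ~ Bernoulli(0.5)`, and `n_it` uniform on a
stated range (20–80 at full scale; 20–40 in the scaled-down runs).  The
variance components are chosen so that the total variance is 6.76 and the
implied correlations are `alpha_w = (sigma_b^2+sigma_w^2)/total = 0.08`
and `alpha_b = sigma_b^2/total = 0.05`, giving
`(sigma_b^2, sigma_w^2, sigma^2) = (0.338, 0.2028, 6.2192)`.  Class-mean
presets: `(22, 21.87, 21.74)` for standardized effect size 0.05,
`(22, 21.35, 20.70)` for 0.25, all zeros for the null.  `beta_z = 0.20`.

**Entropy calibration.**  Class separation is summarised by the relative
entropy `1 - [-sum p log p] / (N log L)` of true-model posteriors.  The
exact ZIP parameter values behind the study's two separation levels are
not published, so presets are *calibrated*: a one-parameter family shrinks
an anchor parameter set toward its across-class centre (rates on the log
scale, zero inflation on the logit scale) and the knob is bisected until a
Monte-Carlo entropy estimate (fixed internal seed, 100k observations) hits
the target — 0.79 ("high") or 0.52 ("low") within ±0.005.  The anchors
were shaped to reproduce the *documented confusion structure* of the
study conditions, not just the entropy scalar: the high-count class 1
carries substantial zero inflation, so that at low separation a class-1
cluster drawing structural zeros on all indicators resembles the
low-count class 3.  The calibrated low preset's implied error matrix has
diagonal roughly (0.72, 0.75, 0.89) with 1-to-3 confusion ~0.18; the high
preset (0.95, 0.87, 0.94) with negligible 1-to-3 confusion.  Calibrated
parameters are frozen as module constants so study conditions are
deterministic; re-running the calibration reproduces them.

What the generator does *not* emulate: real outlet-count marginals and
trends, unbalanced panels, covariate-dependent class membership, or
child-level covariate structure beyond a single Bernoulli predictor.
Passing tests therefore validate the estimator under the stated generating
model, not robustness to violations of it.

## 4. Numerical choices

* **EM (Step 1):** responsibilities at cluster-time level; the M-step
  splits each observed zero between structural and Poisson zeros with the
  current-parameter posterior, making the update an exact EM step (the
  observed-data log-likelihood is provably non-decreasing, and the suite
  checks it).  `lambda` floored at `1e-6`, `p` clipped to
  `[1e-6, 1-1e-6]`; relative log-likelihood tolerance `1e-8`
  (`1e-7` inside the simulation harness); classes relabelled by decreasing
  total rate after every fit.  Starts: an informed start (quantile split
  on total counts, softened toward uniform) plus `n_starts - 1` random
  Dirichlet starts; the informed start makes the simulation harness fast
  and reliable, the random starts guard against local optima.
* **Working-correlation solve (Step 3b):** per-cluster systems are solved
  through the structure of the correlation matrix — batched `L x L`
  solves per cluster-time block plus a Sherman-Morrison step for the
  rank-one between-time part — never forming dense per-cluster inverses.
  The solver is verified against dense inversion to `1e-8` in the suite.
* **Indefiniteness boundary.**  Because `alpha_b` couples all `L^2` copy
  pairs between time points while copies are uncorrelated within a time
  point, the expanded-data "correlation" matrix is *indefinite* for
  moderate cell sizes; only invertibility is required by the estimating
  equation, so this is tolerated.  One genuine boundary exists: the
  copy-sum direction of a within-time block has eigenvalue
  `(1-alpha_w) + n(alpha_w - L alpha_b)`, which vanishes near
  `n ~ (1-alpha_w)/(L alpha_b - alpha_w)` (about 13 children at the study
  values).  Cell sizes at or near that root make the solve singular (an
  explicit error) or ill-conditioned; the study designs (20+ children per
  cell) sit above it.
* **GEE iteration:** initial `beta` from the weighted
  working-independence solve; convergence when the max absolute `beta`
  change drops below `1e-6` (max 100 iterations); one iterative-refinement
  step per linear solve; a half-step damping engages when the step size
  stops shrinking, which settles the occasional two-cycle of the
  alpha/beta alternation onto its fixed point.  `phi` is floored at
  `1e-8` with a warning (negative weights can make the weighted residual
  sum of squares negative in pathological replicates).
* **Moment estimators:** quadratic forms `0.5 e' R_struct (W e)` count
  each unordered pair once with a single weight per pair; the pair counts
  `N_w/L` and `N_b/L` use the same unordered convention, so with unit
  weights and one copy the estimator reduces to the textbook exchangeable
  moment estimator with a `-p` degrees-of-freedom correction.
* **Ties and degeneracies:** modal ties go to the lowest class index;
  empty classes raise errors naming the class; fits with any prevalence
  below `1e-4` are flagged degenerate.

## 5. Simulation harness and problem sizes

`run_scenario` generates each replicate once and shares it across
estimators and correlation structures; replicate seeds spawn
deterministically from the master seed, and replicate failures are logged
and excluded with counts reported.  Reported measures follow the usual
conventions: `%bias = 100 (mean - true)/true` (raw bias when the truth is
zero), MSE and variances scaled by 1000, `Var_e` the empirical variance of
estimates, `Var_f` the mean sandwich variance, Type-I error the rejection
fraction of the per-contrast Wald test at the 5% level with its binomial
Monte-Carlo SE.

The package's standard validation runs use 600 clusters, `T = 4`, 20–40
children per cluster-time, and 200 replicates per scenario (the full-size
design — 1230 clusters, 20–80 children, 500
replicates — is available through the same configuration objects).  At
these sizes the Monte-Carlo SE of a raw percent-bias estimate for the
small-effect scenarios is roughly 4 percentage points — the same order as
the biases being measured.  The harness therefore supports a
*control-variate* bias estimate: requesting the `"oracle"` estimator fits
the same GEE on the **true** latent classes, which is exactly unbiased
for the contrasts and shares each replicate's outcome noise; subtracting
it replicate by replicate (`pct_bias_cv`) estimates the identical bias
with a 35–40% smaller Monte-Carlo SE (about 2.6 points at 200
replicates).  The raw and control-variate columns are both reported; the
acceptance script's bias summary uses the control-variate estimate.

## 6. Known limitations

* One pooled `D` is used for all time points (consistent with measurement
  invariance); a per-time-point error matrix is kept in the data model
  (`D_t = D`) but not separately estimated.
* Proportional (soft) assignment, covariates in the class-membership and
  transition models, non-identity links, and lagged-class outcome models
  are out of scope.
* Step 3a produces no standard errors (none are consumed downstream).
* The sandwich variance can under- or over-state uncertainty in small
  samples or with large effect sizes; the cluster bootstrap is the
  recommended alternative for final inference.
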