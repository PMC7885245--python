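# Methods

## Setting and model

Each record carries an original predicted in-hospital death probability
`p_orig` from an existing severity model, its logit
`lp = log(p_orig / (1 − p_orig))`, a binary hospital-death outcome, an
ICU identifier, and an integer admission order. All recalibration
models are Bernoulli likelihoods for death with `lp` as the only
covariate:

* **Model 1 (intercept offset).** `logit(p) = β₀ + lp`. The MLE of β₀
  solves the monotone score equation `Σ expit(β₀ + lp_i) = Σ y_i`, so
  the fitted model has in-sample SMR exactly 1. Fitted as a GLM with
  `lp` as offset (statsmodels).
* **Model 2 (logistic recalibration).** `logit(p) = β₀ + β₁·lp`,
  the ordinary two-parameter logistic MLE. Its in-sample calibration
  slope and intercept are exactly 1 and 0, because the calibration
  regression of the outcome on `logit(pred)` is a reparametrization of
  the model itself. Identifiability requires non-constant `lp`;
  complete separation is detected and reported, never silently
  regularized.
* **Model 3 (hierarchical generalized additive update).**
  `logit(p) = β₀ + f(lp) + u_i`, `u_i ~ N(0, σ²_u)`.

## The hierarchical GAM fit

`f` uses a cubic B-spline basis of dimension 10 (degree 3, interior
knots at quantiles of the observed `lp`, boundary knots at its range)
with the exact integrated-squared-second-derivative penalty (2-point
Gauss–Legendre per knot span, exact for the piecewise-quadratic
integrand). A sum-to-zero constraint over the fitting sample is applied
by reparametrizing into the null space of the column-mean row, leaving
the constant to the model intercept. The random intercepts are
ridge-penalized unit dummy coefficients; the ridge weight λ_u maps to
the variance component via `σ²_u = 1/λ_u` (the standard
random-effects-as-penalized-smooths equivalence).

Given smoothing parameters, coefficients maximize the penalized
Bernoulli log-likelihood by penalized IRLS with step-halving (penalized
deviance kept monotone; relative-change tolerance 1e-8, 200-iteration
cap, failure raises with the last penalized deviance). The two log
smoothing parameters are chosen by Laplace-approximate restricted
marginal likelihood,

    −ℓ(β̂) + ½ β̂ᵀS_λβ̂ + ½ log|H + S_λ| − ½ log|S_λ|₊ ,

optimized by Nelder–Mead (search box |log λ| ≤ 14, warm-started inner
fits), with a coarse LAML grid as fallback if the optimizer returns no
finite value. `edf` is the trace of the influence matrix
`(H + S_λ)⁻¹H`, including the unpenalized intercept column (which
contributes exactly 1). Because the intercept is unpenalized, the
fitted model's in-sample SMR is exactly 1, like models 1–2.

Prediction for an ICU unseen at fitting time uses `u = 0`, the random
effect's mean. Spline evaluation clamps `lp` to the knot range; the
recalibration is only trusted on the support of the fitting sample.
On a shared cohort this implementation tracks R's reference GAM
machinery closely (prediction correlation > 0.9999, same effective
degrees of freedom to ~0.2), but no coefficient-level equality is
claimed: basis parameterization and optimizer details differ.

## Evaluation battery

* **AUROC** — Mann–Whitney rank form, ties counted ½.
* **Brier / scaled Brier** — mean squared error;
  `1 − Brier/(p̄(1−p̄))`.
* **Modified Hosmer–Lemeshow** — deciles of predicted risk (stable tie
  assignment), `H = Σ (O−E)²/(E(1−E/n_g))`, df = groups − 2 (the models
  are fitted on the data they are tested on). The plain test is
  overpowered in very large cohorts, so above a reference size (default
  25,000 — the registry regime) the statistic is evaluated on repeated
  random subsamples of the reference size and the median statistic and
  p reported; the whole-sample statistic is always reported alongside.
  Degenerate deciles (E = 0 or E = n_g) are merged into the next group
  with df adjusted.
* **Calibration** — decile table of mean predicted vs observed; slope
  and intercept from the free logistic regression of the outcome on
  `logit(pred)`, plus calibration-in-the-large (intercept with slope
  fixed at 1 via offset). Both intercept conventions are labeled in the
  output because they differ off the fitted model's own predictions.
* **AIC** — `−2ℓ̂ + 2k` with k = 1, 2, or `edf` for models 1/2/3.
* **Optimism-corrected AUROC** — Harrell's bootstrap (patients resampled
  with replacement; optional cluster bootstrap by ICU, off by default):
  optimism is the mean of (resample AUROC − original-cohort AUROC) over
  refits, subtracted from the apparent AUROC; non-convergent resamples
  are dropped and counted, more than 10% aborts. For model 3 a
  posterior-simulation alternative draws coefficient vectors from the
  Laplace-approximate Gaussian posterior and reports the mean shortfall
  of drawn-coefficient AUROC against the point estimate; this is this
  package's own definition of posterior optimism.

## Quality monitoring

* **Funnel plots.** Per ICU: O (observed deaths), E (Σ predicted risk),
  V (Σ p(1−p)), SMR = O/E, z = (O−E)/√V. The drawn limit curves use the
  Gaussian approximation on the SMR scale, `center ± z·√(E(1−p̄))/E`
  with p̄ the cohort mean risk, while outlier decisions use each unit's
  exact V — display and decision are deliberately separated. The center
  defaults to the realized overall SMR (a fixed center of 1 is
  supported). Overdispersion factor `Φ = mean(z²)`; Φ > 1 signals
  variation beyond binomial noise.
* **EWMA charts.** `z_t = λ·y_t + (1−λ)·z_{t−1}` over admissions
  ordered by `admission_seq`, starting at the cohort (or unit) mean
  mortality; default λ = 0.005. The center line applies the same
  recursion to the predicted risks (a flat-center option exists), and
  limits are `center_t ± k·√v_t` with the exact time-varying variance
  `v_t = Σ λ²(1−λ)^{2(t−i)} p_i(1−p_i)` — no steady-state shortcut, so
  early-chart widths are correct. Excursions are contiguous runs beyond
  the 3-SD limits. Ties in admission order must be resolved by the
  caller; duplicate sequence values are rejected.

## Synthetic cohorts

The generator emulates the registry's statistical structure, not its
case mix: `lp` is normal with scale 2.2 — chosen so the implied
predicted-risk distribution reproduces the registry's mean 0.170 and SD
0.228 — and location tuned by a 1-D root search on the drawn sample so
mean predicted risk hits the 0.17 target within 0.005. True risk is
`expit(−1.32 + 1.02·lp + c·(lp − l̄)² + u_i)`: the default linear
miscalibration reproduces the two-fold overestimation regime (observed
mortality ≈ 8%, SMR ≈ 0.47); `c` (default 0) adds curvature for
exercising the smooth update; `u_i ~ N(0, 0.3²)` gives unit
heterogeneity of a size that visibly overdisperses funnel plots when
ignored. Unit sizes follow a rounded log-normal partition (log-SD 0.6)
of the cohort across 44 units. Everything derives from one integer
seed; the same seed reproduces the cohort byte-for-byte.

What the generator does not emulate: clinical covariates, case-mix
drift over time, admission clustering within calendar time, data-entry
errors, or informative missingness. Passing tests therefore demonstrate
the statistical machinery under the stated structure, not performance
on any real registry.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at reduced
sizes chosen as this package's own working defaults: n = 10,000 for
end-to-end fits, n = 30,000 for parameter recovery, 500 replicates at
n = 25,000 for the Hosmer–Lemeshow type-I error, 50 paired replicates
at n = 6,000 for overdispersion, 50 replicates for the EWMA operating
characteristics. Logistic fits use statsmodels' IRLS; tests verify them
against an independent Newton solver to 1e-6. Probabilities are clipped
only inside likelihood evaluations (1e-12) and IRLS weights (1e-10);
input risks are never clipped — invalid rows are excluded at ingest and
counted.

## Known limitations

* Smoothing-parameter selection keeps noise-level curvature on a
  minority of draws even when the truth is exactly linear: at
  n = 10,000 roughly one seed in three retains a smooth whose maximum
  in-sample deviation from the linear update reaches 0.02–0.05 on the
  risk scale. R's reference GAM machinery reproduces the same deviation
  on the identical data, so this is a property of marginal-likelihood
  smoothing itself; the nested-agreement test therefore asserts the
  replicate median. By the same shrinkage, the hierarchical model's Φ
  typically lands below 1 (residuals partly absorbed by the random
  intercepts) rather than exactly at 1.
* The modified Hosmer–Lemeshow subsample standardization is one
  reasonable realization of "evaluate at a reference size"; other
  large-sample corrections exist and would give different p values.
* σ̂²_u from 44 units is noisy (order-of-magnitude accuracy, not
  precision); per-unit EWMA charts for units with < 30 admissions are
  produced but flagged as unstable.
* `admission_seq` is taken as given; no tie-breaking or calendar logic
  is applied.
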