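# Methods and design notes

## Instruments and scoring

The SAQ has 19 items in five subscales; each subscale score is
`(sum − min_sum) / (max_sum − min_sum) × 100`, higher = better. The default
item map follows the standard instrument (PL: 9 items scored 1–6; AS: 1
item 1–5; AF: 2 items 1–6; TS: 4 items 1–5; DP: 3 items 1–5) and is
overridable, since administrations differ. Missing items are mean-imputed
within a subscale when at least half its items are answered, otherwise the
subscale is reported missing (NaN, never 0); strict complete-case scoring
is available via `allow_imputation=False`. This imputation rule is common
SAQ practice, not something the source analysis specifies.

EQ-5D-5L utilities come from an additive tariff: per-dimension, per-level
decrements with level 1 decrementing nothing. The bundled Chinese value
set satisfies utility(11111) = 1 and utility(55555) = −0.391 exactly; both
endpoints are enforced at load time, and any tariff supplied as a
`dimension, level, decrement` CSV is validated for non-negative,
level-monotone decrements. Utilities are kept at full float precision and
rounded only in reports (4 dp).

## Direct estimators

The design matrix is an intercept plus the five subscales divided by 100.
The 0–1 covariate scale was chosen because evaluating the shipped
published coefficients at the published cohort subscale means then
reproduces the published mean predictions for OLS (0.8725), Tobit (0.9090)
and RMM (0.9008) to 4-decimal rounding; this derivation ships as a test.
Age, sex, disease type and illness duration are excluded from the default
design (they were dropped as non-significant in the source analysis); the
generator still produces them so users can extend the design.

* **OLS** — closed form (statsmodels).
* **Tobit** — right-censored normal likelihood, BFGS on (β, log σ) with a
  Nelder-Mead polish; prediction is the *latent index* x'β, not
  E[min(y\*, 1)], which is how the source study's Tobit means and >1
  maxima are reproducible.
* **Log-link Gaussian GLM** — IRLS, started from an OLS fit on log
  responses floored at 0.05 so occasional non-positive utilities cannot
  derail initialisation; prediction exp(x'β).
* **CLAD** — Powell's estimator by alternating median regression on the
  active set {x'β < 1} with active-set recomputation until the set
  repeats; the best objective along the way is kept and an iteration cap
  (50) flags cycling. Standard errors by nonparametric bootstrap (199
  resamples by default; disabled inside cross-validation for speed).
* **RMM** — S-estimation from 200 elemental subsets (bisquare c = 1.5476,
  b chosen for 50% breakdown, three IRLS refinement steps each), then an
  M step by IRLS with c = 4.685 (95% Gaussian efficiency) at fixed scale.
  The subsampling seed is an explicit argument. An exact fit (robust
  scale ≈ 0) is an error rather than a silent degenerate result.

## Mixture models

**ALDVMM.** Within component k, P(y = 1) = 1 − Φ((Ψ − x'β_k)/σ_k),
P(y = floor) = Φ((floor − x'β_k)/σ_k), and the normal density between;
the three pieces integrate to one without renormalisation. Membership is
intercept-only multinomial logit (the published component table prints no
membership covariates). Ψ defaults to the largest attainable utility
strictly below 1 — for the bundled tariff 1 − 0.043 = 0.957 — and is
configurable since the source analysis never states its value.
Observations inside the gap (Ψ, 1) are an input error. Estimation is
quasi-Newton (BFGS, numerical gradients) on the full likelihood from
multiple random starts (default 20, seeds derived from one seed argument),
with a simplex polish when line search stalls; components are relabelled
by increasing intercept. Predictions combine the ceiling mass, floor mass
and truncated-normal mean per component and therefore always lie in
[floor, 1].

**Beta mixture.** Two parts that factorise: a logistic regression for
1{y = 1}, and a C-component beta mixture (default C = 1, matching the
single published component) on y\* = (y − L)/(U − L) for y < 1, with
logit-linked means and log-parameterised precisions. Rescaling bounds
default to the tariff range (L = −0.391, U = 1); y\* = 0 is nudged to
ε = 0.5/n (standard beta-regression practice), y = 1 never is — it
belongs to the logit part. The reported log-likelihood includes the
−log(U − L) Jacobian per continuous observation so it is comparable
across bounds.

Numerical guards: log-σ and log-φ are bounded (|log σ| ≤ 12,
−6 ≤ log φ ≤ 14) and non-finite likelihoods return a large penalty, which
keeps BFGS inside the feasible region without constrained optimisation.

## Indirect mapping

Per dimension, a proportional-odds model P(level ≤ j|x) =
logistic(cut_j − x'β) on the five subscales (no intercept; cut points
absorb it), fitted with statsmodels' ordinal MLE. The source text calls
the model multinomial in one place and ordered in another; the ordered
model is primary here because cut points are what the published table
reports. Levels unobserved in training are collapsed out and carry zero
predicted probability. Expected utility uses the expected-decrement
formula, exact for additive tariffs under cross-dimension independence;
Monte-Carlo and modal-state conversions exist for sensitivity analysis.
For the *published* indirect coefficients (three cuts ⇒ four categories),
which levels were collapsed is unknown; the default category→level map is
(1, 2, 3, 4) and is user-overridable — predictions from the published
indirect model carry that assumption.

## Evaluation

CCC uses population (1/n) moments (Lin's original convention; a sample
variant sits behind `sample_moments=True`). Cross-validation shuffles rows
into k near-equal folds with an explicit seed; metrics are reported both
pooled over all held-out predictions (primary) and per fold, since either
convention could underlie a published CV table. Rows of one patient can
land in different folds by default, mirroring a row-level split of pooled
baseline/follow-up data; `groups=pid` (CLI `--group-by-pid`) keeps
patients together and is recommended when waves are strongly dependent.

## Synthetic cohort generator

One latent severity factor θ ~ N(0, 1) per patient drives everything:

* subscale = clip(μ + σ·(λθ + √(1−λ²)ε), 0, 100), with (μ, σ) solved in
  closed form so the *clipped* variable matches the target mean/SD — this
  is also how AS's near-uniform spread (mean 36.18, SD 34.07) arises, via
  a wide normal clipped at both ends;
* dimension level from ordered thresholds on a_d(−θ) + √(1−a_d²)ε_d, so
  the marginal latent is standard normal and thresholds are
  interpretable as cumulative-probability quantiles. Self-care has a
  fixed low loading (0.35) because its observed correlations with the
  subscales are much weaker than the other dimensions'.

Calibration (once per target set, cached by a hash of the targets; the
default calibration ships as package data): Nelder-Mead over (common
loading a, threshold shift, threshold spread) on a fixed 50,000-draw batch
to hit utility mean 0.87, SD 0.14 and ceiling 0.311; then bisection of
each subscale's λ against its Spearman target, and of the follow-up shift
δ against the paired-change target 0.1256. The calibration RNG seed is
fixed: calibration is part of the model definition, while cohort draws use
the user's seed. Infeasible targets (e.g. ceiling share 0) raise a
calibration error with diagnostics rather than returning degenerate
thresholds.

Follow-up: a fraction of patients (default 75/380) is drawn with weights
∝ exp(−θ) — sicker patients are likelier to be followed after discharge —
and re-simulated at θ + δ. Without that selection, a mean improvement of
0.1256 from a baseline mean of 0.87 would require pushing nearly the whole
subset to full health. Levels are redrawn from the shifted latent rather
than via transition matrices (no transition data exist to calibrate them).
Covariates (age 63.04 ± 9.68, 53.72% male, disease-type shares, lognormal
illness duration 2.50 ± 5.54) are independent of θ.

What the generator does *not* emulate: the empirical joint distribution of
a real clinic cohort (only marginals, one rank-correlation structure and
a ceiling), item-level SAQ responses, real missingness, or within-patient
correlation beyond the shared θ of paired waves. Tests passing on these
cohorts show the estimators and harness are internally correct at
realistic signal strengths; they do not certify predictive accuracy on
real patients.

## Problem sizes and numerical choices in the test suite

Parameter-recovery tests simulate from each estimator's own model at
n = 5,000; the direct-estimator replicate harness uses 50 replicates and
checks coefficient-wise coverage within 2 SEs at a 90% pass rate (CLAD,
which has no closed-form SE, is scored against the Monte-Carlo SE across
replicates). Mixture predictions are checked against 10⁶-draw sampling
oracles within 3 Monte-Carlo SEs. Generator acceptance statistics average
10 seeds at n = 380. Mixture fits in tests use 3–5 random starts; the
library default remains 20.

## Known limitations

* Tobit/CLAD assume a single known censoring point (1); no two-limit
  variants.
* No heteroskedasticity-robust or clustered standard errors.
* Beta-mixture precisions are covariate-free; components are capped at
  practical counts (selection by AIC/BIC is available but not automatic).
* The published ALDVMM/BM columns omit scales, weights, precision and Ψ,
  so expected-value prediction from the published mixture columns
  requires explicit user assumptions; exact reproduction of the source
  study's mixture prediction summaries is not possible from the printed
  tables.
* The published indirect model's category→level map is an assumption
  (see above) — override it if you have information about the original
  level coverage.
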