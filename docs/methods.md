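# Methods

This note records the statistical model behind each stage, the defaults
and why they are what they are, and the choices made where the design was
genuinely open. Nothing here asserts an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Scope and estimand

The pipeline estimates the conditional odds ratio of a binary exposure
(a disability indicator) on a binary outcome (current e-cigarette use)
in survey microdata with a stratified multistage design, adjusting for a
small set of confounders chosen by a data-driven screening rule. For each
disability subgroup — respondents reporting the disability of interest
together with respondents reporting no disability at all; respondents
with only other disabilities or with unclassifiable (missing) profiles
are excluded from that subgroup — two models are reported: Model 1
adjusts only for the forced demographics (age, gender, race/ethnicity),
Model 2 additionally for the screened confounders.

## Confounder screening (stability selection)

A variable counts as associated with an endpoint when repeated-subsample
L1-penalized logistic fits keep it in the model almost always:

* 300 iterations (default), each on an 80% subsample drawn **without
  replacement** of size ⌈0.8·n⌉. Subsampling without replacement is the
  convention of stability selection; a subsample that loses an outcome
  class is redrawn (at most 10 times).
* Per iteration, the penalty λ_m minimizes the mean 10-fold
  cross-validated binomial deviance, folds stratified on the endpoint.
  Ties resolve toward the larger penalty (the sparser model).
* The penalized objective is (1/n)·NLL + λ‖β‖₁ on columns standardized to
  unit variance **within the subsample** (each iteration is a
  self-contained fit), intercept unpenalized, so λ_max =
  max_j |x_jᵀ(y − ȳ)|/n. The default grid is 100 log-spaced points down
  to 10⁻⁴·λ_max, rebuilt per subsample.
* A variable is *selected* in an iteration iff at least one of its
  non-missing dummy columns is nonzero at λ_m. Categorical variables are
  reference-coded against their first observed non-missing level, and the
  explicit MISSING level always gets its own dummy precisely so this rule
  can ignore it: a missing-response category carries no substantive
  association.
* Variables selected in **strictly more than 95%** of iterations are
  associated with the endpoint; the confounder set of a subgroup is the
  intersection of the two endpoints' associated sets; forced demographics
  are added afterwards unconditionally.
* Penalized fits are unweighted. The survey design enters the final
  regression models only; screening is treated as a data-reduction step,
  not an inferential one.

What the >95% rule does and does not control: subsampling measures the
stability of an association *within the dataset at hand*. A noise
covariate that happens to have a strong sample association (a |z| ≈ 3
fluke at large n) will be selected stably and admitted; this inflates the
adjustment set slightly but does not bias the exposure estimate, because
admitted covariates are independent of the exposure given the truth's
real confounders.

### Solver

The inner solver is a compiled (numba) glmnet-style coordinate descent:
outer quadratic approximation at the current linear predictor, cyclic
soft-threshold updates with active-set refinement sweeps, warm starts
along the decreasing grid, and early path termination once every
predictor is active and the training deviance stops improving (relative
change < 10⁻⁵ of the null deviance). Cross-validation path fits use a
single quadratic approximation per grid step — with warm starts the
approximation error is far below fold-to-fold noise — while final refits
re-weight to convergence (coefficient change < 10⁻⁶). The unit tests pin
the solver against an independent convex solver (scikit-learn's saga) at
matched penalties, and against the KKT zero-solution bound.

## Multiple imputation (chained equations)

Only categorical covariates carry missing data (the explicit MISSING
level); continuous covariates with holes are rejected. For each of m
streams: initialize every hole with a draw from the variable's observed
marginal, then run a fixed number of sweeps; each sweep refits, for every
incomplete variable in increasing order of missingness, a conditional
model on the currently completed data — all other model covariates plus
the outcome and the exposure as predictors — and redraws that variable's
holes from the fitted predictive distribution. Binary variables use a
logistic conditional, K > 2 categories a multinomial one, both fitted by
Newton's method with a mild ridge (10⁻⁶) so quasi-separation cannot
derail a sweep; aliased predictor columns are dropped with a warning.
Defaults m = 50 and 30 sweeps; the desk-scale profile uses 10 and 10.

Survey weights, strata, and PSUs are deliberately absent from the
conditional models; the design is handled entirely by the analysis
models. Imputation runs separately within each disability subgroup on
exactly the variables entering that subgroup's models, because the
covariate list is subgroup-specific.

Convergence is monitored from per-stream, per-sweep imputed-category
frequencies. A variable is flagged when the between-stream spread grows
over the trailing two-thirds of sweeps (positive OLS slope with t > 3 and
a fitted rise of at least 20% of the window mean) — the signature of
streams drifting apart rather than mixing; stationary sampling noise
stays below this bar by construction of the thresholds.

## Design-weighted logistic regression

Point estimates solve Σᵢ wᵢxᵢ(yᵢ − pᵢ(β)) = 0 by IRLS (tolerance 10⁻¹⁰,
at most 100 iterations; a coefficient magnitude above 30 raises a
separation error naming the term). The covariance is the Taylor
linearization with PSUs treated as sampled with replacement within
strata:

* bread: inverse weighted information (XᵀWX)⁻¹ at the solution;
* meat: Σ_h n_h/(n_h−1) Σ_j (z_hj − z̄_h)(z_hj − z̄_h)ᵀ, where z_hj is the
  PSU total of the score residuals wᵢxᵢ(yᵢ − pᵢ);
* lonely PSUs (strata reduced to a single PSU, as subgroup analyses can
  produce): the singleton's total is centered at the grand mean of all
  PSU totals with factor 1 — a conservative choice that keeps the
  variance defined without discarding the stratum.

Design degrees of freedom are (#PSUs − #strata), floored at 1. These
conventions (with-replacement linearization, t reference on the design
df) follow standard practice for public-use survey files; the estimator
family, CI reference, and lonely-PSU policy are all places where
reasonable analyses differ, so they are isolated in one module and
pinned by oracle tests (exact agreement with independent ML + record-level
sandwich under unit weights and singleton PSUs; 15% agreement with a
brute-force delete-one-PSU jackknife on a clustered fixture — the two
estimators are consistent for the same quantity but not identical).

Collinearity: GVIF(term) = det(R_t)·det(R_o)/det(R) on the weighted
predictor correlation matrix of the fitted model (intercept excluded),
reported as GVIF^(1/(2·df)) and flagged above 1.4.

Weighted prevalences use the ratio estimator with linearized residuals
wᵢ(zᵢ − p̂)/Σw run through the same stratum/PSU machinery; CIs are
±1.96·SE truncated to [0, 1]. Under equal weights and singleton PSUs this
reduces exactly to p̂ ± 1.96·√(p̂(1−p̂)/(n−1)).

## Pooling

Rubin's rules on the log-odds scale (where approximate normality holds),
exponentiated last: q̄, W, B, T = W + (1 + 1/m)B. Degrees of freedom use
the Barnard–Rubin small-sample adjustment with the design df as the
complete-data df; the adjusted df never exceeds it, which matters because
survey design df are modest and the classical (m−1)/λ² formula can
exceed them by orders of magnitude. m = 1 degenerates to the single fit
with a warning. Reported per row: mean analyzed n across imputations
(unrounded), OR, t-based 95% CI, and the pooling internals (W, B, T, df)
for audit.

## Synthetic data generator

The generator emulates what matters downstream of a pooled two-year
public-use telephone-survey file, with every piece of the truth explicit:

* ~15 mostly categorical covariates (the `default_truth` preset; the
  `compact_truth` preset used by the simulation studies has 5) drawn
  independently, with survey-like but deliberately uncalibrated
  marginals;
* one modelled disability from logit P(D=1) = α₀ + αᵀC, the outcome from
  logit P(Y=1) = β₀ + β_D·D + βᵀC, so the true confounders are exactly
  the covariates with nonzero coefficients in both models, and exp(β_D)
  is the estimand;
* the five remaining disability indicators as low-prevalence independent
  Bernoulli draws (prevalences in the neighborhood of published
  young-adult figures), so subgroup construction has realistic structure
  without contaminating the truth;
* a disproportionate stratified design: 8 strata × 6 PSUs, lognormal
  weights (σ = 0.5) around stratum base weights log-spaced over a 4×
  range, two year labels at 50/50 — weights independent of the outcome
  given stratum, so the weighted estimator targets the same conditional
  OR as the unweighted one and recovery tests have a single target;
* missing-at-random holes in covariates only (never the outcome,
  disability answers, or design columns), driven by fully observed
  variables — e.g. employment missing at 12% for males vs 5% otherwise in
  `compact_truth`, matching the order of item nonresponse seen in income-
  and employment-type questions.

What the generator does **not** emulate: covariate dependence beyond the
designed confounding, informative weighting, skip-pattern logic beyond
the gate-question fixture, within-PSU correlation of responses, or any
real codebook's marginals. Passing simulation tests therefore demonstrate
that the chain recovers a known conditional OR under a correctly
specified model with realistic design noise — not that it is robust to
model misspecification in real data.

In `compact_truth`, the demographics influence the outcome only, so the
designed confounder set is exactly {employment}; employment's positive
effects on both endpoints (log-odds 0.8 and 0.7) make the crude and
Model 1 estimates overshoot the truth, giving the crude-versus-adjusted
attenuation pattern the pipeline is supposed to expose. Intercepts target
roughly 10% disability and 5% outcome prevalence, the order of magnitude
in the young-adult never-smoker population this design mirrors.

## Profiles and problem sizes

The `reference` profile carries the full-scale settings: 300 stability
iterations, 100-point penalty grid to 10⁻⁴·λ_max, m = 50 imputations
with 30 sweeps. The `test` profile is the package's own desk-scale
choice used by the simulation studies: 100 iterations, 16-point grid to
2·10⁻³·λ_max, m = 10 with 10 sweeps. With n in the low tens of
thousands and a handful of covariates the selection frequencies and
pooled intervals are insensitive to the finer grid, and the coarse grid
keeps a full 40-replicate operating-characteristics study on one CPU in
the tens of minutes. The simulation studies run at n = 20,000 (end-to-end
coverage and null control) and n = 2,000 (selection recovery), sizes at
which the designed effects are comfortably but not trivially detectable.

## Seeding and determinism

One master seed expands through `numpy.random.SeedSequence` into
per-disability, per-stage, per-iteration streams keyed by *names* (via
CRC32), not positions: removing a disability from a configuration, or
re-ordering them, leaves every other disability's results bit-identical.
Identical configuration and seed reproduce every report file exactly.

## Known limitations

* Stability selection with the CV-minimum penalty is liberal at large n;
  the intersection rule and the >95% threshold temper but do not remove
  this (see the screening note above). No finite-sample error control on
  the selected set is claimed.
* The imputation models are not congenial with the analysis model in the
  strict sense (the conditional of a confounder given D, Y and the rest
  is not exactly logistic under the generative truth); at the missingness
  rates of the presets the induced bias is well inside simulation noise,
  but heavy missingness would need a richer conditional family.
* Replicate-weight (BRR/jackknife-weight) variance estimation, raking,
  multinomial outcomes, and continuous-variable imputation are out of
  scope.
* The real-data path (SAS transport files plus a codebook mapping) is
  limited to CSV + sidecar schema ingestion here; the preprocessing
  semantics (sentinel recoding, gate-question backfill, combined-year
  weighting by 1/#years with year-unique strata) are implemented and
  tested on synthetic fixtures.
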