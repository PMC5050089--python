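# Methods

## Setting

A two-arm randomized trial measures a dietary outcome at follow-up.  Everyone
provides one self-report `Q`; a calibration sub-study of `n_i` of the `N_i`
individuals in arm `i` additionally provides `K = 2` biomarker replicates
`M_1, M_2`.  True intake `T` is latent.  The three working models are linear:
`T = μ_Ti + ε_T`, `Q = α_0i + α_1i T + ε_Q`, `M_k = T + ε_Mk`, with mutually
independent mean-zero errors (normal for the likelihood; the moment estimators
need only the first two moments).  The estimand is `θ = μ_T2 − μ_T1`.  The
biomarker's classical error makes the difference of biomarker means unbiased
for `θ`; the self-report difference is biased unless `α_01 = α_02` and
`α_11 = α_12` (*non-differential* error).  The container admits `K > 2`
replicate columns, but the moment estimators use the first two replicates —
a documented limitation; unbalanced replicate counts are out of scope.

## Method-of-moments estimation

Within the sub-study of arm `i`, with `M̄ = (M_1 + M_2)/2`:

* slope `α̂_1i = cov(Q, M̄) / cov(M_1, M_2)`, intercept
  `α̂_0i = Q̄_is − α̂_1i M̄_i` (sample covariances, n−1 denominator; the
  denominator convention cancels in the slope);
* under non-differential error the covariances pool the two arms' sub-study
  members into one sample — the between-arm spread enters both covariances
  and cancels in the ratio exactly when the calibration line is shared;
* error variances `σ̂²_M = var(M) − cov(M_1, M_2)` (column-averaged sample
  variance, so identical replicates give exactly zero) and
  `σ̂²_Q = var(Q) − α̂²_1 cov(M_1, M_2)`.

The two effect estimators are

```
θ̂_bio = M̄₂ − M̄₁
θ̂_sr  = (Q̄₂ − Q̄₂ₛ)/α̂₁₂ − (Q̄₁ − Q̄₁ₛ)/α̂₁₁ + M̄₂ − M̄₁     (differential)
θ̂_sr  = (Q̄₂ − Q̄₁)/α̂₁                                     (non-differential)
```

where `Q̄_i` averages over the whole arm and `Q̄_is` over its sub-study.  The
differential form corrects the sub-study biomarker contrast for the chance
difference between the sub-study and the full arm, using the self-report as
an auxiliary variable; at 100% calibration it collapses to `θ̂_bio`
identically, and the combination below returns the biomarker estimator with
weight one in that degenerate case.

**Variance machinery.**  The 2×2 variance matrix of `(θ̂_bio, θ̂_sr)` comes
from stacked estimating equations: one equation per first or second moment
entering the estimators (per-arm means of `Q` in and out of the sub-study,
sub-study means of `M_1`, `M_2`, and the two covariances, per arm or pooled as
the structure dictates), solved exactly by the sample moments with
n-denominator covariances.  At the solution the averaged Jacobian (bread) is
exactly diagonal — every off-diagonal term is a centered sample mean — a fact
the test-suite verifies against a numerical Jacobian; the meat is the
empirical outer product of the per-individual estimating functions, so the
resulting matrix is positive semi-definite by construction.  A delta-method
gradient (central differences on the smooth map from moments to the two
estimators) completes the sandwich.  The matrix is validated against a
stratified bootstrap (resampling within arm × sub-study strata, which keeps
the design sizes fixed): on a trial large enough for the linearization to be
in its regime (2000 per arm, 50% calibration) the variances agree within 10%.
The linearization is a large-`n_i` approximation: with very small sub-studies
the slope `α̂_1` is poorly resolved and `θ̂_sr` is heavy-tailed, which the
per-replicate variance estimate tracks only approximately.

**Combination.**  `θ̂ = w θ̂_bio + (1−w) θ̂_sr` with the minimum-variance
weight `w = (v_sr − c)/(v_bio + v_sr − 2c)`; combined variance
`(v_bio v_sr − c²)/(v_bio + v_sr − 2c)`.  Weights are not clipped to [0, 1].
A fit is flagged invalid — never truncated — when `cov(M_1, M_2) ≤ 0` in any
arm used (slope denominator), when an error-variance estimate is
non-positive, or when the combination matrix is not positive definite.  The
scenario runner drops invalid replicates per method and reports the retained
count.  Because the exclusion rule covers every non-positive variance
estimate, small-calibration cells retain somewhat fewer replicates (~92-96%
at 10% calibration) than rules that only guard the variance formulas.

## Maximum likelihood

The likelihood is the product of trivariate-normal densities for sub-study
triples `(M_1, M_2, Q)` — mean `(μ_Ti, μ_Ti, α_0i + α_1i μ_Ti)`, covariance
with compound-symmetric biomarker block `σ²_Ti + σ²_Mi` / `σ²_Ti` and cross
terms `α_1i σ²_Ti` — and univariate densities `N(α_0i + α_1i μ_Ti,
α²_1i σ²_Ti + σ²_Qi)` for everyone else.  Arms are independent, so the fit
works from per-arm sufficient statistics (mean vector, scatter matrix,
out-of-sub-study mean and sum of squares) and its cost is independent of the
sample size.  Unconstrained the differential model has 12 parameters and the
non-differential 10; equality constraints on `σ²_T`, `σ²_M`, `σ²_Q` across
arms are available (tying the two error variances gives the 10- and
8-parameter fits exposed by the CLI's `--equal-variances`).

Numerical choices: variances are optimized on the log scale (positivity
without constraints); starting values are the moment estimates where valid,
else naive moments; BFGS with a Nelder-Mead polish on stall; relative
convergence to ~1e-8 with failures and near-boundary variances flagged, never
silently accepted.  The reported variance matrix is the inverse observed
information on the natural scale (central-difference Hessian via
statsmodels' numerical differentiation).  The sandwich variance
`A⁻¹ B A⁻ᵀ` uses the total negative Hessian and the empirical outer product
of per-individual scores; because the MLEs here are moment estimators, the
point estimates remain consistent under non-normal intake while the
model-based variance does not — the sandwich is the variance to report in
that case.  Exactly noise-free data (a singular likelihood along the variance
boundary) are detected and the analytic limit — group means and the exact
regression line — is returned with an explanatory flag.  Nested models are
compared with `2Δloglik` against chi-square; a Wald version of the joint
2-df test of non-differential error is also exposed, and neither is labelled
canonical.

## Synthetic-data generator

`ScenarioConfig` defaults encode the reference emulation of a sodium-reduction
trial: 500 per arm, `μ_T = (4.6, 4.1)` (effect −0.5 on the transformed scale),
`σ²_T = 0.1`, `σ²_M = 0.2`, differential `α = (0.3, 0.8)` / `(1.5, 0.5)` or
non-differential `α = (0.9, 0.65)`, `σ²_Q ∈ {0.09, 0.3, 0.5, 0.7}`, and
calibration fractions 10/25/50/100% masked by simple random sampling
stratified by arm (stratification keeps the sub-study sizes non-random, as in
the reported designs).  Masking happens after generation, so the unmasked
dataset serves as the gold standard within the same replicate; the scenario
runner reuses one base dataset per replicate across calibration fractions
(common random numbers).  Seeding uses one master seed with deterministic
per-replicate substreams, so any single replicate is individually
reproducible.

A skewed-truth option draws `T` from a gamma distribution shifted and scaled
to the target mean and variance, with skewness as the free shape control
(`skew = 2/√shape`); zero skewness falls back to the normal draw.  The family
is a configurable stand-in for "some right-skewed intake distribution" rather
than a canonical choice.  The generator emulates a single post-intervention
measurement occasion with a randomly sampled calibration sub-study; it does
not emulate longitudinal visits, dropout, item non-response, correlated
self-report/biomarker errors, or seasonal effects — so passing tests speak to
the estimators' behaviour under the stated error models, not to the full
messiness of field data.

Preprocessing mirrors the standard workflow for real data: biomarkers are
first divided by a known urinary excretion fraction (0.86 for sodium), then
all measurements are power-transformed (exponent supplied by the user, 0.3
being typical from a Box-Cox analysis; selection is deliberately not
automated).  Whether rescaling precedes the transform is a convention; this
order is the package default and both knobs are configurable.

## Operating characteristics

Per scenario cell and method, over the valid replicates: bias, MSE, empirical
SD (n−1), model SE (root mean model-based variance), 95% normal-quantile CI
coverage (the CI construction is a convention; ±1.96·SE), and efficiency
`100 × var(gold) / var(method)` with the gold-standard variance computed over
the same replicate subset.  MSE equals `bias² + emp_sd²·(n−1)/n` exactly.

## Known limitations and a reproducibility note

* The biomarkers-only efficiency at calibration fraction `f` is analytically
  `100·f` here (estimator variances `2(σ²_T + σ²_M/2)/(f·500)` versus the
  gold standard's `2(σ²_T + σ²_M/2)/500`), and the simulated values land
  there within Monte-Carlo noise.
* Under these generator settings the attainable efficiency of *any* (fixed- or
  adaptively-weighted) combination of the two component estimators is capped
  by the Fisher information of the model.  At `σ²_Q = 0.09` the bound is
  ≈11.6% / 28.4% / 54.3% at 10/25/50% calibration for the differential
  structure, and the oracle fixed-weight frontier of the pair is ≈15% for the
  non-differential structure at 10%.  The package's combined estimators reach
  these frontiers to within weight-estimation noise (≈10.2 / 28.6 / 52.3 and
  ≈15.1 in 1000-replicate runs).  Some previously published
  operating-characteristics tables for this design report combined-estimator
  efficiencies above these information bounds (e.g. 15.7 / 37.2 / 62.3);
  those values are consistent with a generator whose self-report error
  variance is the *square* of the stated value (0.09² ≈ 0.008) — under which
  this package reproduces them closely — but they are not attainable under
  the stated `σ²_Q = 0.09`.  The simulation defaults here follow the stated
  parameter values, and the discrepancy is surfaced rather than calibrated
  away.
* The delta-method variance of the differential self-report estimator is
  unstable when `cov(M_1, M_2)` is small relative to its sampling noise
  (sub-studies of a few dozen); such replicates are flagged rather than
  repaired.
* Cost/sample-size planning and designs with more than two arms or
  longitudinal outcomes are out of scope.
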