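# Methods

## Model

For subject *i* = 1..N observed at visits *j* = 1..n_i:

    y_ij = β0 + ν_i + x'_ij β' + ε_ij,
    ε_ij ~ N(0, σ²_ij),      σ²_ij = exp(τ0 + ω_i + w'_ij τ'),
    (ν_i, ω_i) ~ N2(0, Σ),   Σ = [[σ²_ν, σ_νω], [σ_νω, σ²_ω]].

The location sub-model carries a random subject intercept ν_i; the
log-linear scale sub-model lets the level-1 (within-subject, "WS")
variance differ across subjects (random scale intercept ω_i) and
visits (covariates w_ij).  Only random intercepts are supported; random
slopes and covariates on the random-effect variances are out of scope.
With `scale_model=False` the scale sub-model is dropped and the model
reduces to a standard mixed-effects regression (MRM) with homoskedastic
level-1 variance exp(τ0).

## Estimation

The marginal likelihood integrates each subject's bivariate random
effect.  For fixed (β, τ) the subject's integrand depends on (ν, ω)
only through three sufficient statistics (weighted residual sums), so
one likelihood evaluation costs O(total observations) plus
O(N × quadrature nodes) regardless of cluster size.  The double
integral uses adaptive Gauss–Hermite quadrature: a damped Newton
iteration locates each subject's integrand mode and curvature
(initialized at the subject's own no-prior mode — weighted residual
mean and matching log WS variance — so the Newton steps mostly apply
prior shrinkage), and a product Hermite grid (default 7 points per
dimension, 49 nodes; configurable, odd) is centred and scaled there.
The MRM marginal likelihood is evaluated in closed form via the
Woodbury identity instead.

The optimizer works on an unconstrained internal scale: the Cholesky
factor of Σ with logged diagonal, which guarantees a positive
semi-definite reported Σ̂.  L-BFGS-B is followed by Newton polishing
steps using a central-difference Hessian; a fit is declared converged
when the relative log-likelihood change criterion is met and the
gradient infinity norm on the internal scale is ≤ 1e-3.  Failures never
raise — results carry an honest `converged=False` so replication
drivers can apply exclusion rules.  Standard errors come from the
observed information of the quadrature-approximated likelihood
(central differences, relative step 1e-5), mapped to the natural scale
(β, τ, σ²_ν, σ²_ω, σ_νω) by the delta method.

Starting values: β from pooled OLS; σ²_ν from the between-subject
variance of mean residuals; τ0 and σ²_ω from the mean and variance of
the per-subject log residual variances; τ' = 0, σ_νω = 0.  Centring the
scale side on per-subject log variances matters: a token σ²_ω start
pushes a scale-outlying subject's misfit onto the location effects.

### A real degeneracy, and the guard against it

If one subject's responses are an exact affine function of its
covariates (conceivable with two-valued careless answers), the MELS
likelihood is unbounded: the global β can interpolate that subject,
its conditional residual variance reaches zero, and the marginal
contribution grows like exp(n²σ²_ω/8).  This is intrinsic to
location-scale likelihoods (the Gaussian-mixture variance degeneracy in
different clothes), not an implementation artifact.  Two safeguards
keep estimation on the scientifically meaningful optimum: the
per-subject mode search and the quadrature nodes are confined to ±8
prior SDs with an absolute ceiling of 12 on |ω| (a WS variance ratio of
e^12 ≈ 1.6·10⁵ against the structural model), i.e. the integral is
taken over a truncated random-effect support; and the bundled careless
pattern generator emits a balanced two-by-two pattern (each response
value at both covariate values) rather than an exactly collinear one.
For any data whose subjects are not exactly interpolable these guards
are numerically invisible (the truncated prior mass at 8 SDs is
~6·10⁻¹⁶).

## Leave-one-out models and influence measures

To assess subject i\*, the intercept and random-intercept loading are
multiplied by 1(i ≠ i\*) in both sub-models and a new indicator column
1(i = i\*) enters each, with coefficients c_i\* (location) and d_i\*
(scale).  The target subject thus contributes no random-effect mass but
stays in the data, and the baseline model is nested in the augmented
one (2 extra parameters; 1 in MRM mode, which has no scale effect).
Leave-one-out fits are warm-started from the baseline estimates with
c_i\* at the subject's mean location residual and d_i\* at the log
variance of those residuals; if a warm-started fit undercuts the
baseline log-likelihood (nesting violation), it is retried from the
default starts.  LR = 2(ℓ_loo − ℓ) is clamped at zero with a warning
when numerical noise makes it slightly negative, tested against χ² with
df = number of added parameters, and Benjamini–Hochberg corrected
across the N subjects (default q = 0.05).

A calibration caveat: the baseline treats the target subject as a
random draw (its likelihood contribution is integrated over the
prior), while the leave-one-out model profiles over the subject's own
fixed effects.  Under the null the resulting deviance gap is
stochastically larger than χ²_df — it carries an offset of roughly
z²_prior plus log(prior SD / posterior SD) per random-effect
dimension, which grows with cluster size.  On null simulations at 40
observations per subject the LR median is ≈ 5.5 against the χ²₂ median
of 1.39, and χ²-based FDR rejects well above the nominal rate.  The
LR column is therefore best read as a descriptive measure of fit
change; the rank-based measures below are the calibrated detectors.

Per parameter group γ ∈ {β, τ, η} (η = (σ²_ν, σ²_ω, σ_νω)):

* Cook's distance  C = (γ̂ − γ̂₋)' Σ̂₋⁻¹ (γ̂ − γ̂₋) / r_γ,
* DFBETAS          (θ̂ − θ̂₋) / SE(θ̂₋)  per single parameter,
* COVTRACE         |Tr(Σ̂⁻¹ Σ̂₋) − r_γ|,
* COVRATIO         det(Σ̂₋) / det(Σ̂),

where the subscript "₋" is the leave-one-out quantity — the formulas
use the leave-one-out covariance exactly where defined, with no
symmetrization.  Singular covariance blocks fall back to the
Moore–Penrose pseudo-inverse and flag the row as ill-conditioned.
Cutoff flags: C > 4/N, |DFBETAS| > 2/√N, COVRATIO outside 1 ± 3 r_γ/N,
LR flagged when its q-value ≤ q.  In MRM mode only the β group and
σ²_ν measures exist; scale-side columns are absent rather than zero.

## Synthetic scenarios

Both generators emulate daily physical-activity minutes; negative
draws are removed (configurable), generators are seed-deterministic
and return ground-truth labels.

* **Scenario 1** — x ~ |N(3, 1)| per visit; y = 100 + ν + 10x + ε with
  WS variance exp(7 + ω + 0.5x), Σ = [[20.09, 0.45], [0.45, 1]];
  default 50 subjects × 500 visits.  Careless responders replace all
  their rows with responses cycling 150/155 against covariates cycling
  3/4 in a balanced two-by-two pattern (see the degeneracy note); the
  covariate is then standardized pooled over all retained rows.
* **Scenario 2** — x = time period 0..7, a fixed count of visits per
  period (default 25); y = 100 + ν + 15x + ε with WS variance
  exp(3 + ω + 0.6x), Σ = [[20.09, 0.22], [0.22, 0.25]].  Consistent
  subjects are generated with a zero scale intercept (τ0 → 0 and
  ω = 0); the covariate is not standardized.

What these generators do *not* emulate: missingness, autocorrelated
within-subject errors, floor/ceiling effects of rating scales, or
time-invariant covariates.  Passing detection studies therefore shows
the measures separate gross scale outliers under the stated model, not
robustness to those real-data features.

The detection study fits the baseline and all N leave-one-out models
per replicate, excludes any replicate with a non-converged fit, and
counts a detection when the designated subject attains the extreme rank
(all k designated subjects within the top/bottom k, for k injected
subjects).  Replicate r uses seed base+r for exact re-runs.  Desk-scale
defaults used by the test suite and the acceptance script are 20
subjects with 100 visits (scenario 1) or 8 × 13 visits (scenario 2) and
20 replicates (10 for the three-subject variants); the full-scale
dimensions remain available through `ScenarioConfig`.

## Direction of the τ0 effect under ML

Separating a subject with abnormally *low* WS variance raises the
leave-one-out scale intercept τ̂0 (the subject no longer drags the
average log WS variance down), so under maximum likelihood its
DFBETAS for τ0 is the most *negative* value in the sample — it is
detected as the extreme, but on the small side.  Regression-based
two-stage estimators can place the same subject on the positive side.
The package reports the signed value per the definition above; rank
summaries report largest and smallest sides separately.

## Known limitations

* Two-level models, Gaussian responses, random intercepts only.
* Observation-level influence is not computed.
* The truncated-support quadrature slightly biases the likelihood for
  subjects genuinely beyond 8 prior SDs; such subjects are exactly the
  ones the influence analysis is meant to flag, and the ranks are
  unaffected in practice.
* With small N (≲ 10) the LR null distribution is only approximately
  χ², and leave-one-out fits may sit near the PSD boundary of Σ̂.
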