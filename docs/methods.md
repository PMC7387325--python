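# Methods

## Data model

Cohorts are long-format counting-process tables: one row per
subject-interval `(start, stop]` with an event indicator, the
time-dependent treatment status `A(t)`, and covariate values.
Conventions, chosen once and used everywhere:

* Intervals are half-open `(start, stop]`; events and treatment
  switches attach to `stop`.  This is the standard counting-process
  convention and makes risk-set membership (`start < t ≤ stop`)
  unambiguous.
* Covariate values on a row are the values known at `start`
  (left-continuous, last observation carried forward), so covariates
  are predictable with respect to the hazard filtration.
* A tie between a recorded event and a recorded treatment start at the
  same time is resolved as event-first (`T < V`) by default; the
  `event_precedence` flag flips this.  In continuous time the tie has
  probability zero, but recorded data are discrete.
* Missing time-updated covariates are filled by LOCF within subject and
  then by the cohort median.  This is deliberately simple plumbing;
  model-based single imputation is out of scope.
* Two study designs are represented.  When follow-up continues after
  treatment initiation, `V` is carried by the `treated` column
  switching 0 → 1.  When follow-up stops at treatment, no treated
  person-time exists, so `V` is carried by a cause indicator column
  `tx` on the final interval (exactly as a competing-risks cause code);
  `tx` is derived automatically in the first design.

Episode splitting (`episode_split`) cuts intervals at arbitrary times
while copying covariates and weights and moving indicator columns to
the terminal piece.  The counting-process partial likelihood is
invariant under splitting; the suite checks log-likelihood equality to
1e-10.  Splitting is what attaches time-varying coefficients and
time-resolved weights to the data.

## Proportional-hazards engine

The Cox engine maximises the weighted partial likelihood on start–stop
data with either the Efron (default, used throughout the estimators) or
Breslow tie correction; the weighted Efron form follows the convention
of weighting the within-tie averages by the tied subjects' total case
weight.  Numerical choices:

* Newton–Raphson with step-halving; convergence when the score
  sup-norm falls below 1e-9 or the Newton increment falls below 1e-11
  (the latter matters on large cohorts, where accumulated floating
  error puts a floor under attainable score norms); at most 50
  iterations.
* Covariates are centred at their weighted means during optimisation to
  avoid overflow with age-scale covariates; the baseline hazard is
  un-centred afterwards, so `baseline_hazard` is referenced at
  covariates = 0 and predictions for an explicit profile are unaffected
  by centring.
* Monotone likelihood (perfect separation) is reported as a
  `ConvergenceError` when a coefficient drifts beyond ±20, or when
  likelihood improvements vanish while a coefficient exceeds ±10.
* The baseline cumulative hazard uses the tie-matched estimator
  (Efron or Breslow form) as increments at the distinct event times.

Risk prediction evaluates
`1 − exp(−Σ_{t_j ≤ t} exp(x(t_j)ᵀβ(t_j)) dΛ0(t_j))` over the
baseline-hazard steps, where `x(t)` may follow a piecewise-constant
path (e.g. the treatment indicator held at 0) and `β(t)` may be a step
function.  Grids beyond the last event time are returned flat with an
`extrapolated` flag.

Step (time-varying) coefficients are specified by user-chosen cutpoints
on study time; there is no automatic changepoint search.  Whether such
cutpoints should sit on time-since-baseline or time-since-treatment is
a modelling decision; this implementation uses study time, which also
keeps the piecewise likelihood exact after episode splitting.

Nonparametric estimators (product-limit Kaplan–Meier, Aalen–Johansen
cumulative incidence) share the same risk-set accumulator and accept
per-interval weights and delayed entry.  The semiparametric cumulative
incidence from two cause-specific fits uses discrete product
integration, `S(t) = Π (1 − dΛ_event − dΛ_treat)`, which reproduces the
nonparametric Aalen–Johansen exactly for null-covariate Breslow fits;
an `exp` form is available when hazard jumps are large.

## Strategy estimators

With an empty covariate list each estimator switches to the matching
nonparametric route (KM for ignore/composite/censored-hypothetical,
Aalen–Johansen for while-untreated); with covariates it uses Cox–Efron
fits.  The ignore strategy refuses cohorts whose follow-up stops at
treatment (the estimand is not identified there), as do the
treatment-modelling hypothetical methods.

For the hypothetical strategy:

* `censor` censors follow-up at `V`; valid when treatment decisions
  depend only on the baseline covariates in the model.
* `model_treatment` keeps post-treatment follow-up, adds a
  time-dependent treatment term (optionally a step coefficient and
  treatment × baseline interactions) and predicts with `A(t) = 0`.
* `censor_ipcw` / `model_iptw` additionally weight by stabilized
  inverse probabilities of remaining untreated.  The weight at time `t`
  is `S_num(t | numerator covariates) / S_den(t | history)`, both from
  cause-specific Cox models for treatment initiation fitted on
  untreated person-time.  The numerator defaults to intercept-only (the
  marginal probability, as is common when the outcome model conditions
  on little); numerator covariates can be supplied, in which case
  predictions should condition on the same covariates.  Survivor
  ratios are evaluated at interval stops using interval-start covariate
  values, keeping weights predictable.  Before weighting, the cohort is
  episode-split on a regular grid (`weight_update_interval`, default
  0.25 time units) so each subject's weight is refreshed over follow-up
  rather than frozen over long intervals; estimates are otherwise
  invariant to this split.  Under IPTW, a treated subject's weight is
  frozen at its value at `V` for all post-treatment intervals — once
  treated, always treated, so no further initiation-model contributions
  accrue.  Weight truncation at percentiles is available but off by
  default: truncation trades bias for variance and should be an
  explicit choice.
* Before weighted estimation a positivity report lists deciles of each
  weight covariate containing zero treated or zero untreated
  person-time; this warns (suggesting a shorter horizon) but does not
  abort.

When no subject initiates treatment all four hypothetical methods, and
indeed all four strategies, coincide by construction; the estimators
short-circuit to the ignore-treatment estimate in that case.

## Simulator and oracles

The generator is a three-state illness-death model (untreated →
treated → dead) with exact competing-clock sampling: all hazards are
piecewise constant, so transition times are drawn by inverse-CDF
sampling between rate-change boundaries, with the exponential clock
redrawn at each boundary (memorylessness makes this exact; no
thinning).  Per subject:

* baseline covariates: an age-like normal covariate (mean 60, sd 15,
  centred in all hazards) and a binary modality-like covariate;
* untreated death hazard `λ = λ0 · exp(effects + γ Z(t))`, treated
  death hazard the same with `μ0` in place of `λ0`, treatment
  initiation intensity `α = α0 · exp(effects + δ Z_obs(t))`;
* a latent binary marker `Z` jumping 0 → 1 at rate `κ`, observed only
  at visits every Δ = 0.5 time units (LOCF).  The *death* hazard
  follows the latent marker (biology), while the *treatment* intensity
  follows the marker as observed at visits (decisions are made on
  measured values).  This split is what makes the recorded covariate
  history sufficient for the treatment decisions — the exchangeability
  assumption of the weighted estimators holds with respect to data the
  analyst can actually see, while censoring at treatment remains
  informative because the latent marker keeps driving death;
* administrative censoring at τ = 10 plus optional independent
  exponential censoring.

One root seed spawns a deterministic substream per subject, so
enlarging `n` never perturbs earlier subjects and the counterfactual
no-treatment arm (`simulate_counterfactual_untreated`) can re-run the
same subjects with the treatment clock disabled — the draw sequence is
arranged so that a disabled clock consumes the same draws, making the
two arms subject-wise identical when `α = 0`.

True estimands: for constant-hazard configurations without an active
confounder the four risks have closed forms —
`F_hyp = 1 − e^{−λt}`, `F_comp = 1 − e^{−(λ+α)t}`,
`F_wu = λ/(λ+α) · F_comp`, and
`F_ign = F_wu + ∫_0^t α e^{−(λ+α)s}(1 − e^{−μ(t−s)}) ds`
(adaptive quadrature for the integral).  Any other configuration falls
back to two uncensored Monte-Carlo arms (factual and counterfactual,
drawn from seeds derived to be independent of any estimation cohort)
with binomial standard errors recorded.  The probability inequalities
`F_wu ≤ F_ign ≤ F_comp` hold for the true estimands in every
configuration and are asserted as invariants; model-based *estimates*
may violate the ordering because the proportionality assumptions act on
different scales, so the estimate-level ordering is only checked
nonparametrically and without censoring before the horizon.

Shipped scenarios: `default_scenario` (dialysis-like: age log-HR 0.04
per year on death, −0.03 on treatment, protective treatment
μ0 = 0.04 < λ0 = 0.10, moderate confounding, 2% independent
censoring) and `confounded_scenario` (covariate-free: λ0 = 0.06,
α0 = 0.15, μ0 = 0.03, κ = 0.3, γ = ln 2, δ = ln 3).  The latter's rates
were fixed so that the systematic bias of naive censoring at treatment
(about −0.03 at t = 10) is an order of magnitude above the Monte-Carlo
resolution of the evaluation sample sizes, and its true hypothetical
10-year risk (≈ 0.63) is of the magnitude seen in dialysis cohorts.

## What the simulations do and do not show

The generator produces exactly the structure the estimators assume:
proportional hazards given the (latent) state, a single absorbing
treatment episode, one binary confounder with one jump, and visit-grid
observation.  Passing tests therefore demonstrate correctness of the
estimators under their stated assumptions — they do not demonstrate
robustness to misspecified hazards, multiple or continuous confounders,
measurement error beyond observation delay, recurrent treatment
episodes, or informative loss to follow-up.  Estimator variance at the
end of the horizon grows as the untreated risk set thins; evaluation
against oracles therefore averages replicate cohorts when measuring
bias.

## Evaluation sizes

The test suite and the acceptance script use: n = 20,000 for the
closed-form agreement checks (±0.015 tolerance at t ∈ {1, 2, 5, 10});
10 replicate cohorts of n = 10,000 against a 200,000-subject
counterfactual arm for the confounding-repair comparison; and 40
replicates of n = 5,000 for 3-SE coverage of parameter recovery.
These sizes keep each oracle's Monte-Carlo error several times smaller
than the effect being measured.

## Known limitations

* No uncertainty intervals for the risk curves (model-based covariance
  is available for coefficients; resampling the whole pipeline is the
  user's responsibility).
* No g-formula, copula or multiple-imputation estimators of the
  hypothetical risk; no principal-stratum analogue; no validation /
  performance assessment of the predictions.
* Weight models are Cox models on untreated person-time; pooled
  discrete-time logistic weight models are not provided.
* Single treatment episode only; no recovery or cessation states; no
  calendar-time effects.
* Hypothetical scenarios other than complete elimination of treatment
  (e.g. "start treatment after one year") are not implemented.
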