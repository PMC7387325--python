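# predictimand

Risk-prediction estimands ("predictimands") for time-to-event cohorts in
which a treatment may be initiated *after* baseline.

When a prediction model is developed on such a cohort — think patients
starting dialysis, some of whom later receive a kidney transplant — the
question "what is this patient's 10-year mortality risk?" is ambiguous.
With `T` the time to the event of interest, `V` the time to treatment
start and `X(0)` the baseline covariates, four distinct targets can be
meant:

| strategy          | estimand                                  | reading |
|-------------------|-------------------------------------------|---------|
| ignore treatment  | `P(T ≤ t_hor | X(0))`                     | risk under the development cohort's treatment policy |
| composite         | `P(min(T, V) ≤ t_hor | X(0))`             | event *or* treatment, whichever comes first |
| while untreated   | `P(T ≤ t_hor, T < V | X(0))`              | cumulative incidence with treatment as competing event |
| hypothetical      | `P(T^{v=∞} ≤ t_hor | X(0))`               | counterfactual risk were treatment eliminated |

The package implements an estimator for each strategy on long-format
counting-process data (one row per subject-interval `(start, stop]`),
plus the machinery they need:

* a self-contained weighted Cox engine for start–stop data (Efron or
  Breslow ties, step/time-varying coefficients, treatment × covariate
  interactions, baseline cumulative hazard, Schoenfeld residuals), with
  weighted Kaplan–Meier and Aalen–Johansen estimators for the
  covariate-free case;
* four estimation routes for the hypothetical risk: censor at `V`;
  model the time-dependent treatment term and predict with `A(t) = 0`;
  and both again with stabilized inverse-probability-of-treatment
  weights (IPCW on the censored view, IPTW in a marginal structural
  model) to correct for time-updated confounders of treatment
  initiation;
* an illness-death simulator (untreated → treated → dead) with a
  latent binary marker that raises both the death hazard and the
  treatment intensity, visit-based (LOCF) marker observation, and a
  counterfactual no-treatment arm plus closed-form oracles, so every
  estimator can be checked against ground truth.

Estimators follow the scikit-learn protocol: construct with
parameters, `fit(cohort)`, then `predict_risk(profile, times)`.

## Worked example

Simulate a dialysis-like cohort (age and modality affect death, younger
patients are treated sooner, treatment is protective, a binary marker
confounds treatment and death) and compare all four 10-year risks for
two baseline profiles:

```python
import predictimand as pm
from predictimand.estimators import PredictimandSpec, compare_predictimands

data = pm.simulate_cohort(pm.default_scenario(n=5000, seed=1))
specs = [PredictimandSpec(strategy=s, horizon=10.0)
         for s in ("ignore", "composite", "while_untreated")]
specs.append(PredictimandSpec(strategy="hypothetical", horizon=10.0,
                              hypothetical_method="censor_ipcw"))
table = compare_predictimands(
    data, ["age", "modality"], specs,
    profiles=[{"age": 50.0, "modality": 1.0}, {"age": 70.0, "modality": 1.0}],
    weight_config={"denominator": ["z"]},
)
print(table.to_string(index=False))
```

```
          profile            strategy      method  horizon     risk
age=50,modality=1              ignore                 10.0 0.542932
age=50,modality=1           composite                 10.0 0.988565
age=50,modality=1 one_minus_composite                 10.0 0.011435
age=50,modality=1     while_untreated                 10.0 0.285020
age=50,modality=1        hypothetical censor_ipcw     10.0 0.699094
age=70,modality=1              ignore                 10.0 0.838346
age=70,modality=1           composite                 10.0 0.990043
age=70,modality=1 one_minus_composite                 10.0 0.009957
age=70,modality=1     while_untreated                 10.0 0.600610
age=70,modality=1        hypothetical censor_ipcw     10.0 0.924663
```

Each row answers a different question for the same patient.  At age 50:
a 54% chance of dying within 10 years under the current treatment
policy (*ignore*); a 29% chance of dying before being treated (*while
untreated*); a 1% chance of being alive and still untreated at 10 years
(*one minus composite*); and a 70% chance of dying were treatment never
available (*hypothetical*) — higher than the ignore-treatment risk
because treatment is protective.  The composite curves for ages 50 and
70 are nearly equal: younger patients die less but are treated more.

The same analyses run from the shell:

```bash
predictimand simulate --config scenario.yaml --out cohort.csv
predictimand estimate --data cohort.csv --strategy hypothetical \
    --method censor_ipcw --weight-covars z --horizon 10 --out risk.csv
predictimand compare --data cohort.csv --covars age,modality \
    --profile age=50,modality=1 --horizon 10 --out table.csv
predictimand truth --config scenario.yaml --grid 1,5,10 --out truth.csv
```

## Layout

```
src/predictimand/
  cohort.py      counting-process data model, views, episode splitting
  survival.py    Cox engine, KM/Aalen-Johansen, CIF, Schoenfeld residuals
  weights.py     stabilized inverse-probability weights
  estimators.py  the four strategy estimators + comparison table
  simulate.py    illness-death simulator and true-estimand oracles
  cli.py         command-line interface
docs/methods.md  model, assumptions, numerical choices, limitations
```
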