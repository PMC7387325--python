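import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import predictimand as pm

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_df(rows, **covs):
    """Build a counting-process frame from (id, start, stop, event, treated) tuples."""
    df = pd.DataFrame(rows, columns=["id", "start", "stop", "event", "treated"])
    for name, vals in covs.items():
        df[name] = vals
    return df


def make_cohort(rows, roles=None, followup_mode="continues_after_treatment", **covs):
    return pm.CohortDataset(
        make_df(rows, **covs), covariate_roles=roles or {}, followup_mode=followup_mode
    )


def exponential_cohort(n, seed, rate0=0.1, log_hr=np.log(2.0), censor_time=8.0):
    """Simple single-interval exponential data with one binary covariate."""
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n)
    t = rng.exponential(1.0 / (rate0 * np.exp(log_hr * x)))
    stop = np.minimum(t, censor_time)
    event = (t <= censor_time).astype(int)
    df = pd.DataFrame(
        dict(id=np.arange(n), start=0.0, stop=stop, event=event, treated=0, group=x)
    )
    return pm.CohortDataset(df, covariate_roles={"group": "baseline"})


@pytest.fixture(scope="session")
def small_sim():
    """A 20-subject simulated cohort with treatment and a confounder."""
    cfg = pm.SimulationConfig(
        n=20, seed=42, death_rate=0.15, treat_rate=0.2, post_treat_death_rate=0.05,
        confounder_rate=0.3, confounder_death_log_hr=np.log(2),
        confounder_treat_log_hr=np.log(3), censor_rate=0.05,
    )
    return pm.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def confounded_cohort():
    """Mid-size confounded cohort shared across weight/estimator tests."""
    return pm.simulate_cohort(pm.confounded_scenario(n=4000, seed=7))
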