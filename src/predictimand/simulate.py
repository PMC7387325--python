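"""Illness-death cohort simulator with a time-updated confounder.

States: untreated (initial) -> treated (intermediate) -> dead (terminal).
Subjects carry an age-like continuous baseline covariate, a binary
modality-like baseline covariate, and a binary time-updated marker Z(t)
that jumps 0 -> 1 at rate kappa and raises both the death hazard (by
e^gamma) and the treatment-initiation intensity (by e^delta) -- the
confounding mechanism that makes censoring at treatment informative.

All transition hazards are piecewise constant given the current state, so
event times are drawn exactly by competing-clock inverse-CDF sampling
(no thinning).  The marker is *observed* only at scheduled visits (LOCF),
emulating covariates measured at fixed intervals; the latent jump still
drives the hazards.

A root seed spawns one substream per subject, so growing ``n`` never
perturbs earlier subjects, and the counterfactual no-treatment arm can
re-run the same subjects with the treatment clock disabled.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import integrate

from .cohort import BASELINE, TIME_UPDATED, CONTINUES_AFTER_TREATMENT, CohortDataset


@dataclasses.dataclass
class SimulationConfig:
    """Transition intensities, confounder dynamics, censoring and seed.

    Rates are per unit study time; covariate effects are log hazard
    ratios.  The continuous covariate enters all hazards centered at
    ``age_mean`` so baseline rates are rates for an average subject.
    """

    n: int = 1000
    seed: int = 0
    # baseline covariates
    age_mean: float = 60.0
    age_sd: float = 15.0
    modality_prevalence: float = 0.65
    # untreated death hazard lambda(t) = death_rate * exp(effects + gamma Z)
    death_rate: float = 0.1
    death_log_hr_age: float = 0.0
    death_log_hr_modality: float = 0.0
    # treatment initiation intensity alpha(t, H_t)
    treat_rate: float = 0.2
    treat_log_hr_age: float = 0.0
    treat_log_hr_modality: float = 0.0
    # post-treatment death hazard mu(t) = post_treat_death_rate * exp(same effects)
    post_treat_death_rate: float = 0.05
    # binary confounder Z(t): one 0 -> 1 jump
    confounder_rate: float = 0.0          # kappa
    confounder_death_log_hr: float = 0.0  # gamma
    confounder_treat_log_hr: float = 0.0  # delta
    # observation and censoring
    visit_interval: float = 0.5           # Delta between marker measurements
    admin_censor_time: float = 10.0       # tau
    censor_rate: float = 0.0              # independent exponential censoring

    def __post_init__(self) -> None:
        for f in ("death_rate", "treat_rate", "post_treat_death_rate",
                  "confounder_rate", "censor_rate"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.visit_interval <= 0 or self.admin_censor_time <= 0:
            raise ValueError("visit_interval and admin_censor_time must be > 0")

    @property
    def has_confounder(self) -> bool:
        return self.confounder_rate > 0 and (
            self.confounder_death_log_hr != 0 or self.confounder_treat_log_hr != 0
        )

    @property
    def is_analytic(self) -> bool:
        """True when the four estimands have closed forms given X(0)."""
        return not (self.confounder_rate > 0 and (
            self.confounder_death_log_hr != 0 or self.confounder_treat_log_hr != 0
        ))

    def hazards_for(self, age: float, modality: float):
        """(lambda, alpha, mu) for a subject with Z = 0."""
        a = age - self.age_mean
        lam = self.death_rate * math.exp(
            self.death_log_hr_age * a + self.death_log_hr_modality * modality
        )
        alp = self.treat_rate * math.exp(
            self.treat_log_hr_age * a + self.treat_log_hr_modality * modality
        )
        mu = self.post_treat_death_rate * math.exp(
            self.death_log_hr_age * a + self.death_log_hr_modality * modality
        )
        return lam, alp, mu

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def default_scenario(n: int = 2000, seed: int = 0) -> SimulationConfig:
    """Dialysis-like scenario: age and modality affect death, younger
    subjects are treated sooner, treatment is protective, and a binary
    marker confounds treatment initiation and death."""
    return SimulationConfig(
        n=n,
        seed=seed,
        age_mean=60.0,
        age_sd=15.0,
        modality_prevalence=0.65,
        death_rate=0.10,
        death_log_hr_age=0.04,
        death_log_hr_modality=0.15,
        treat_rate=0.12,
        treat_log_hr_age=-0.03,
        treat_log_hr_modality=0.0,
        post_treat_death_rate=0.04,
        confounder_rate=0.3,
        confounder_death_log_hr=math.log(2.0),
        confounder_treat_log_hr=math.log(3.0),
        visit_interval=0.5,
        admin_censor_time=10.0,
        censor_rate=0.02,
    )


def confounded_scenario(n: int = 10_000, seed: int = 0) -> SimulationConfig:
    """Covariate-free confounded scenario: the marker alone drives both
    treatment initiation (delta = ln 3) and death (gamma = ln 2), with a
    protective treatment, so censoring at treatment start is informative."""
    return SimulationConfig(
        n=n,
        seed=seed,
        death_rate=0.06,
        treat_rate=0.15,
        post_treat_death_rate=0.03,
        confounder_rate=0.3,
        confounder_death_log_hr=math.log(2.0),
        confounder_treat_log_hr=math.log(3.0),
        visit_interval=0.5,
        admin_censor_time=10.0,
        censor_rate=0.0,
    )


# ---------------------------------------------------------------------------
# sampling kernel


def _sample_subject(rng, cfg: SimulationConfig, treatment_enabled: bool, t_cap: float):
    """One subject's path by exact competing-clock sampling.

    The latent marker Z drives the death hazard from its jump onward; the
    treatment intensity responds to the *observed* marker, i.e. from the
    first visit at or after the jump (treatment decisions are made on
    measured values, biology follows the latent state).  All hazards are
    piecewise constant, so sampling is exact: exponential clocks between
    rate-change boundaries, redrawn (memorylessness) at each boundary.

    Returns (age, modality, censor_time, death_time, treat_time, z_time),
    times inf when the transition does not happen before ``t_cap``.  The
    draw sequence is identical whether or not the treatment clock is
    enabled (a disabled clock has rate zero), so the counterfactual arm
    reuses per-subject substreams coherently.
    """
    age = rng.normal(cfg.age_mean, cfg.age_sd)
    modality = 1.0 if rng.random() < cfg.modality_prevalence else 0.0
    e_cens = rng.exponential(1.0)
    c_indep = e_cens / cfg.censor_rate if cfg.censor_rate > 0 else math.inf

    lam, alp, mu = cfg.hazards_for(age, modality)
    if not treatment_enabled:
        alp = 0.0
    g = math.exp(cfg.confounder_death_log_hr)
    d = math.exp(cfg.confounder_treat_log_hr)

    t = 0.0
    z = 0                 # latent marker
    z_seen = 0            # marker as observed at visits
    z_obs_t = math.inf    # first visit at/after the latent jump
    treated = False
    death = math.inf
    v = math.inf
    z_time = math.inf
    while t < t_cap:
        r_death = (mu if treated else lam) * (g if z else 1.0)
        r_treat = 0.0 if treated else alp * (d if z_seen else 1.0)
        r_z = cfg.confounder_rate if z == 0 else 0.0
        total = r_death + r_treat + r_z
        boundary = z_obs_t if (z and not z_seen) else math.inf
        if total <= 0.0:
            if boundary < t_cap:
                t = boundary
                z_seen = 1
                continue
            break
        t_next = t + rng.exponential(1.0) / total
        if t_next >= min(boundary, t_cap):
            if boundary < t_cap:
                t = boundary
                z_seen = 1
                continue
            break
        t = t_next
        u = rng.random() * total
        if u < r_death:
            death = t
            break
        elif u < r_death + r_treat:
            treated = True
            v = t
        else:
            z = 1
            z_time = t
            z_obs_t = cfg.visit_interval * math.ceil(t / cfg.visit_interval)
    return age, modality, c_indep, death, v, z_time


def _substreams(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Generate a counting-process cohort under the illness-death model.

    Rows break at marker-observation changes (first visit at or after the
    latent jump), at treatment initiation and at exit; the ``z`` column
    holds the observed (LOCF) marker value at interval start.
    """
    cfg = config
    tau = cfg.admin_censor_time
    rows_id, rows = [], {k: [] for k in ("start", "stop", "event", "treated", "age", "modality", "z")}
    for i, ss in enumerate(_substreams(cfg.seed, cfg.n)):
        rng = np.random.default_rng(ss)
        age, modality, c_indep, death, v, z_time = _sample_subject(rng, cfg, True, tau)
        end = min(tau, c_indep, death)
        if end <= 0:
            continue
        event = 1 if death <= min(tau, c_indep) else 0
        # observed marker switches at the first visit at/after the jump
        z_obs = (
            cfg.visit_interval * math.ceil(z_time / cfg.visit_interval)
            if z_time < math.inf
            else math.inf
        )
        breaks = {z_obs, v}
        pts = [0.0] + sorted(b for b in breaks if 0.0 < b < end) + [end]
        for s, e in zip(pts[:-1], pts[1:]):
            rows_id.append(i)
            rows["start"].append(s)
            rows["stop"].append(e)
            rows["event"].append(event if e == end else 0)
            rows["treated"].append(1 if s >= v else 0)
            rows["age"].append(age)
            rows["modality"].append(modality)
            rows["z"].append(1.0 if s >= z_obs else 0.0)
    df = pd.DataFrame({"id": rows_id, **rows})
    roles = {"age": BASELINE, "modality": BASELINE, "z": TIME_UPDATED}
    return CohortDataset(df=df, covariate_roles=roles,
                         followup_mode=CONTINUES_AFTER_TREATMENT)


def simulate_counterfactual_untreated(
    config: SimulationConfig, n_mc: int | None = None, seed: int | None = None
) -> np.ndarray:
    """Death times in the hypothetical world with treatment eliminated.

    The death mechanism (including the latent confounder process) is
    unchanged; only the treatment clock is disabled and censoring is not
    applied, so the returned times are the gold standard for the
    hypothetical risk.  Times are inf when death does not occur before
    the administrative horizon.  With ``seed=None`` the cohort's own
    substreams are reused (subject i matches subject i of
    :func:`simulate_cohort`); pass a different seed for an independent
    Monte-Carlo arm.
    """
    cfg = config
    n = config.n if n_mc is None else int(n_mc)
    times = np.empty(n)
    for i, ss in enumerate(_substreams(cfg.seed if seed is None else seed, n)):
        rng = np.random.default_rng(ss)
        _, _, _, death, _, _ = _sample_subject(rng, cfg, False, cfg.admin_censor_time)
        times[i] = death
    return times


# ---------------------------------------------------------------------------
# true estimands


@dataclasses.dataclass
class TrueEstimands:
    """Oracle values of the four risks on a grid, with provenance."""

    grid: np.ndarray
    f_ignore: np.ndarray
    f_composite: np.ndarray
    f_while_untreated: np.ndarray
    f_hypothetical: np.ndarray
    provenance: str
    mc_arm_size: int | None = None
    mc_se: dict | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        for name in ("f_ignore", "f_composite", "f_while_untreated", "f_hypothetical"):
            setattr(self, name, np.asarray(getattr(self, name), float))

    def as_dict(self) -> dict:
        return {
            "ignore": self.f_ignore,
            "composite": self.f_composite,
            "while_untreated": self.f_while_untreated,
            "hypothetical": self.f_hypothetical,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, vals in self.as_dict().items():
            for t, v in zip(self.grid, vals):
                se = None
                if self.mc_se is not None:
                    se = float(np.interp(t, self.grid, self.mc_se[name]))
                rows.append(
                    {"time": t, "estimand": name, "value": v,
                     "provenance": self.provenance, "mc_se": se}
                )
        return pd.DataFrame(rows)


def closed_form_estimands(lam: float, alp: float, mu: float, grid) -> TrueEstimands:
    """Exact risks under constant hazards and no confounder.

    F_hyp(t)  = 1 - e^{-lam t}
    F_comp(t) = 1 - e^{-(lam+alp) t}
    F_wu(t)   = lam/(lam+alp) (1 - e^{-(lam+alp) t})
    F_ign(t)  = F_wu(t) + int_0^t alp e^{-(lam+alp)s} (1 - e^{-mu (t-s)}) ds
    (the last term: treated at s, then dying from the post-treatment
    hazard before t), the integral by adaptive quadrature.
    """
    grid = np.asarray(grid, float)
    tot = lam + alp
    f_hyp = 1.0 - np.exp(-lam * grid)
    f_comp = 1.0 - np.exp(-tot * grid)
    f_wu = (lam / tot) * f_comp if tot > 0 else np.zeros_like(grid)
    f_ign = np.array(
        [
            fw
            + integrate.quad(
                lambda s, t=t: alp * math.exp(-tot * s) * (1.0 - math.exp(-mu * (t - s))),
                0.0,
                t,
            )[0]
            for t, fw in zip(grid, f_wu)
        ]
    )
    return TrueEstimands(grid, f_ign, f_comp, f_wu, f_hyp, provenance="closed_form")


def true_estimands(
    config: SimulationConfig,
    grid: Sequence[float],
    profile: dict | None = None,
    n_mc: int = 200_000,
) -> TrueEstimands:
    """Oracle values of the four estimands for the given configuration.

    Configurations without an active confounder have closed forms
    conditional on the baseline profile (defaults to the covariate means,
    i.e. baseline rates).  Otherwise two uncensored Monte-Carlo arms are
    run (the factual cohort and the no-treatment counterfactual), with
    binomial standard errors recorded.
    """
    cfg = config
    grid = np.asarray(grid, float)
    if cfg.is_analytic:
        profile = profile or {}
        age = profile.get("age", cfg.age_mean)
        modality = profile.get("modality", 0.0)
        lam, alp, mu = cfg.hazards_for(age, modality)
        return closed_form_estimands(lam, alp, mu, grid)

    # Monte-Carlo: population-average risks from uncensored arms
    big = dataclasses.replace(
        cfg, n=n_mc, censor_rate=0.0,
        admin_censor_time=max(cfg.admin_censor_time, float(grid.max())),
    )
    # truth arms use seeds derived from (but distinct from) the config seed,
    # so they are independent of any estimation cohort drawn with cfg.seed
    death = np.empty(n_mc)
    tmin = np.empty(n_mc)
    wu = np.empty(n_mc)
    for i, ss in enumerate(_substreams(_derive_seed(big.seed + 1), n_mc)):
        rng = np.random.default_rng(ss)
        _, _, _, d, v, _ = _sample_subject(rng, big, True, big.admin_censor_time)
        death[i] = d
        tmin[i] = min(d, v)
        wu[i] = d if d < v else math.inf
    cf = simulate_counterfactual_untreated(big, n_mc=n_mc, seed=_derive_seed(big.seed))

    def ecdf(x):
        return np.array([(x <= t).mean() for t in grid])

    vals = {
        "ignore": ecdf(death),
        "composite": ecdf(tmin),
        "while_untreated": ecdf(wu),
        "hypothetical": ecdf(cf),
    }
    se = {k: np.sqrt(v * (1 - v) / n_mc) for k, v in vals.items()}
    return TrueEstimands(
        grid,
        vals["ignore"],
        vals["composite"],
        vals["while_untreated"],
        vals["hypothetical"],
        provenance="monte_carlo",
        mc_arm_size=n_mc,
        mc_se=se,
    )


def _derive_seed(seed: int) -> int:
    # distinct but deterministic stream for the counterfactual arm
    return (int(seed) * 2654435761 + 97) % (2**31 - 1)
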