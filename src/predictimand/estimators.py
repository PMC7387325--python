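"""The four predictimand strategies as fit/predict estimators.

Each estimator is fitted on a :class:`~predictimand.cohort.CohortDataset`
and predicts P(outcome by t | baseline profile) on a time grid:

``IgnoreTreatmentRisk``
    risk of the event regardless of treatment, P(T <= t | X(0)) --
    survival model for T, no censoring at treatment start (needs
    follow-up continuing after initiation).
``CompositeRisk``
    risk of event-or-treatment, P(min(T, V) <= t | X(0)).
``WhileUntreatedRisk``
    risk of the event before treatment, P(T <= t, T < V | X(0)) --
    cumulative incidence from two cause-specific hazard models.
``HypotheticalRisk``
    counterfactual risk were treatment eliminated,
    P(T^{v=inf} <= t | X(0)), by one of four methods: censor at V,
    model the time-dependent treatment term and predict with A(t) = 0,
    or either of these with stabilized inverse-probability weights
    (IPCW / IPTW) correcting for time-updated confounders of treatment
    initiation.

With an empty covariate list the estimators switch to the matching
nonparametric estimator (Kaplan-Meier / Aalen-Johansen), Cox-Efron
otherwise.  The classes follow the scikit-learn estimator protocol
(``get_params``/``set_params``/``clone``, fitted attributes suffixed
with ``_``); the module-level ``estimate_*`` functions are thin wrappers.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import (
    COMPOSITE,
    CONTINUES_AFTER_TREATMENT,
    HYPOTHETICAL_CENSOR,
    IGNORE,
    WHILE_UNTREATED,
    CapabilityError,
    CohortDataset,
    apply_strategy_view,
    episode_split,
)
from .survival import (
    RiskCurve,
    StepCoefficient,
    aalen_johansen,
    cuminc_from_cause_specific,
    fit_cox,
    kaplan_meier,
    predict_survival,
)
from .weights import IPCW, IPTW, compute_stabilized_weights, fit_weight_models

HYPOTHETICAL = "hypothetical"
STRATEGIES = (IGNORE, COMPOSITE, WHILE_UNTREATED, HYPOTHETICAL)
HYPOTHETICAL_METHODS = ("censor", "model_treatment", "censor_ipcw", "model_iptw")

#: Table-1-style key assumptions attached to each strategy's result.
ASSUMPTIONS = {
    IGNORE: ("treatment_policy_stable", "noninformative_censoring"),
    COMPOSITE: ("treatment_policy_stable", "noninformative_censoring"),
    WHILE_UNTREATED: ("treatment_policy_stable", "noninformative_censoring"),
    HYPOTHETICAL: ("exchangeability", "consistency", "positivity"),
}


@dataclasses.dataclass
class PredictimandSpec:
    """What to estimate: strategy, horizon, profile and evaluation grid."""

    strategy: str
    horizon: float
    baseline_profile: dict = dataclasses.field(default_factory=dict)
    grid: Sequence[float] | None = None
    hypothetical_method: str | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if (self.hypothetical_method is not None) != (self.strategy == HYPOTHETICAL):
            raise ValueError(
                "hypothetical_method must be given exactly when strategy='hypothetical'"
            )
        if self.hypothetical_method is not None and (
            self.hypothetical_method not in HYPOTHETICAL_METHODS
        ):
            raise ValueError(f"unknown hypothetical method {self.hypothetical_method!r}")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.grid is None:
            self.grid = np.linspace(0.0, self.horizon, 101)[1:]
        self.grid = np.asarray(self.grid, float)
        if (np.diff(self.grid) <= 0).any() or (self.grid <= 0).any() or (
            self.grid > self.horizon + 1e-12
        ).any():
            raise ValueError("grid must be strictly increasing within (0, horizon]")


@dataclasses.dataclass
class PredictimandResult:
    """A risk curve together with its strategy, method and assumptions."""

    curve: RiskCurve
    strategy: str
    method: str | None = None
    assumptions: tuple = ()
    details: dict = dataclasses.field(default_factory=dict)


class _BasePredictimand(BaseEstimator):
    """Shared fit/predict plumbing for the strategy estimators."""

    strategy: str = ""

    def __init__(self, covariates=(), ties="efron"):
        self.covariates = covariates
        self.ties = ties

    # -- helpers -----------------------------------------------------------

    def _covars(self) -> list[str]:
        return list(self.covariates or ())

    def _check_fitted(self) -> None:
        if not hasattr(self, "nonparametric_"):
            raise RuntimeError("estimator is not fitted; call fit(data) first")

    def fit(self, data: CohortDataset, y=None):
        self.nonparametric_ = not self._covars()
        self._fit(data)
        return self

    def predict_risk(self, profile: Mapping[str, float] | None, times) -> RiskCurve:
        """Risk curve at a baseline profile (ignored when nonparametric)."""
        self._check_fitted()
        times = np.asarray(times, float)
        curve = self._predict(dict(profile or {}), times)
        curve.strategy = self.strategy
        return curve

    def predict(self, profile, times) -> np.ndarray:
        return self.predict_risk(profile, times).risk

    @staticmethod
    def _np_curve_at(curve: RiskCurve, times: np.ndarray) -> RiskCurve:
        vals = np.array([curve.risk_at(t) for t in times])
        return RiskCurve(times, vals)


class IgnoreTreatmentRisk(_BasePredictimand):
    """P(T <= t | X(0)) under the development data's treatment policy."""

    strategy = IGNORE

    def _fit(self, data: CohortDataset) -> None:
        view = apply_strategy_view(data, IGNORE)
        if self.nonparametric_:
            df = view.df
            self.curve_ = kaplan_meier(
                df["stop"], df["event"], start=df["start"], strategy=IGNORE
            )
        else:
            self.model_ = fit_cox(view, covariates=self._covars(), ties=self.ties)

    def _predict(self, profile, times) -> RiskCurve:
        if self.nonparametric_:
            return self._np_curve_at(self.curve_, times)
        return predict_survival(self.model_, profile, times)


class CompositeRisk(_BasePredictimand):
    """P(min(T, V) <= t | X(0)): event or treatment, whichever first."""

    strategy = COMPOSITE

    def _fit(self, data: CohortDataset) -> None:
        view = apply_strategy_view(data, COMPOSITE)
        if self.nonparametric_:
            df = view.df
            self.curve_ = kaplan_meier(
                df["stop"], df["event"], start=df["start"], strategy=COMPOSITE
            )
        else:
            self.model_ = fit_cox(view, covariates=self._covars(), ties=self.ties)

    def _predict(self, profile, times) -> RiskCurve:
        if self.nonparametric_:
            return self._np_curve_at(self.curve_, times)
        return predict_survival(self.model_, profile, times)


class WhileUntreatedRisk(_BasePredictimand):
    """P(T <= t, T < V | X(0)): cumulative incidence with treatment competing."""

    strategy = WHILE_UNTREATED

    def _fit(self, data: CohortDataset) -> None:
        views = apply_strategy_view(data, WHILE_UNTREATED)
        if self.nonparametric_:
            ev, tr = views["event"].df, views["treatment"].df
            cause = np.where(ev["event"] == 1, 1, np.where(tr["event"] == 1, 2, 0))
            cif1, _ = aalen_johansen(ev["stop"], cause, start=ev["start"])
            self.curve_ = cif1
        else:
            self.event_model_ = fit_cox(
                views["event"], covariates=self._covars(), ties=self.ties
            )
            if views["treatment"].df["event"].sum() == 0:
                # nobody treated: no competing cause
                self.treatment_model_ = None
            else:
                self.treatment_model_ = fit_cox(
                    views["treatment"], covariates=self._covars(), ties=self.ties
                )

    def _predict(self, profile, times) -> RiskCurve:
        if self.nonparametric_:
            return self._np_curve_at(self.curve_, times)
        return cuminc_from_cause_specific(
            self.event_model_, self.treatment_model_, profile, times
        )


class HypotheticalRisk(_BasePredictimand):
    """P(T^{v=inf} <= t | X(0)): risk were treatment eliminated.

    Parameters
    ----------
    method : {"censor", "model_treatment", "censor_ipcw", "model_iptw"}
        censor: censor follow-up at treatment start (assumes initiation
        depends on X(0) only); model_treatment: keep post-treatment
        follow-up, add a time-dependent treatment term and predict with
        A(t) = 0; the *_ipcw / *_iptw variants additionally reweight by
        stabilized inverse probabilities of remaining untreated, given
        the time-updated ``weight_denominator`` covariates.
    treatment_cutpoints : optional times at which the treatment
        coefficient jumps (piecewise-constant time-varying effect).
    treatment_interactions : optional baseline covariate names
        interacted with the treatment term.
    weight_numerator, weight_denominator : covariate lists for the
        stabilized-weight models (numerator default: intercept only).
    weight_truncation : optional (lo, hi) percentile clipping.
    weight_update_interval : time resolution at which the stabilized
        weights are refreshed: the cohort is episode-split on this grid
        before weighting, so each subject's weight tracks the survivor
        ratio over follow-up instead of being frozen over long
        intervals.  Fitted quantities are otherwise invariant to the
        split.
    """

    strategy = HYPOTHETICAL

    def __init__(
        self,
        covariates=(),
        ties="efron",
        method="censor",
        treatment_cutpoints=None,
        treatment_interactions=(),
        weight_numerator=(),
        weight_denominator=(),
        weight_truncation=None,
        weight_update_interval=0.25,
    ):
        super().__init__(covariates=covariates, ties=ties)
        self.method = method
        self.treatment_cutpoints = treatment_cutpoints
        self.treatment_interactions = treatment_interactions
        self.weight_numerator = weight_numerator
        self.weight_denominator = weight_denominator
        self.weight_truncation = weight_truncation
        self.weight_update_interval = weight_update_interval

    def _fit(self, data: CohortDataset) -> None:
        method = self.method
        if method not in HYPOTHETICAL_METHODS:
            raise ValueError(f"unknown hypothetical method {method!r}")
        if method in ("model_treatment", "model_iptw") and (
            data.followup_mode != CONTINUES_AFTER_TREATMENT
        ):
            raise CapabilityError(
                f"hypothetical method {method!r} models the treatment effect and "
                "requires continued follow-up after treatment initiation"
            )
        nobody_treated = (data.df["treated"].max() == 0) and (data.df["tx"].max() == 0)
        if nobody_treated:
            # nothing to censor, model or weight: every method coincides
            # with the ignore-treatment estimate
            view = data.copy_with(data.df.copy())
            if self.nonparametric_:
                df = view.df
                self.curve_ = kaplan_meier(df["stop"], df["event"], start=df["start"])
            else:
                self.model_ = fit_cox(view, covariates=self._covars(), ties=self.ties)
            self._degenerate_untreated_ = True
            return
        self._degenerate_untreated_ = False

        weighted = method in ("censor_ipcw", "model_iptw")
        if weighted and not list(self.weight_denominator):
            raise ValueError(
                f"method {method!r} needs weight_denominator covariates "
                "(the time-updated confounders of treatment initiation)"
            )

        weights = None
        if weighted:
            dt = self.weight_update_interval
            if dt:
                tmax = float(data.df["stop"].max())
                data = episode_split(data, np.arange(dt, tmax, dt))
            self.weight_models_ = fit_weight_models(
                data,
                numerator_covars=list(self.weight_numerator),
                denominator_covars=list(self.weight_denominator),
                ties=self.ties,
            )
            mode = IPCW if method == "censor_ipcw" else IPTW
            self.weight_set_ = compute_stabilized_weights(
                self.weight_models_, data, mode=mode,
                truncation=self.weight_truncation,
            )
            self.positivity_report_ = positivity_report(
                data, list(self.weight_denominator)
            )
            if len(self.positivity_report_):
                warnings.warn(
                    "positivity: some covariate strata have no treated or no "
                    "untreated person-time; a shorter prediction horizon may "
                    "be needed (see positivity_report_)",
                    UserWarning,
                    stacklevel=2,
                )

        if method in ("censor", "censor_ipcw"):
            view = apply_strategy_view(data, HYPOTHETICAL_CENSOR)
            if weights is None and weighted:
                weights = self._align_weights(view.df)
            if self.nonparametric_:
                df = view.df
                self.curve_ = kaplan_meier(
                    df["stop"], df["event"], start=df["start"], weights=weights
                )
            else:
                self.model_ = fit_cox(
                    view, covariates=self._covars(), weights=weights, ties=self.ties
                )
        else:  # model_treatment / model_iptw
            view = apply_strategy_view(data, IGNORE)
            if weighted:
                weights = self._align_weights(view.df)
            step_terms = []
            if self.treatment_cutpoints:
                step_terms.append(StepCoefficient("treated", list(self.treatment_cutpoints)))
            interactions = [("treated", c) for c in (self.treatment_interactions or ())]
            self.model_ = fit_cox(
                view,
                covariates=self._covars() + ["treated"],
                step_terms=step_terms,
                interactions=interactions,
                weights=weights,
                ties=self.ties,
            )

    def _align_weights(self, view_df: pd.DataFrame) -> np.ndarray:
        merged = view_df[["id", "start", "stop"]].merge(
            self.weight_set_.table, on=["id", "start", "stop"], how="left",
            validate="one_to_one",
        )
        w = merged["weight"].to_numpy(float)
        if np.isnan(w).any():
            raise RuntimeError("weight set does not cover all view intervals")
        return w

    def _predict(self, profile, times) -> RiskCurve:
        if self.nonparametric_ and (
            self._degenerate_untreated_ or self.method in ("censor", "censor_ipcw")
        ):
            return self._np_curve_at(self.curve_, times)
        path = None
        if not self._degenerate_untreated_ and self.method in ("model_treatment", "model_iptw"):
            # eliminate treatment over the whole horizon
            path = {"treated": 0.0}
        return predict_survival(self.model_, profile, times, covariate_path=path)


def positivity_report(data: CohortDataset, covariates: Sequence[str]) -> pd.DataFrame:
    """Deciles of each weight covariate with zero treated or zero untreated
    person-time over follow-up (a warning sign for the positivity
    assumption behind the weighted hypothetical estimators)."""
    df = data.df
    persontime = df["stop"] - df["start"]
    treated_anytime = df.groupby("id", sort=False)["treated"].transform("max")
    rows = []
    for cov in covariates:
        x = df[cov].to_numpy(float)
        qs = np.unique(np.quantile(x, np.linspace(0, 1, 11)))
        if len(qs) < 2:
            continue
        bins = np.clip(np.searchsorted(qs, x, side="right") - 1, 0, len(qs) - 2)
        for b in range(len(qs) - 1):
            sel = bins == b
            pt_treated = float(persontime[sel & (treated_anytime == 1)].sum())
            pt_untreated = float(persontime[sel & (treated_anytime == 0)].sum())
            if pt_treated == 0.0 or pt_untreated == 0.0:
                rows.append(
                    {
                        "covariate": cov,
                        "stratum": b + 1,
                        "lower": qs[b],
                        "upper": qs[b + 1],
                        "persontime_treated": pt_treated,
                        "persontime_untreated": pt_untreated,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# functional wrappers


_CLASS_FOR = {
    IGNORE: IgnoreTreatmentRisk,
    COMPOSITE: CompositeRisk,
    WHILE_UNTREATED: WhileUntreatedRisk,
}


def _wrap(est, data, spec: PredictimandSpec, **details) -> PredictimandResult:
    est.fit(data)
    curve = est.predict_risk(spec.baseline_profile, spec.grid)
    return PredictimandResult(
        curve=curve,
        strategy=spec.strategy,
        method=getattr(est, "method", None),
        assumptions=ASSUMPTIONS[spec.strategy],
        details={"estimator": est, **details},
    )


def estimate_ignore(data, covariates, spec: PredictimandSpec) -> PredictimandResult:
    return _wrap(IgnoreTreatmentRisk(covariates=covariates), data, spec)


def estimate_composite(data, covariates, spec: PredictimandSpec) -> PredictimandResult:
    return _wrap(CompositeRisk(covariates=covariates), data, spec)


def estimate_while_untreated(data, covariates, spec: PredictimandSpec) -> PredictimandResult:
    return _wrap(WhileUntreatedRisk(covariates=covariates), data, spec)


def estimate_hypothetical(
    data, covariates, spec: PredictimandSpec, weight_config: dict | None = None
) -> PredictimandResult:
    weight_config = dict(weight_config or {})
    est = HypotheticalRisk(
        covariates=covariates,
        method=spec.hypothetical_method or "censor",
        treatment_cutpoints=weight_config.pop("treatment_cutpoints", None),
        treatment_interactions=weight_config.pop("treatment_interactions", ()),
        weight_numerator=weight_config.pop("numerator", ()),
        weight_denominator=weight_config.pop("denominator", ()),
        weight_truncation=weight_config.pop("truncation", None),
    )
    if weight_config:
        raise ValueError(f"unknown weight_config keys: {sorted(weight_config)}")
    return _wrap(est, data, spec)


def estimate(data, covariates, spec: PredictimandSpec, weight_config=None) -> PredictimandResult:
    """Dispatch a :class:`PredictimandSpec` to the matching estimator."""
    if spec.strategy == HYPOTHETICAL:
        return estimate_hypothetical(data, covariates, spec, weight_config)
    cls = _CLASS_FOR[spec.strategy]
    return _wrap(cls(covariates=covariates), data, spec)


ONE_MINUS_COMPOSITE = "one_minus_composite"


def compare_predictimands(
    data: CohortDataset,
    covariates: Sequence[str],
    specs: Sequence[PredictimandSpec],
    profiles: Sequence[Mapping[str, float]] | None = None,
    weight_config: dict | None = None,
) -> pd.DataFrame:
    """Long table of horizon risks: profile x strategy (x method).

    Whenever a composite spec is included, the complementary
    "event-free and untreated" row (one minus composite) is appended for
    each profile.
    """
    if not specs:
        raise ValueError("specs must be nonempty")
    profiles = list(profiles) if profiles is not None else [
        specs[0].baseline_profile
    ]
    rows = []
    for prof in profiles:
        for spec in specs:
            sp = dataclasses.replace(spec, baseline_profile=dict(prof))
            res = estimate(data, covariates, sp, weight_config)
            risk = res.curve.risk_at(sp.horizon)
            rows.append(
                {
                    "profile": _profile_label(prof),
                    "strategy": sp.strategy,
                    "method": res.method or "",
                    "horizon": sp.horizon,
                    "risk": risk,
                }
            )
            if sp.strategy == COMPOSITE:
                rows.append(
                    {
                        "profile": _profile_label(prof),
                        "strategy": ONE_MINUS_COMPOSITE,
                        "method": "",
                        "horizon": sp.horizon,
                        "risk": 1.0 - risk,
                    }
                )
    return pd.DataFrame(rows)


def _profile_label(profile: Mapping[str, float]) -> str:
    return ",".join(f"{k}={v:g}" for k, v in sorted(profile.items())) or "(marginal)"
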