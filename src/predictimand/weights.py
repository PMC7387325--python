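"""Stabilized inverse-probability weights for treatment initiation.

The weight of subject i at time t is the ratio of two predicted
probabilities of still being untreated at t,

    w_i(t) = S_num(t | numerator covariates) / S_den(t | covariate history),

with both survivor functions taken from cause-specific Cox models for
treatment initiation fitted on untreated person-time (treatment start is
the event; untreated follow-up is censored at death or end of follow-up).
The numerator is typically intercept-only (a marginal probability), the
denominator conditions on the time-updated confounders, so the weights
undo the dependence of treatment initiation on risk-factor progression.

Evaluation convention: the weight attached to an interval ``(start, stop]``
is the survivor ratio at ``stop`` computed with the covariate values at
``start`` (left-continuous histories), so weights are predictable.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortDataset, WHILE_UNTREATED, apply_strategy_view
from .survival import CoxFit, DegenerateDataError, fit_cox

IPCW = "ipcw"
IPTW = "iptw"


@dataclasses.dataclass
class WeightModelPair:
    """Numerator and denominator treatment-initiation models."""

    numerator: CoxFit
    denominator: CoxFit
    numerator_covariates: list[str]
    denominator_covariates: list[str]


@dataclasses.dataclass
class WeightSet:
    """Per-interval stabilized weights (positive, constant within interval)."""

    table: pd.DataFrame  # columns id, start, stop, weight
    mode: str
    truncation: tuple[float, float] | None = None

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy(float)

    def summary(self, deciles_of: np.ndarray | None = None) -> pd.DataFrame:
        """Weight summaries (mean/min/max/percentiles) per follow-up decile."""
        t = self.table["stop"].to_numpy(float)
        edges = np.quantile(t, np.linspace(0, 1, 11))
        edges[0] -= 1e-9
        rows = []
        for k in range(10):
            sel = (t > edges[k]) & (t <= edges[k + 1])
            w = self.weights[sel]
            if w.size == 0:
                continue
            rows.append(
                {
                    "decile": k + 1,
                    "t_max": edges[k + 1],
                    "n": w.size,
                    "mean": w.mean(),
                    "min": w.min(),
                    "p1": np.percentile(w, 1),
                    "p99": np.percentile(w, 99),
                    "max": w.max(),
                }
            )
        return pd.DataFrame(rows)


def fit_weight_models(
    data: CohortDataset,
    numerator_covars: Sequence[str] = (),
    denominator_covars: Sequence[str] = (),
    ties: str = "efron",
) -> WeightModelPair:
    """Fit the two treatment-initiation models on untreated person-time.

    An empty ``numerator_covars`` gives the intercept-only (marginal)
    numerator.  ``denominator_covars`` should include the time-updated
    confounders of treatment initiation.
    """
    view = apply_strategy_view(data, WHILE_UNTREATED)["treatment"]
    if view.df["event"].sum() == 0:
        raise DegenerateDataError("no treatment-initiation events in cohort")
    num = fit_cox(view, covariates=list(numerator_covars), ties=ties)
    den = fit_cox(view, covariates=list(denominator_covars), ties=ties)
    return WeightModelPair(
        numerator=num,
        denominator=den,
        numerator_covariates=list(numerator_covars),
        denominator_covariates=list(denominator_covars),
    )


def _cumhaz_at_stops(fit: CoxFit, df: pd.DataFrame, covars: Sequence[str]) -> np.ndarray:
    """Cumulative treatment-initiation hazard at each interval stop.

    Accumulates e^{x(start)'beta} dLambda0 over baseline-hazard jumps in
    ``(start, stop]``, then cumulates along each subject's intervals, so
    H(stop_k) uses the covariate path as stepped through the intervals.
    """
    start = df["start"].to_numpy(float)
    stop = df["stop"].to_numpy(float)
    if fit.baseline_times.size == 0:
        return np.zeros(len(df))
    cum = np.concatenate([[0.0], np.cumsum(fit.baseline_hazard)])
    lo = np.searchsorted(fit.baseline_times, start, side="right")
    hi = np.searchsorted(fit.baseline_times, stop, side="right")
    dL = cum[hi] - cum[lo]
    if covars:
        X = df[list(covars)].to_numpy(float)
        eta = X @ fit.coefficients.reindex(list(covars)).to_numpy(float)
    else:
        eta = np.zeros(len(df))
    inc = np.exp(eta) * dL
    return pd.Series(inc).groupby(df["id"].to_numpy()).cumsum().to_numpy()


def compute_stabilized_weights(
    models: WeightModelPair,
    data: CohortDataset,
    mode: str = IPCW,
    truncation: tuple[float, float] | None = None,
) -> WeightSet:
    """Stabilized weights for every interval the mode covers.

    ``ipcw`` weights untreated person-time only (treated time is censored
    away by the accompanying view); ``iptw`` additionally carries each
    treated subject's weight frozen at its value at treatment start for
    all post-treatment intervals.  ``truncation=(lo, hi)`` clips at those
    percentiles of the untruncated weight distribution.
    """
    if mode not in (IPCW, IPTW):
        raise ValueError(f"unknown weight mode {mode!r}")
    df = data.df
    untreated = df.loc[df["treated"] == 0, ["id", "start", "stop"]].copy()
    udf = df.loc[df["treated"] == 0]
    H_num = _cumhaz_at_stops(models.numerator, udf, models.numerator_covariates)
    H_den = _cumhaz_at_stops(models.denominator, udf, models.denominator_covariates)
    if not (np.isfinite(H_num).all() and np.isfinite(H_den).all()):
        bad = untreated["id"].iloc[int(np.argmax(~np.isfinite(H_num + H_den)))]
        raise FloatingPointError(f"non-finite survivor evaluation for subject {bad!r}")
    w = np.exp(H_den - H_num)  # S_num / S_den
    untreated["weight"] = w

    if mode == IPTW:
        treated = df.loc[df["treated"] == 1, ["id", "start", "stop"]].copy()
        last_w = untreated.groupby("id", sort=False)["weight"].last()
        treated["weight"] = last_w.reindex(treated["id"]).to_numpy()
        table = pd.concat([untreated, treated], ignore_index=True)
        table = table.sort_values(["id", "start"], kind="mergesort").reset_index(drop=True)
    else:
        table = untreated.reset_index(drop=True)

    if truncation is not None:
        lo, hi = truncation
        lo_v, hi_v = np.percentile(table["weight"], [lo, hi])
        table["weight"] = table["weight"].clip(lo_v, hi_v)
    if (table["weight"] <= 0).any() or not np.isfinite(table["weight"]).all():
        raise FloatingPointError("nonpositive or non-finite stabilized weight")
    return WeightSet(table=table, mode=mode, truncation=truncation)
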