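"""Proportional-hazards machinery on counting-process data.

Implements the weighted Cox partial likelihood for ``(start, stop]``
interval data with Efron or Breslow tie handling, Newton-Raphson with
step-halving, the matching baseline cumulative hazard referenced at
covariates = 0, risk-curve prediction with piecewise-constant covariate
paths and step (piecewise-constant-in-time) coefficients, weighted
Kaplan-Meier and Aalen-Johansen estimators, cumulative incidence built
from two cause-specific fits by product-integration, and Schoenfeld
residuals.

Everything funnels through one vectorised risk-set accumulator: for each
distinct event time t_j the sums over the risk set {i : start_i < t_j <=
stop_i} of w_i e^{eta_i} q_i are obtained by difference arrays over the
sorted event times (O(n log m)).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortDataset, SchemaError, split_intervals


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge (e.g. monotone likelihood)."""


class DegenerateDataError(ValueError):
    """No events (or otherwise uninformative data) for the requested fit."""


@dataclasses.dataclass
class StepCoefficient:
    """A coefficient that is piecewise constant in study time.

    ``cutpoints`` are the jump times; a covariate with k cutpoints gets
    k + 1 coefficients, piece j applying on ``(c_{j-1}, c_j]``.
    """

    covariate: str
    cutpoints: Sequence[float]

    def __post_init__(self) -> None:
        self.cutpoints = [float(c) for c in self.cutpoints]
        if sorted(self.cutpoints) != self.cutpoints or len(set(self.cutpoints)) != len(
            self.cutpoints
        ):
            raise ValueError("cutpoints must be strictly increasing")

    @property
    def n_pieces(self) -> int:
        return len(self.cutpoints) + 1

    def piece_names(self) -> list[str]:
        edges = [0.0, *self.cutpoints, np.inf]
        return [
            f"{self.covariate}[{edges[j]:g},{edges[j + 1]:g})" for j in range(self.n_pieces)
        ]

    def piece_at(self, t) -> np.ndarray:
        """Index of the piece containing time t (value on ``(c_{j-1}, c_j]``)."""
        return np.searchsorted(self.cutpoints, np.asarray(t, float), side="left")


@dataclasses.dataclass
class RiskCurve:
    """P(outcome by t) on a time grid for one strategy and baseline profile."""

    times: np.ndarray
    risk: np.ndarray
    strategy: str = ""
    profile: dict | None = None
    extrapolated: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.risk = np.asarray(self.risk, float)

    @property
    def survival(self) -> np.ndarray:
        return 1.0 - self.risk

    def risk_at(self, t: float) -> float:
        """Right-continuous step interpolation; 0 before the first step."""
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return 0.0 if i < 0 else float(self.risk[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "risk": self.risk, "strategy": self.strategy}
        )


# ---------------------------------------------------------------------------
# risk-set accumulator


class _RiskSetAccumulator:
    """Sums of per-row quantities over the risk set of each distinct event time."""

    def __init__(self, start, stop, event, times=None):
        self.start = np.asarray(start, float)
        self.stop = np.asarray(stop, float)
        self.event = np.asarray(event)
        if times is None:
            times = np.unique(self.stop[self.event == 1])
        self.times = times
        self.m = len(times)
        # interval (s, e] covers event-time indices [a, b)
        self.a = np.searchsorted(times, self.start, side="right")
        self.b = np.searchsorted(times, self.stop, side="right")
        self.is_event = (self.event == 1) & np.isin(self.stop, times)
        self.event_idx = np.searchsorted(times, self.stop[self.is_event])

    def riskset_sum(self, q: np.ndarray) -> np.ndarray:
        """S(j) = sum of q_i over rows at risk at event time j."""
        add = np.bincount(self.a, weights=q, minlength=self.m + 1)
        sub = np.bincount(self.b, weights=q, minlength=self.m + 1)
        return np.cumsum(add - sub)[: self.m]

    def event_sum(self, q: np.ndarray) -> np.ndarray:
        """Sum of q_i over rows with an event at event time j."""
        return np.bincount(self.event_idx, weights=q[self.is_event], minlength=self.m)


@dataclasses.dataclass
class CoxFit:
    """A fitted (weighted) proportional-hazards model.

    ``baseline_times`` / ``baseline_hazard`` are the distinct event times and
    the increments dLambda0 of the cumulative baseline hazard referenced at
    covariates = 0, using the tie-matched (Efron or Breslow) estimator.
    """

    coefficients: pd.Series
    covariance: pd.DataFrame
    baseline_times: np.ndarray
    baseline_hazard: np.ndarray
    tie_method: str
    weighted: bool
    n_iter: int
    final_grad_norm: float
    log_likelihood: float
    covariates: list[str]
    step_terms: list[StepCoefficient]
    interactions: list[tuple[str, str]]
    n_events: int

    @property
    def baseline_cumhaz(self) -> np.ndarray:
        return np.cumsum(self.baseline_hazard)

    def to_yaml(self, path) -> None:
        """Serialize coefficients, step-term cutpoints and baseline-hazard
        steps so a fit can be reloaded for prediction."""
        import yaml

        payload = {
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "covariance": self.covariance.to_numpy().tolist(),
            "baseline_times": [float(t) for t in self.baseline_times],
            "baseline_hazard": [float(h) for h in self.baseline_hazard],
            "tie_method": self.tie_method,
            "weighted": bool(self.weighted),
            "n_iter": int(self.n_iter),
            "final_grad_norm": float(self.final_grad_norm),
            "log_likelihood": float(self.log_likelihood),
            "covariates": list(self.covariates),
            "step_terms": [
                {"covariate": s.covariate, "cutpoints": list(s.cutpoints)}
                for s in self.step_terms
            ],
            "interactions": [list(i) for i in self.interactions],
            "n_events": int(self.n_events),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CoxFit":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        names = list(d["coefficients"])
        return cls(
            coefficients=pd.Series(d["coefficients"], dtype=float),
            covariance=pd.DataFrame(
                np.asarray(d["covariance"], float), index=names, columns=names
            ),
            baseline_times=np.asarray(d["baseline_times"], float),
            baseline_hazard=np.asarray(d["baseline_hazard"], float),
            tie_method=d["tie_method"],
            weighted=d["weighted"],
            n_iter=d["n_iter"],
            final_grad_norm=d["final_grad_norm"],
            log_likelihood=d["log_likelihood"],
            covariates=d["covariates"],
            step_terms=[
                StepCoefficient(s["covariate"], s["cutpoints"]) for s in d["step_terms"]
            ],
            interactions=[tuple(i) for i in d["interactions"]],
            n_events=d["n_events"],
        )

    def standard_errors(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.covariance.to_numpy())), index=self.coefficients.index
        )

    def linear_predictor_at(self, profile: Mapping[str, float], t,
                            covariate_path: Mapping | None = None) -> np.ndarray:
        """x(t)' beta(t) for a baseline profile and optional covariate paths.

        ``covariate_path`` maps a covariate name to either a scalar (constant
        path) or a pair ``(cut_times, values)`` of a piecewise-constant path,
        ``values[j]`` applying on ``(cut_{j-1}, cut_j]``.
        """
        t = np.asarray(t, float)
        covariate_path = dict(covariate_path or {})
        step_by_cov = {s.covariate: s for s in self.step_terms}
        eta = np.zeros_like(t, dtype=float)
        beta = self.coefficients

        def value_path(name):
            if name in covariate_path:
                p = covariate_path[name]
                if np.isscalar(p):
                    return np.full_like(t, float(p))
                cuts, vals = p
                return np.asarray(vals, float)[
                    np.searchsorted(np.asarray(cuts, float), t, side="left")
                ]
            if name not in profile:
                raise SchemaError(f"profile is missing covariate {name!r}")
            return np.full_like(t, float(profile[name]))

        for name in self.covariates:
            x = value_path(name)
            if name in step_by_cov:
                sc = step_by_cov[name]
                piece = sc.piece_at(t)
                coefs = np.array([beta[p] for p in sc.piece_names()])
                eta += x * coefs[piece]
            else:
                eta += x * beta[name]
        for a, bcov in self.interactions:
            eta += value_path(a) * value_path(bcov) * beta[f"{a}:{bcov}"]
        return eta


def _design_matrix(
    df: pd.DataFrame,
    covariates: Sequence[str],
    step_terms: Sequence[StepCoefficient],
    interactions: Sequence[tuple[str, str]],
):
    """Expanded design matrix; step terms use the covariate value gated by
    the time piece containing the interval stop (intervals must not cross
    cutpoints -- the caller episode-splits first)."""
    step_by_cov = {s.covariate: s for s in step_terms}
    cols, names = [], []
    stop = df["stop"].to_numpy(float)
    for name in covariates:
        missing = name not in df.columns
        if missing:
            raise SchemaError(f"covariate {name!r} not in data")
        x = df[name].to_numpy(float)
        if name in step_by_cov:
            sc = step_by_cov[name]
            piece = sc.piece_at(stop)
            for j, pname in enumerate(sc.piece_names()):
                cols.append(np.where(piece == j, x, 0.0))
                names.append(pname)
        else:
            cols.append(x)
            names.append(name)
    for a, b in interactions:
        cols.append(df[a].to_numpy(float) * df[b].to_numpy(float))
        names.append(f"{a}:{b}")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    if X.size and not np.isfinite(X).all():
        raise SchemaError("non-finite covariate values in design matrix")
    return X, names


def fit_cox(
    data,
    covariates: Sequence[str] = (),
    step_terms: Sequence[StepCoefficient] = (),
    interactions: Sequence[tuple[str, str]] = (),
    weights=None,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
) -> CoxFit:
    """Maximise the (weighted) Cox partial likelihood on counting-process data.

    Parameters
    ----------
    data : CohortDataset or DataFrame with columns id,start,stop,event.
    covariates : columns entering the linear predictor.
    step_terms : per-covariate piecewise-constant-in-time coefficients
        (data are episode-split at the cutpoints internally; estimates are
        invariant under that split).
    weights : optional per-interval positive case weights (column name or
        array aligned to the rows of ``data``).
    ties : "efron" (default) or "breslow".
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    ds = data if isinstance(data, CohortDataset) else None
    df = data.df if ds is not None else data
    if isinstance(weights, str):
        weights = df[weights].to_numpy(float)
    elif weights is not None:
        weights = np.asarray(weights, float)

    cutpoints = sorted({c for s in step_terms for c in s.cutpoints})
    if cutpoints:
        df = df.copy()
        df["_w"] = 1.0 if weights is None else weights
        df = split_intervals(df, cutpoints)
        weights = df.pop("_w").to_numpy(float)

    start = df["start"].to_numpy(float)
    stop = df["stop"].to_numpy(float)
    event = df["event"].to_numpy(int)
    n = len(df)
    w = np.ones(n) if weights is None else weights
    if (w <= 0).any() or not np.isfinite(w).all():
        raise ValueError("weights must be positive and finite")
    if event.sum() == 0:
        raise DegenerateDataError("no events in data; cannot fit hazard model")

    X, names = _design_matrix(df, covariates, step_terms, interactions)
    p = X.shape[1]
    acc = _RiskSetAccumulator(start, stop, event)

    # weighted event-time summaries (fixed across iterations)
    d_count = acc.event_sum(np.ones(n))             # integer tied-event counts
    W_d = acc.event_sum(w)                          # weighted event mass
    # flattened (event time j, within-tie index l) pairs for Efron
    if ties == "efron":
        d_int = d_count.astype(int)
        rep_j = np.repeat(np.arange(acc.m), d_int)
        l_frac = np.concatenate([np.arange(k) / k for k in d_int]) if acc.m else np.array([])
        mult = np.repeat(W_d / np.maximum(d_int, 1), d_int)
    else:
        rep_j = np.arange(acc.m)
        l_frac = np.zeros(acc.m)
        mult = W_d

    center = (w[:, None] * X).sum(axis=0) / w.sum() if p else np.zeros(0)
    Xc = X - center

    iu = np.triu_indices(p)

    def evaluate(beta):
        eta = Xc @ beta if p else np.zeros(n)
        r = w * np.exp(eta)
        S0 = acc.riskset_sum(r)
        D0 = acc.event_sum(r)
        denom = S0[rep_j] - l_frac * D0[rep_j]
        if (denom <= 0).any():
            return -np.inf, None, None, None
        ll = float((w * event * (Xc @ beta if p else 0.0))[acc.is_event].sum()
                   if p else 0.0) - float((mult * np.log(denom)).sum())
        if p == 0:
            return ll, np.zeros(0), np.zeros((0, 0)), (r, S0, D0, denom)
        S1 = np.column_stack([acc.riskset_sum(r * Xc[:, k]) for k in range(p)])
        D1 = np.column_stack([acc.event_sum(r * Xc[:, k]) for k in range(p)])
        num1 = S1[rep_j] - l_frac[:, None] * D1[rep_j]
        mu = num1 / denom[:, None]
        grad = (w[:, None] * Xc)[acc.is_event].sum(axis=0) - (mult[:, None] * mu).sum(axis=0)
        # second moments, upper triangle only
        S2 = np.column_stack(
            [acc.riskset_sum(r * Xc[:, k] * Xc[:, l]) for k, l in zip(*iu)]
        )
        D2 = np.column_stack(
            [acc.event_sum(r * Xc[:, k] * Xc[:, l]) for k, l in zip(*iu)]
        )
        num2 = S2[rep_j] - l_frac[:, None] * D2[rep_j]
        m2 = (mult[:, None] * (num2 / denom[:, None])).sum(axis=0)
        M2 = np.zeros((p, p))
        M2[iu] = m2
        M2 = M2 + M2.T - np.diag(np.diag(M2))
        info = M2 - (mult[:, None, None] * mu[:, :, None] * mu[:, None, :]).sum(axis=0)
        return ll, grad, info, (r, S0, D0, denom)

    beta = np.zeros(p)
    ll, grad, info, cache = evaluate(beta)
    it = 0
    if p:
        for it in range(1, max_iter + 1):
            gnorm = np.abs(grad).max()
            if gnorm < tol:
                break
            try:
                delta = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular information matrix: {exc}") from exc
            if np.abs(delta).max() < 1e-11:
                # Newton increment below numerical resolution: converged
                beta = beta + delta
                ll, grad, info, cache = evaluate(beta)
                break
            # accept any step that does not decrease the likelihood beyond
            # the rounding floor of the accumulated sums
            ll_floor = ll - 1e-10 * (abs(ll) + 1.0)
            step = 1.0
            for _ in range(30):
                cand = beta + step * delta
                ll_new, g_new, i_new, c_new = evaluate(cand)
                if ll_new >= ll_floor:
                    break
                step /= 2.0
            else:
                if np.abs(beta).max() > 10:
                    j = int(np.abs(beta).argmax())
                    raise ConvergenceError(
                        f"likelihood improvements vanished while the coefficient "
                        f"for {names[j]!r} drifts ({beta[j]:.1f}): monotone partial "
                        "likelihood (perfect separation) likely"
                    )
                raise ConvergenceError("step-halving failed to improve likelihood")
            beta, ll, grad, info, cache = cand, ll_new, g_new, i_new, c_new
        else:
            raise ConvergenceError(
                f"no convergence in {max_iter} iterations "
                f"(gradient sup-norm {np.abs(grad).max():.3g})"
            )
        if np.abs(beta).max() > 20:
            j = int(np.abs(beta).argmax())
            raise ConvergenceError(
                f"coefficient for {names[j]!r} diverged to {beta[j]:.1f}: likely "
                "monotone partial likelihood (perfect separation); check the "
                "covariate or rescale it"
            )
    gnorm = float(np.abs(grad).max()) if p else 0.0

    r, S0, D0, denom = cache
    # tie-matched baseline hazard increments (centered reference)
    dL_centered = np.bincount(rep_j, weights=mult / denom, minlength=acc.m)
    # un-center: eta_true = eta_centered + center' beta
    dL0 = dL_centered * np.exp(-(center @ beta)) if p else dL_centered

    cov = np.linalg.inv(info) if p else np.zeros((0, 0))
    return CoxFit(
        coefficients=pd.Series(beta, index=names, dtype=float),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        baseline_times=acc.times.copy(),
        baseline_hazard=dL0,
        tie_method=ties,
        weighted=weights is not None,
        n_iter=it,
        final_grad_norm=gnorm,
        log_likelihood=ll,
        covariates=list(covariates),
        step_terms=list(step_terms),
        interactions=[tuple(x) for x in interactions],
        n_events=int(event.sum()),
    )


# ---------------------------------------------------------------------------
# prediction


def predict_survival(
    fit: CoxFit,
    profile: Mapping[str, float],
    grid: Sequence[float],
    covariate_path: Mapping | None = None,
    strategy: str = "",
) -> RiskCurve:
    """Risk curve 1 - exp(-int_0^t e^{x(s)'beta(s)} dLambda0(s)) on a grid.

    ``covariate_path`` gives piecewise-constant paths for time-dependent
    terms (e.g. the treatment indicator set to 0 over the whole horizon);
    covariates without a path are held at their ``profile`` value.
    """
    grid = np.asarray(grid, float)
    tj = fit.baseline_times
    eta = fit.linear_predictor_at(profile, tj, covariate_path)
    dH = np.exp(eta) * fit.baseline_hazard
    cumhaz_at_events = np.cumsum(dH)
    idx = np.searchsorted(tj, grid, side="right")
    cum = np.concatenate([[0.0], cumhaz_at_events])[idx]
    risk = 1.0 - np.exp(-cum)
    extrapolated = bool(tj.size and (grid > tj[-1]).any())
    return RiskCurve(grid, risk, strategy=strategy, profile=dict(profile),
                     extrapolated=extrapolated)


# ---------------------------------------------------------------------------
# nonparametric estimators


def _as_start_stop(stop, start=None):
    stop = np.asarray(stop, float)
    start = np.zeros_like(stop) if start is None else np.asarray(start, float)
    return start, stop


def kaplan_meier(stop, event, start=None, weights=None, strategy="kaplan_meier") -> RiskCurve:
    """(Weighted) product-limit estimator on (possibly delayed-entry) data.

    Returns the risk curve 1 - S(t) stepped at the distinct event times.
    """
    start, stop = _as_start_stop(stop, start)
    event = np.asarray(event, int)
    w = np.ones_like(stop) if weights is None else np.asarray(weights, float)
    acc = _RiskSetAccumulator(start, stop, event)
    Y = acc.riskset_sum(w)
    d = acc.event_sum(w)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(Y > 0, d / Y, 0.0)
    S = np.cumprod(1.0 - frac)
    return RiskCurve(acc.times, 1.0 - S, strategy=strategy)


def aalen_johansen(stop, cause, start=None, weights=None):
    """Aalen-Johansen cumulative incidence for two competing causes.

    ``cause`` is 0 (censored), 1 or 2.  Returns ``(cif1, cif2)`` as
    :class:`RiskCurve` objects stepped at the pooled event times, with
    CIF_k(t) = sum_{s<=t} S(s-) d_k(s)/Y(s) and S the all-cause
    product-limit survivor.
    """
    start, stop = _as_start_stop(stop, start)
    cause = np.asarray(cause, int)
    w = np.ones_like(stop) if weights is None else np.asarray(weights, float)
    any_event = (cause > 0).astype(int)
    acc = _RiskSetAccumulator(start, stop, any_event)
    Y = acc.riskset_sum(w)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_all = acc.event_sum(w)
        S = np.cumprod(np.where(Y > 0, 1.0 - d_all / Y, 1.0))
        S_minus = np.concatenate([[1.0], S[:-1]])
        curves = []
        for k in (1, 2):
            acc_k = _RiskSetAccumulator(start, stop, (cause == k).astype(int), times=acc.times)
            d_k = acc_k.event_sum(w)
            inc = np.where(Y > 0, S_minus * d_k / Y, 0.0)
            curves.append(RiskCurve(acc.times, np.cumsum(inc), strategy=f"cif{k}"))
    return tuple(curves)


def cuminc_from_cause_specific(
    fit_event: CoxFit,
    fit_treatment: CoxFit | None,
    profile: Mapping[str, float],
    grid: Sequence[float],
    form: str = "product",
    strategy: str = "while_untreated",
) -> RiskCurve:
    """Cumulative incidence of the event from two cause-specific Cox fits.

    Product-integration over the merged event-time grid (default): the
    all-cause survivor is prod(1 - dL_event - dL_treat) and
    CIF(t|X) = sum_{s<=t} S(s-|X) dL_event(s|X).  ``form="exp"`` uses
    S = exp(-L_event - L_treat) instead (useful when hazard jumps are large).
    ``fit_treatment=None`` means the competing cause never occurs, reducing
    the curve to 1 minus the survivor of ``fit_event``.
    """
    grid = np.asarray(grid, float)
    if fit_treatment is None:
        out = predict_survival(fit_event, profile, grid, strategy=strategy)
        out.strategy = strategy
        return out
    times = np.union1d(fit_event.baseline_times, fit_treatment.baseline_times)

    def increments(fit):
        dL = np.zeros_like(times)
        if fit.baseline_times.size:
            pos = np.searchsorted(times, fit.baseline_times)
            eta = fit.linear_predictor_at(profile, fit.baseline_times)
            dL[pos] = np.exp(eta) * fit.baseline_hazard
        return dL

    dLe = increments(fit_event)
    dLt = increments(fit_treatment)
    if form == "product":
        factors = 1.0 - dLe - dLt
        if (factors < 0).any():
            raise ValueError(
                "negative survivor increment (hazard jump > 1); use finer data "
                "or form='exp'"
            )
        S = np.cumprod(factors)
    elif form == "exp":
        S = np.exp(-np.cumsum(dLe) - np.cumsum(dLt))
    else:
        raise ValueError(f"unknown form {form!r}")
    S_minus = np.concatenate([[1.0], S[:-1]])
    cif = np.cumsum(S_minus * dLe)
    idx = np.searchsorted(times, grid, side="right")
    vals = np.clip(np.concatenate([[0.0], cif])[idx], 0.0, 1.0)
    return RiskCurve(grid, vals, strategy=strategy, profile=dict(profile),
                     extrapolated=bool(times.size and (grid > times[-1]).any()))


# ---------------------------------------------------------------------------
# diagnostics


def schoenfeld_residuals(fit: CoxFit, data, weights=None) -> pd.DataFrame:
    """Schoenfeld residuals at each event: case covariate minus the
    risk-set weighted mean, tie-adjusted per the fit's tie method.

    Returns one row per event (``time`` column plus one column per model
    term); per-term sums vanish at the MLE (score equation).
    """
    df = data.df if isinstance(data, CohortDataset) else data
    if isinstance(weights, str):
        weights = df[weights].to_numpy(float)
    cutpoints = sorted({c for s in fit.step_terms for c in s.cutpoints})
    if cutpoints:
        df = df.copy()
        df["_w"] = 1.0 if weights is None else np.asarray(weights, float)
        df = split_intervals(df, cutpoints)
        weights = df.pop("_w").to_numpy(float)
    X, names = _design_matrix(df, fit.covariates, fit.step_terms, fit.interactions)
    p = X.shape[1]
    if p == 0:
        return pd.DataFrame(columns=["time"])
    beta = fit.coefficients.reindex(names).to_numpy(float)
    n = len(df)
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    acc = _RiskSetAccumulator(
        df["start"].to_numpy(float), df["stop"].to_numpy(float), df["event"].to_numpy(int)
    )
    r = w * np.exp(X @ beta)
    S0 = acc.riskset_sum(r)
    S1 = np.column_stack([acc.riskset_sum(r * X[:, k]) for k in range(p)])
    if fit.tie_method == "efron":
        D0 = acc.event_sum(r)
        D1 = np.column_stack([acc.event_sum(r * X[:, k]) for k in range(p)])
        d = acc.event_sum(np.ones(n)).astype(int)
        mean = np.zeros((acc.m, p))
        for j in np.nonzero(d)[0]:
            l = np.arange(d[j]) / d[j]
            denom = S0[j] - l * D0[j]
            mean[j] = ((S1[j] - l[:, None] * D1[j]) / denom[:, None]).mean(axis=0)
    else:
        mean = S1 / S0[:, None]
    case_rows = np.nonzero(acc.is_event)[0]
    j_of_case = acc.event_idx
    res = X[case_rows] - mean[j_of_case]
    out = pd.DataFrame(res, columns=names)
    out.insert(0, "time", df["stop"].to_numpy(float)[case_rows])
    out["weight"] = w[case_rows]
    return out.sort_values("time").reset_index(drop=True)
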