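"""Counting-process cohort data model for treatment initiation after baseline.

A cohort is stored long-format: one row per subject-interval ``(start, stop]``
carrying the event indicator, the time-dependent treatment status A(t) and
covariate values.  Intervals are half-open ``(start, stop]``; events and
treatment switches attach to ``stop``.  Covariates on a row are the values
known at ``start`` (left-continuous, last observation carried forward), which
keeps them predictable with respect to the hazard filtration.

Two follow-up designs are supported: follow-up that stops when treatment is
initiated (treatment recorded through the ``tx`` cause indicator on the last
interval) and follow-up that continues after initiation (treatment recorded
through the ``treated`` column switching 0 -> 1).
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

REQUIRED_COLUMNS = ("id", "start", "stop", "event", "treated")

STOPS_AT_TREATMENT = "stops_at_treatment"
CONTINUES_AFTER_TREATMENT = "continues_after_treatment"

BASELINE = "baseline"
TIME_UPDATED = "time_updated"


class CohortError(ValueError):
    """Base class for cohort data errors."""


class StructuralError(CohortError):
    """Interval structure violates the counting-process invariants."""


class SchemaError(CohortError):
    """Missing or inconsistent columns / covariate roles."""


class CapabilityError(CohortError):
    """The requested analysis needs follow-up the study design did not collect."""


@dataclasses.dataclass
class SubjectRecord:
    """Per-subject view of the counting-process rows.

    ``treatment_time`` (V), ``event_time`` (T) and ``censor_time`` (C) are
    derived from the intervals; exactly one of T and C is present.
    """

    subject_id: object
    intervals: pd.DataFrame
    baseline: dict
    treatment_time: float | None
    event_time: float | None
    censor_time: float | None


@dataclasses.dataclass
class CohortDataset:
    """Validated cohort in counting-process form.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``id, start, stop, event, treated`` plus covariates; an
        optional ``tx`` column marks treatment initiation at the interval
        stop (required to represent V when ``followup_mode`` is
        ``stops_at_treatment``, derived from ``treated`` otherwise).
    covariate_roles : mapping
        covariate name -> ``"baseline"`` or ``"time_updated"``.
    followup_mode : str
        ``"stops_at_treatment"`` or ``"continues_after_treatment"``.
    event_precedence : bool
        Tie-break for an event and a treatment start recorded at the same
        time: if True (default) the event counts as occurring first (T < V).
    """

    df: pd.DataFrame
    covariate_roles: dict = dataclasses.field(default_factory=dict)
    followup_mode: str = CONTINUES_AFTER_TREATMENT
    event_precedence: bool = True

    def __post_init__(self) -> None:
        self.df = self.df.copy()
        if "tx" not in self.df.columns:
            self.df["tx"] = 0
        cols = list(REQUIRED_COLUMNS) + ["tx"] + self.covariate_names
        missing = [c for c in cols if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        self.df = (
            self.df[cols]
            .sort_values(["id", "start"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.df["start"] = self.df["start"].astype(float)
        self.df["stop"] = self.df["stop"].astype(float)
        self.df["event"] = self.df["event"].astype(int)
        self.df["treated"] = self.df["treated"].astype(int)
        self.df["tx"] = self.df["tx"].astype(int)
        self._derive_tx()
        self.validate()

    # -- schema ------------------------------------------------------------

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariate_roles)

    @property
    def baseline_covariates(self) -> list[str]:
        return [c for c, r in self.covariate_roles.items() if r == BASELINE]

    @property
    def time_updated_covariates(self) -> list[str]:
        return [c for c, r in self.covariate_roles.items() if r == TIME_UPDATED]

    @property
    def n_subjects(self) -> int:
        return self.df["id"].nunique()

    # -- construction helpers ---------------------------------------------

    def _derive_tx(self) -> None:
        """Fill the treatment-initiation indicator from the treated switch."""
        df = self.df
        if self.followup_mode == CONTINUES_AFTER_TREATMENT:
            g = df.groupby("id", sort=False)["treated"]
            first_treated = df["treated"].eq(1) & g.shift(1, fill_value=0).eq(0)
            prev_stop = df.groupby("id", sort=False)["stop"].shift(1)
            # initiation happens at the start of the first treated interval,
            # i.e. at the stop of the preceding (untreated) row
            mark = first_treated.shift(-1, fill_value=False) & df["id"].eq(
                df["id"].shift(-1)
            )
            df.loc[mark, "tx"] = 1
            # a subject whose very first interval is treated would have V=0;
            # disallowed (treatment strictly after baseline)
            first_row = ~df["id"].duplicated()
            if (df.loc[first_row, "treated"] == 1).any():
                bad = df.loc[first_row & df["treated"].eq(1), "id"].iloc[0]
                raise StructuralError(
                    f"subject {bad!r}: treated at baseline; treatment must start after 0"
                )
            del prev_stop

    def validate(self) -> None:
        df = self.df
        for col in ("start", "stop"):
            if not np.isfinite(df[col].to_numpy(float)).all():
                raise StructuralError(f"non-finite values in {col!r}")
        if (df["start"] < 0).any():
            raise StructuralError("negative start time")
        if (df["stop"] <= df["start"]).any():
            bad = df.loc[df["stop"] <= df["start"], "id"].iloc[0]
            raise StructuralError(f"subject {bad!r}: interval with stop <= start")
        if not df["event"].isin([0, 1]).all() or not df["treated"].isin([0, 1]).all():
            raise StructuralError("event and treated must be 0/1")

        same = df["id"].eq(df["id"].shift(1))
        prev_stop = df["stop"].shift(1)
        gap = same & ~np.isclose(df["start"], prev_stop, rtol=0.0, atol=1e-12)
        if gap.any():
            bad = df.loc[gap, "id"].iloc[0]
            if (df.loc[gap & df["id"].eq(bad), "start"] < prev_stop[gap & df["id"].eq(bad)]).any():
                raise StructuralError(f"subject {bad!r}: overlapping intervals")
            raise StructuralError(f"subject {bad!r}: non-contiguous intervals")
        first = ~df["id"].duplicated()
        if (df.loc[first, "start"] != 0).any():
            bad = df.loc[first & df["start"].ne(0), "id"].iloc[0]
            raise StructuralError(f"subject {bad!r}: first interval must start at 0")

        last = ~df["id"].duplicated(keep="last")
        if (df.loc[~last, "event"] == 1).any():
            bad = df.loc[~last & df["event"].eq(1), "id"].iloc[0]
            raise StructuralError(f"subject {bad!r}: event before the last interval")
        if (df.loc[~last, "tx"] == 1).any() and self.followup_mode == STOPS_AT_TREATMENT:
            bad = df.loc[~last & df["tx"].eq(1), "id"].iloc[0]
            raise StructuralError(f"subject {bad!r}: tx before the last interval")

        revert = same & df["treated"].lt(df["treated"].shift(1))
        if revert.any():
            bad = df.loc[revert, "id"].iloc[0]
            raise StructuralError(
                f"subject {bad!r}: treated reverting 1 -> 0 (treatment is absorbing)"
            )
        if self.followup_mode == STOPS_AT_TREATMENT and (df["treated"] == 1).any():
            bad = df.loc[df["treated"].eq(1), "id"].iloc[0]
            raise StructuralError(
                f"subject {bad!r}: treated person-time in a stops_at_treatment cohort"
            )

    # -- per-subject summaries ---------------------------------------------

    def subject_summary(self) -> pd.DataFrame:
        """One row per subject with V, T and C (NaN where absent)."""
        df = self.df
        last = df.loc[~df["id"].duplicated(keep="last")]
        out = pd.DataFrame({"id": last["id"].to_numpy()})
        out["event_time"] = np.where(last["event"] == 1, last["stop"], np.nan)
        out["censor_time"] = np.where(last["event"] == 0, last["stop"], np.nan)

        tx_rows = df.loc[df["tx"] == 1, ["id", "stop"]].rename(
            columns={"stop": "treatment_time"}
        )
        out = out.merge(tx_rows, on="id", how="left")
        # tie at T == V: under event precedence the event counts as first
        # recorded ties are exact equalities (both attach to the same stop)
        tie = out["event_time"].to_numpy(float) == out["treatment_time"].to_numpy(float)
        if self.event_precedence:
            out.loc[tie, "treatment_time"] = np.nan
        return out

    def subjects(self) -> Iterator[SubjectRecord]:
        summ = self.subject_summary().set_index("id")
        base = self.baseline_covariates
        for sid, g in self.df.groupby("id", sort=False):
            row = summ.loc[sid]
            yield SubjectRecord(
                subject_id=sid,
                intervals=g.reset_index(drop=True),
                baseline={c: g[c].iloc[0] for c in base},
                treatment_time=None if pd.isna(row["treatment_time"]) else float(row["treatment_time"]),
                event_time=None if pd.isna(row["event_time"]) else float(row["event_time"]),
                censor_time=None if pd.isna(row["censor_time"]) else float(row["censor_time"]),
            )

    def copy_with(self, df: pd.DataFrame, followup_mode: str | None = None) -> "CohortDataset":
        return CohortDataset(
            df=df,
            covariate_roles=dict(self.covariate_roles),
            followup_mode=followup_mode or self.followup_mode,
            event_precedence=self.event_precedence,
        )


# ---------------------------------------------------------------------------
# I/O


def read_schema(path) -> dict:
    with open(path) as fh:
        schema = yaml.safe_load(fh) or {}
    bad = {c: r for c, r in schema.items() if r not in (BASELINE, TIME_UPDATED)}
    if bad:
        raise SchemaError(f"invalid covariate role(s): {bad}")
    return schema


def read_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    followup_mode: str = CONTINUES_AFTER_TREATMENT,
    event_precedence: bool = True,
) -> CohortDataset:
    """Read a cohort CSV (columns ``id,start,stop,event,treated[,tx],<covariates>``).

    ``schema`` maps covariate name -> role (``baseline``/``time_updated``); a
    path to a YAML file with the same mapping is accepted.  Covariate columns
    not named in the schema are ignored.
    """
    if isinstance(schema, (str, bytes)) or hasattr(schema, "read"):
        schema = read_schema(schema)
    schema = dict(schema or {})
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    missing_cov = [c for c in schema if c not in df.columns]
    if missing_cov:
        raise SchemaError(f"schema names covariate(s) absent from data: {missing_cov}")
    return CohortDataset(
        df=df,
        covariate_roles=schema,
        followup_mode=followup_mode,
        event_precedence=event_precedence,
    )


def write_cohort(data: CohortDataset, path) -> None:
    """Write the canonical column set as CSV (UTF-8, '.' decimal)."""
    data.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Transformations


def split_intervals(df: pd.DataFrame, cut_times: Sequence[float]) -> pd.DataFrame:
    """Split rows of a counting-process frame at the given cut times.

    Works on any frame with ``start``/``stop``/``event`` (and optionally
    ``tx``) columns; indicator columns are carried only by the terminal
    sub-interval, every other column is copied to all pieces.
    """
    cuts = np.asarray(sorted(set(float(c) for c in cut_times)), dtype=float)
    if cuts.size and cuts[0] <= 0:
        raise ValueError("cut times must be positive")
    if not cuts.size:
        return df.copy()

    start = df["start"].to_numpy(float)
    stop = df["stop"].to_numpy(float)
    # cuts strictly inside (start, stop) split the row
    lo = np.searchsorted(cuts, start, side="right")
    hi = np.searchsorted(cuts, stop, side="left")
    n_pieces = (hi - lo) + 1
    rep = np.repeat(np.arange(len(df)), n_pieces)
    out = df.iloc[rep].reset_index(drop=True)

    piece = np.concatenate([np.arange(k) for k in n_pieces]) if len(df) else np.array([], int)
    inner = np.concatenate(
        [cuts[l:h] for l, h in zip(lo, hi)] if len(df) else [np.array([])]
    )
    # bounds of each output piece
    new_start = start[rep].copy()
    new_stop = stop[rep].copy()
    not_first = piece > 0
    not_last = piece < (n_pieces[rep] - 1)
    # inner cut k of a row is the stop of piece k and the start of piece k+1
    inner_idx = np.cumsum(n_pieces - 1) - (n_pieces - 1)
    cut_for_stop = np.zeros(len(out))
    cut_for_start = np.zeros(len(out))
    if inner.size:
        cut_for_stop[not_last] = inner[inner_idx[rep[not_last]] + piece[not_last]]
        cut_for_start[not_first] = inner[inner_idx[rep[not_first]] + piece[not_first] - 1]
    new_stop[not_last] = cut_for_stop[not_last]
    new_start[not_first] = cut_for_start[not_first]
    out["start"] = new_start
    out["stop"] = new_stop
    out.loc[not_last, "event"] = 0
    if "tx" in out.columns:
        out.loc[not_last, "tx"] = 0
    return out


def episode_split(data: CohortDataset, cut_times: Sequence[float]) -> CohortDataset:
    """Split every interval of a cohort crossing a cut time.

    The event (and tx) indicator is carried only by the terminal
    sub-interval; treated status, covariates and any extra columns (e.g.
    weights) are copied.  Splitting never changes any quantity fitted
    downstream, because the counting-process likelihood is invariant
    under it.
    """
    return data.copy_with(split_intervals(data.df, cut_times))


def stop_followup_at_treatment(data: CohortDataset) -> CohortDataset:
    """Discard post-treatment follow-up, yielding a stops_at_treatment cohort."""
    df = data.df
    keep = df["treated"] == 0
    out = df.loc[keep].copy()
    # death recorded after treatment is no longer observed in this design
    return data.copy_with(out, followup_mode=STOPS_AT_TREATMENT)


def fill_time_updated(data: CohortDataset) -> CohortDataset:
    """LOCF within subject, then cohort median, for time-updated covariates."""
    df = data.df.copy()
    for c in data.time_updated_covariates:
        df[c] = df.groupby("id", sort=False)[c].ffill()
        df[c] = df[c].fillna(df[c].median())
    return data.copy_with(df)


# ---------------------------------------------------------------------------
# Strategy views

IGNORE = "ignore"
COMPOSITE = "composite"
WHILE_UNTREATED = "while_untreated"
HYPOTHETICAL_CENSOR = "hypothetical_censor"


def apply_strategy_view(data: CohortDataset, strategy: str):
    """Transform the cohort into the outcome view a strategy estimates on.

    Returns a :class:`CohortDataset` for ``ignore``, ``composite`` and
    ``hypothetical_censor``; for ``while_untreated`` returns a dict with the
    two parallel cause views ``{"event": ..., "treatment": ...}`` (follow-up
    censored at the competing cause in each).
    """
    df = data.df
    if strategy == IGNORE:
        if data.followup_mode != CONTINUES_AFTER_TREATMENT:
            raise CapabilityError(
                "the ignore-treatment strategy requires continued follow-up "
                "after treatment initiation (not collected in this cohort)"
            )
        return data.copy_with(df.copy())

    # all remaining views live on untreated person-time
    untreated = df.loc[df["treated"] == 0].copy()
    last = ~untreated["id"].duplicated(keep="last")
    tx_here = (untreated["tx"] == 1) & last
    death_here = (untreated["event"] == 1) & last
    # tie T == V at the same stop: event precedence keeps the death
    if data.event_precedence:
        tx_here = tx_here & ~death_here

    if strategy == COMPOSITE:
        out = untreated
        out.loc[last, "event"] = (tx_here | death_here).loc[last].astype(int)
        out["tx"] = 0
        return data.copy_with(out, followup_mode=STOPS_AT_TREATMENT)

    if strategy == HYPOTHETICAL_CENSOR:
        out = untreated
        out.loc[tx_here, "event"] = 0
        out["tx"] = 0
        return data.copy_with(out, followup_mode=STOPS_AT_TREATMENT)

    if strategy == WHILE_UNTREATED:
        ev = untreated.copy()
        ev.loc[tx_here, "event"] = 0
        ev["tx"] = 0
        tr = untreated.copy()
        tr["event"] = tx_here.astype(int)
        tr["tx"] = 0
        return {
            "event": data.copy_with(ev, followup_mode=STOPS_AT_TREATMENT),
            "treatment": data.copy_with(tr, followup_mode=STOPS_AT_TREATMENT),
        }

    raise ValueError(f"unknown strategy view {strategy!r}")
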