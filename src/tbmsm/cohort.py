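"""Longitudinal cohort records and their discrete-time person-period expansion.

A cohort is carried as two tidy tables:

* a **baseline** table, one row per child — enrollment anchor, age, sex,
  WHO clinical stage and CD4 class at enrollment, and the descriptive
  cohort arm label (``haart`` / ``non_haart``);
* a **visits** table, one row per clinic encounter — months since
  enrollment, current HAART status, time-varying CD4 class, WHO stage,
  adherence, cotrimoxazole prophylaxis (CPT), follow-up status and the
  TB event flag.

Everything downstream (descriptive statistics, inverse-probability
weights, pooled logistic outcome models) consumes the **person-period**
expansion produced by :func:`build_person_period`: one row per child per
month at risk, with time-varying covariates carried forward from the
most recent visit and the event/censoring indicator set only on the
final row.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CohortError",
    "SchemaError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "build_person_period",
    "person_period_to_visits",
    "write_person_period",
    "BASELINE_COLUMNS",
    "VISIT_COLUMNS",
    "PERSON_PERIOD_COLUMNS",
]


class CohortError(ValueError):
    """Base class for cohort data problems."""


class SchemaError(CohortError):
    """A file does not conform to the documented CSV schema."""


class ValidationError(CohortError):
    """Parsed rows violate a cohort invariant (duplicates, ordering, referential)."""


BASELINE_COLUMNS = [
    "subject_id",
    "enrollment_date",
    "age_years",
    "sex",
    "who_stage",
    "cd4_class",
    "arm",
]

VISIT_COLUMNS = [
    "subject_id",
    "month",
    "on_haart",
    "cd4_class",
    "who_stage",
    "adherence",
    "cpt",
    "status",
    "tb_event",
]

PERSON_PERIOD_COLUMNS = [
    "subject_id",
    "t",
    "exposure",
    "on_haart",
    "months_on_haart",
    "age_years",
    "sex",
    "who_stage_baseline",
    "cd4_baseline",
    "arm",
    "cd4_class",
    "who_stage",
    "adherence",
    "cpt",
    "event",
    "censored",
]

SEX_LEVELS = {"male", "female"}
WHO_LEVELS = {"I", "II", "III", "IV"}
CD4_LEVELS = {"below_threshold", "above_threshold"}
ADHERENCE_LEVELS = {"good", "fair", "poor"}
STATUS_LEVELS = {"active", "lost", "died", "transferred_out"}
TERMINAL_STATUSES = {"lost", "died", "transferred_out"}
ARM_LEVELS = {"haart", "non_haart"}


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file is missing required column(s): {', '.join(missing)}")


def _check_levels(df, column, allowed, what, errors, allow_missing=False):
    vals = df[column]
    bad = ~vals.isin(allowed)
    if allow_missing:
        bad &= vals.notna() & (vals != "")
    else:
        bad |= vals.isna() | (vals == "")
    for idx in df.index[bad]:
        # +2: header line plus 0-based index
        errors.append(f"{what} line {idx + 2}: invalid {column} {vals.loc[idx]!r}")


def _parse_bool(series: pd.Series, allow_missing: bool = False) -> pd.Series:
    mapping = {"1": True, "0": False, "true": True, "false": False,
               "True": True, "False": False}
    out = series.map(mapping)
    if allow_missing:
        out = out.where(series.notna() & (series != ""), other=pd.NA)
    return out


def read_cohort(baseline_path, visits_path):
    """Read and validate a cohort from its two CSV files.

    Returns ``(subjects, visits)`` as typed DataFrames.  Raises
    :class:`SchemaError` naming the offending column or lines, or
    :class:`ValidationError` for duplicate / orphan subject ids and
    within-subject ordering violations.
    """
    baseline_path, visits_path = Path(baseline_path), Path(visits_path)
    subjects = pd.read_csv(baseline_path, dtype=str, keep_default_na=False,
                           na_values=[""])
    visits = pd.read_csv(visits_path, dtype=str, keep_default_na=False,
                         na_values=[""])
    _require_columns(subjects, BASELINE_COLUMNS, "baseline")
    _require_columns(visits, VISIT_COLUMNS, "visits")

    errors: list[str] = []
    _check_levels(subjects, "sex", SEX_LEVELS, "baseline", errors)
    _check_levels(subjects, "who_stage", WHO_LEVELS, "baseline", errors)
    _check_levels(subjects, "cd4_class", CD4_LEVELS, "baseline", errors)
    _check_levels(subjects, "arm", ARM_LEVELS, "baseline", errors)
    age = pd.to_numeric(subjects["age_years"], errors="coerce")
    for idx in subjects.index[age.isna() | (age < 0) | (age >= 15)]:
        errors.append(
            f"baseline line {idx + 2}: age_years {subjects['age_years'].loc[idx]!r} "
            "not a number in [0, 15)")

    month = pd.to_numeric(visits["month"], errors="coerce")
    for idx in visits.index[month.isna() | (month < 0)]:
        errors.append(f"visits line {idx + 2}: month {visits['month'].loc[idx]!r} "
                      "not a non-negative number")
    _check_levels(visits, "cd4_class", CD4_LEVELS, "visits", errors, allow_missing=True)
    _check_levels(visits, "who_stage", WHO_LEVELS, "visits", errors, allow_missing=True)
    _check_levels(visits, "adherence", ADHERENCE_LEVELS, "visits", errors, allow_missing=True)
    _check_levels(visits, "status", STATUS_LEVELS, "visits", errors)
    if errors:
        raise SchemaError("schema violations:\n" + "\n".join(errors))

    subjects = subjects.assign(age_years=age)
    visits = visits.assign(
        month=month,
        on_haart=_parse_bool(visits["on_haart"]).astype(bool),
        tb_event=_parse_bool(visits["tb_event"]).astype(bool),
        cpt=_parse_bool(visits["cpt"], allow_missing=True),
    )
    validate_cohort(subjects, visits)
    return subjects, visits


def validate_cohort(subjects: pd.DataFrame, visits: pd.DataFrame) -> None:
    """Check referential and within-subject ordering invariants."""
    dup = subjects["subject_id"][subjects["subject_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate subject_id in baseline: {sorted(set(dup))}")
    known = set(subjects["subject_id"])
    orphan = set(visits["subject_id"]) - known
    if orphan:
        raise ValidationError(f"visits reference unknown subject_id: {sorted(orphan)[:10]}")

    v = visits.sort_index()
    by = v.groupby("subject_id", sort=False)
    if (by["month"].diff().dropna() < 0).any():
        raise ValidationError("months_since_enrollment decreases within a subject")
    if (by["tb_event"].sum() > 1).any():
        raise ValidationError("a subject has more than one tb_event visit")
    # no visit after the first event or after a terminal follow-up status
    terminal = v["tb_event"] | v["status"].isin(TERMINAL_STATUSES)
    after_terminal = by.apply(
        lambda g: bool(terminal.loc[g.index].shift(fill_value=False).cumsum().astype(bool)
                       .any()), include_groups=False)
    if after_terminal.any():
        bad = after_terminal[after_terminal].index.tolist()
        raise ValidationError(f"visits recorded after a terminal visit for: {bad[:10]}")


def write_cohort(subjects: pd.DataFrame, visits: pd.DataFrame,
                 baseline_path, visits_path) -> None:
    """Serialize a cohort back to the canonical CSV schemas (booleans as 0/1)."""
    s = subjects.loc[:, BASELINE_COLUMNS].copy()
    v = visits.loc[:, VISIT_COLUMNS].copy()
    for col in ("on_haart", "tb_event", "cpt"):
        v[col] = v[col].map(lambda x: "" if pd.isna(x) else str(int(bool(x))))
    s.to_csv(baseline_path, index=False)
    v.to_csv(visits_path, index=False)


def _locf(grid: pd.DataFrame, visits: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Merge visit covariates onto the interval grid, last observation carried forward."""
    right = visits[["subject_id", "month", *columns]].sort_values(
        "month", kind="stable")
    merged = pd.merge_asof(
        grid.sort_values("start", kind="stable"),
        right,
        by="subject_id", left_on="start", right_on="month",
        direction="backward", allow_exact_matches=True,
    )
    merged = merged.sort_values(["subject_id", "t"], kind="stable",
                                ignore_index=True)
    return merged.drop(columns=["month"])


def build_person_period(subjects: pd.DataFrame, visits: pd.DataFrame,
                        interval_width_months: float = 1.0,
                        exposure_lag_months: float = 2.0) -> pd.DataFrame:
    """Expand a validated cohort into one row per child per interval at risk.

    Intervals are half-open ``[t*w, (t+1)*w)`` in months since enrollment.
    A child contributes rows ``t = 0 .. T`` where ``T`` is the interval
    containing the final visit (TB event, censoring, or administrative
    end).  The ``exposure`` column implements the "on HAART for at least
    `exposure_lag_months` months by the start of the interval" definition
    and is absorbing; ``on_haart`` is the raw carried-forward treatment
    status (the initiation process the weight models describe).

    Time-varying covariates are last-observation-carried-forward; CD4 and
    WHO stage fall back to the baseline value when unobserved at t=0 and
    to an explicit ``"missing"`` level thereafter.  ``event`` is set only
    on the final row of a child whose last visit records TB; ``censored``
    marks informative censoring (lost, died, transferred out).  When a
    final visit records both, the event wins.
    """
    if interval_width_months <= 0:
        raise ValueError("interval_width_months must be positive")
    if exposure_lag_months < 0:
        raise ValueError("exposure_lag_months must be non-negative")
    w = float(interval_width_months)

    v = visits.sort_values(["subject_id", "month"], kind="stable")
    last = v.groupby("subject_id", sort=False).tail(1).set_index("subject_id")

    ids = subjects["subject_id"]
    no_followup = ~ids.isin(last.index)
    if no_followup.any():
        dropped = ids[no_followup].tolist()
        logger.warning("excluding %d subject(s) with zero follow-up: %s",
                       len(dropped), dropped[:10])
    kept = subjects.loc[~no_followup].set_index("subject_id")

    last = last.loc[kept.index]
    n_rows = (np.floor(last["month"].to_numpy() / w)).astype(int) + 1
    terminal_event = last["tb_event"].to_numpy()
    terminal_cens = last["status"].isin(TERMINAL_STATUSES).to_numpy()
    both = terminal_event & terminal_cens
    if both.any():
        logger.warning("event and terminal censoring in the same interval for "
                       "%d subject(s); event takes precedence", int(both.sum()))
    terminal_cens &= ~terminal_event

    grid = pd.DataFrame({
        "subject_id": np.repeat(kept.index.to_numpy(), n_rows),
        "t": np.concatenate([np.arange(n) for n in n_rows]),
    })
    grid["start"] = grid["t"] * w

    pp = _locf(grid, v, ["on_haart", "cd4_class", "who_stage", "adherence", "cpt"])
    pp["on_haart"] = pp["on_haart"].fillna(False).astype(bool)

    base = kept.loc[pp["subject_id"]]
    pp["age_years"] = base["age_years"].to_numpy()
    pp["sex"] = base["sex"].to_numpy()
    pp["who_stage_baseline"] = base["who_stage"].to_numpy()
    pp["cd4_baseline"] = base["cd4_class"].to_numpy()
    pp["arm"] = base["arm"].to_numpy()

    pp["cd4_class"] = pp["cd4_class"].fillna(pp["cd4_baseline"])
    pp["who_stage"] = pp["who_stage"].fillna(pp["who_stage_baseline"])
    pp["adherence"] = pp["adherence"].fillna("missing")
    pp["cpt"] = pp["cpt"].map(lambda x: "missing" if pd.isna(x) else str(bool(x)))

    # exposure: >= lag months accrued on HAART by the interval start, absorbing
    init_month = (v[v["on_haart"]].groupby("subject_id", sort=False)["month"].min()
                  .reindex(kept.index))
    m0 = init_month.loc[pp["subject_id"]].to_numpy(dtype=float)
    accrued = pp["start"].to_numpy() - m0
    accrued = np.where(np.isnan(accrued), -np.inf, accrued)
    pp["months_on_haart"] = np.maximum(accrued, 0.0)
    pp["exposure"] = accrued >= exposure_lag_months

    is_last = (pp["t"] == pp.groupby("subject_id", sort=False)["t"]
               .transform("max")).to_numpy()
    ev = pd.Series(terminal_event, index=kept.index).loc[pp["subject_id"]].to_numpy()
    ce = pd.Series(terminal_cens, index=kept.index).loc[pp["subject_id"]].to_numpy()
    pp["event"] = is_last & ev
    pp["censored"] = is_last & ce

    return pp.drop(columns=["start"]).loc[:, PERSON_PERIOD_COLUMNS].reset_index(drop=True)


def person_period_to_visits(pp: pd.DataFrame,
                            interval_width_months: float = 1.0) -> pd.DataFrame:
    """Collapse a person-period table back into the visits schema.

    Emits one visit per interval carrying the carried-forward covariate
    values, with the terminal status / TB flag on the final row.  Feeding
    the result back through :func:`build_person_period` reproduces the
    table (expansion is idempotent on its own collapsed form).
    """
    v = pp.copy()
    v["month"] = v["t"] * float(interval_width_months)
    v["status"] = np.where(v["censored"], "lost", "active")
    v["tb_event"] = v["event"]
    v["cpt"] = v["cpt"].map({"True": True, "False": False}).astype(object)
    for col in ("cd4_class", "who_stage"):
        v[col] = v[col].replace("missing", pd.NA)
    v["adherence"] = v["adherence"].replace("missing", pd.NA)
    return v.loc[:, VISIT_COLUMNS].reset_index(drop=True)


def write_person_period(pp: pd.DataFrame, path) -> None:
    """Write the person-period table (audit copy) in the documented column order."""
    pp.loc[:, PERSON_PERIOD_COLUMNS].to_csv(path, index=False)
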