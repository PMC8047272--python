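"""Descriptive layer: person-time incidence, survival curves, simple tests.

Incidence rates are expressed per 100 child-years with confidence limits
from Byar's cube-root normal approximation to the Poisson tails — the
method behind the person-time rate calculators used in field
epidemiology, which reproduces their printed limits to three decimals.
An exact mid-P interval is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import optimize, stats

__all__ = [
    "IncidenceEstimate", "TestResult", "incidence_rate", "km_curve",
    "logrank_test", "chi_square_test", "mann_whitney_test",
    "cohort_table", "row_percentages", "subject_survival",
]


@dataclass
class IncidenceEstimate:
    events: int
    person_time: float           # child-years
    rate_per_100cy: float
    ci_low: float
    ci_high: float
    ci_method: str = "byar"
    confidence_level: float = 0.95


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    df: int | None = None
    n1: int | None = None
    n2: int | None = None


def _byar_limits(d: int, level: float) -> tuple[float, float]:
    """Byar's approximation to the Poisson count confidence limits."""
    z = stats.norm.ppf(1 - (1 - level) / 2)
    if d == 0:
        low = 0.0
    else:
        low = d * (1 - 1 / (9 * d) - z / (3 * np.sqrt(d))) ** 3
    dh = d + 1
    high = dh * (1 - 1 / (9 * dh) + z / (3 * np.sqrt(dh))) ** 3
    return low, high


def _midp_limits(d: int, level: float) -> tuple[float, float]:
    """Exact mid-P Poisson limits by root finding on the mid-P tail."""
    alpha = (1 - level) / 2

    def lower_tail(mu):  # P(X < d) + 0.5 P(X = d) under Poisson(mu)
        return stats.poisson.cdf(d - 1, mu) + 0.5 * stats.poisson.pmf(d, mu)

    def upper_tail(mu):  # P(X > d) + 0.5 P(X = d)
        return stats.poisson.sf(d, mu) + 0.5 * stats.poisson.pmf(d, mu)

    # upper limit: mu large enough that observing <= d is improbable
    hi = optimize.brentq(lambda mu: lower_tail(mu) - alpha, max(d, 1e-8),
                         10 * d + 50)
    # lower limit: mu small enough that observing >= d is improbable
    lo = 0.0 if d == 0 else optimize.brentq(lambda mu: upper_tail(mu) - alpha,
                                            1e-12, max(d, 1.0) * 2)
    return lo, hi


def incidence_rate(events: int, person_time: float, level: float = 0.95,
                   method: str = "byar") -> IncidenceEstimate:
    """Person-time incidence per 100 child-years with Poisson CI.

    ``person_time`` is in child-years.  ``method`` is ``"byar"``
    (default) or ``"midp"``.
    """
    if person_time <= 0:
        raise ValueError("person_time must be positive")
    if events < 0:
        raise ValueError("events must be non-negative")
    limits = {"byar": _byar_limits, "midp": _midp_limits}
    if method not in limits:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = limits[method](int(events), level)
    scale = 100.0 / person_time
    return IncidenceEstimate(
        events=int(events), person_time=float(person_time),
        rate_per_100cy=events * scale, ci_low=lo * scale, ci_high=hi * scale,
        ci_method=method, confidence_level=level)


def subject_survival(pp: pd.DataFrame) -> pd.DataFrame:
    """Collapse a person-period table to one row per subject.

    ``time`` is the number of intervals survived (event or censoring in
    interval ``t`` gives ``time = t + 1``); ``event`` flags observed TB.
    Baseline covariates and the arm label are carried along for grouped
    survival analyses and Cox screening.
    """
    last = pp.sort_values(["subject_id", "t"], kind="stable") \
             .groupby("subject_id", sort=False).tail(1)
    out = last[["subject_id", "age_years", "sex", "who_stage_baseline",
                "cd4_baseline", "arm", "event"]].copy()
    out["time"] = last["t"].to_numpy() + 1
    return out.reset_index(drop=True)


def km_curve(pp: pd.DataFrame, group: str = "arm") -> pd.DataFrame:
    """Kaplan-Meier TB-free survival per group.

    Returns a tidy table (group, time, survival, at_risk) over the
    observed interval endpoints.
    """
    surv = subject_survival(pp)
    frames = []
    for label, g in surv.groupby(group, sort=True):
        if len(g) == 0:
            raise ValueError(f"empty group {label!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(g["time"], event_observed=g["event"])
        times = kmf.survival_function_.index.to_numpy()
        at_risk = np.array([(g["time"] >= max(t, 1e-12)).sum() for t in times])
        frames.append(pd.DataFrame({
            "group": label, "time": times,
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "at_risk": at_risk}))
    if not frames:
        raise ValueError("no groups present")
    return pd.concat(frames, ignore_index=True)


def logrank_test(pp: pd.DataFrame, group: str = "arm") -> TestResult:
    """Two-group log-rank test on TB-free survival (df = 1)."""
    surv = subject_survival(pp)
    labels = sorted(surv[group].unique())
    if len(labels) != 2:
        raise ValueError(f"log-rank test requires exactly two groups, got {labels}")
    a = surv[surv[group] == labels[0]]
    b = surv[surv[group] == labels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("one group is empty")
    res = _ll_logrank(a["time"], b["time"], event_observed_A=a["event"],
                      event_observed_B=b["event"])
    return TestResult(statistic=float(res.test_statistic),
                      p_value=float(res.p_value), test_name="logrank", df=1,
                      n1=len(a), n2=len(b))


def chi_square_test(table, yates: bool = False) -> TestResult:
    """Pearson chi-square on a two-way contingency table of counts."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a row or column margin is zero")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=yates)
    return TestResult(statistic=float(chi2), p_value=float(p),
                      test_name="chi_square", df=int(dof))


def mann_whitney_test(sample_a, sample_b) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    Uses the exact null distribution when both samples are small and
    tie-free, otherwise the normal approximation with tie correction.
    The reported U is for ``sample_a``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      test_name="mann_whitney", n1=len(a), n2=len(b))


AGE_BAND_LABELS = ["<1", "1-3", "3-5", "5-15"]
AGE_BAND_EDGES = [0.0, 1.0, 3.0, 5.0, 15.0]


def row_percentages(counts: pd.DataFrame,
                    no_col: str = "tb_no", yes_col: str = "tb_yes") -> pd.DataFrame:
    """Append within-row percentages to a (TB no, TB yes) counts table.

    Percentages are computed within each covariate level (per arm):
    ``pct_no = 100 * no / (no + yes)``, and zero totals give 0/0 -> 0.
    """
    out = counts.copy()
    total = out[no_col] + out[yes_col]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["pct_no"] = np.where(total > 0, 100.0 * out[no_col] / total, 0.0)
        out["pct_yes"] = np.where(total > 0, 100.0 * out[yes_col] / total, 0.0)
    return out


def cohort_table(subjects: pd.DataFrame, pp: pd.DataFrame) -> pd.DataFrame:
    """Baseline-characteristics summary split by arm and TB status.

    One row per (characteristic, category, arm) with TB no / TB yes
    counts and within-row percentages — the layout of a standard cohort
    Table 1 stratified on the exposure arm.
    """
    surv = subject_survival(pp)
    df = surv.copy()
    df["age_band"] = pd.cut(df["age_years"], AGE_BAND_EDGES, right=False,
                            labels=AGE_BAND_LABELS, include_lowest=True)

    characteristics = {
        "age": ("age_band", AGE_BAND_LABELS),
        "sex": ("sex", ["male", "female"]),
        "who_stage": ("who_stage_baseline", ["I", "II", "III", "IV"]),
        "cd4": ("cd4_baseline", ["below_threshold", "above_threshold"]),
    }
    arms = ["non_haart", "haart"]
    rows = []
    for char, (col, levels) in characteristics.items():
        for level in levels:
            for arm in arms:
                sub = df[(df[col] == level) & (df["arm"] == arm)]
                rows.append({
                    "characteristic": char, "category": level, "arm": arm,
                    "tb_no": int((~sub["event"]).sum()),
                    "tb_yes": int(sub["event"].sum()),
                })
    return row_percentages(pd.DataFrame(rows))
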