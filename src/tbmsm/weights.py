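"""Stabilized inverse-probability-of-treatment-and-censoring (IPTC) weights.

Treatment in this setting is an absorbing initiation process: each month
an untreated child either starts therapy or does not, and the weight
models describe that discrete initiation hazard with pooled logistic
regressions.  The stabilized treatment weight for a child-month ``t`` is
the cumulative product over months ``k <= t`` of

    P(observed action at k | baseline, time) /
    P(observed action at k | baseline, time, time-varying history),

with factors fixed at 1 once therapy has started.  Censoring weights are
built the same way from models for remaining uncensored, and the total
weight is their product.  With correctly specified denominators the
weighted person-period table behaves like a sequentially randomized,
censoring-free pseudo-population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .timebasis import time_basis

logger = logging.getLogger(__name__)

__all__ = [
    "WeightModelSpec", "FittedProcessModel", "fit_treatment_model",
    "fit_censoring_model", "stabilized_weights", "weight_diagnostics",
    "BASELINE_COVARIATES", "TIME_VARYING_COVARIATES",
    "SeparationError", "PositivityError",
]

BASELINE_COVARIATES = ["age_years", "sex", "who_stage_baseline", "cd4_baseline"]
TIME_VARYING_COVARIATES = ["cd4_class", "who_stage", "adherence", "cpt"]

# fixed category orderings; first level is the reference
CATEGORY_LEVELS = {
    "sex": ["male", "female"],
    "who_stage_baseline": ["I", "II", "III", "IV"],
    "cd4_baseline": ["above_threshold", "below_threshold"],
    "cd4_class": ["above_threshold", "below_threshold", "missing"],
    "who_stage": ["I", "II", "III", "IV", "missing"],
    "adherence": ["good", "fair", "poor", "missing"],
    "cpt": ["False", "True", "missing"],
}


class SeparationError(RuntimeError):
    """A weight model is completely separated on some covariate."""


class PositivityError(RuntimeError):
    """A denominator probability of zero makes a weight undefined."""


@dataclass
class WeightModelSpec:
    """Covariate specification for a treatment or censoring process model."""

    numerator_covariates: list = field(default_factory=lambda: list(BASELINE_COVARIATES))
    denominator_covariates: list = field(
        default_factory=lambda: list(BASELINE_COVARIATES) + list(TIME_VARYING_COVARIATES))
    time_kind: str = "spline"
    time_df: int = 4

    def validate(self) -> None:
        extra = set(self.numerator_covariates) - set(self.denominator_covariates)
        if extra:
            raise ValueError(
                "numerator covariates must be a subset of denominator "
                f"covariates; extra: {sorted(extra)}")


def design_matrix(pp: pd.DataFrame, covariates, tb: np.ndarray):
    """Intercept + covariate columns + time basis, with stable dummy coding.

    Numeric columns pass through; known categoricals are one-hot encoded
    against :data:`CATEGORY_LEVELS` with the first level as reference.
    All-zero dummy columns (levels absent from the data) are dropped.
    """
    cols, names = [np.ones(len(pp))], ["intercept"]
    for cov in covariates:
        s = pp[cov]
        if cov in CATEGORY_LEVELS:
            for level in CATEGORY_LEVELS[cov][1:]:
                col = (s.astype(str) == level).to_numpy(dtype=float)
                if col.any():
                    cols.append(col)
                    names.append(f"{cov}[{level}]")
        elif pd.api.types.is_bool_dtype(s):
            cols.append(s.to_numpy(dtype=float))
            names.append(cov)
        elif pd.api.types.is_numeric_dtype(s):
            cols.append(s.to_numpy(dtype=float))
            names.append(cov)
        else:  # unknown categorical: levels from the data, first as reference
            levels = sorted(s.astype(str).unique())
            for level in levels[1:]:
                cols.append((s.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{cov}[{level}]")
    for j in range(tb.shape[1]):
        cols.append(np.asarray(tb)[:, j])
        names.append(f"time_{j+1}")
    return np.column_stack(cols), names


def _fit_logistic(y, X, names, what):
    if y.sum() == 0:
        raise ValueError(f"no events to fit the {what} model")
    with np.errstate(all="ignore"):
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    # complete separation: the model predicts every outcome perfectly and
    # the MLE does not exist (quasi-separation on a rare level is benign —
    # the runaway cancels between numerator and denominator weights)
    mu = res.predict(X)
    if np.abs(y - mu).max() < 1e-6:
        offender = names[1:][int(np.argmax(np.abs(res.params[1:])))]
        raise SeparationError(f"complete separation in the {what} model "
                              f"on covariate {offender!r}")
    return res


@dataclass
class FittedProcessModel:
    """Numerator/denominator pooled logistic fits for one weight process.

    ``p_num`` / ``p_den`` are aligned with the person-period table and
    hold, per row, the predicted probability of the *observed* outcome of
    the process (the observed treatment action, or remaining
    uncensored); rows outside the process risk set carry probability 1.
    """

    process: str
    p_num: np.ndarray
    p_den: np.ndarray
    num_result: object | None = None
    den_result: object | None = None
    num_names: list | None = None
    den_names: list | None = None

    def coefficient_table(self, which: str = "den") -> pd.DataFrame:
        res = self.den_result if which == "den" else self.num_result
        names = self.den_names if which == "den" else self.num_names
        if res is None:
            return pd.DataFrame(columns=["coef", "se"])
        return pd.DataFrame({"coef": res.params, "se": res.bse}, index=names)


def _initiation_risk_set(pp: pd.DataFrame) -> pd.Series:
    """True for rows where the subject is still untreated at interval start."""
    started_before = (pp.groupby("subject_id", sort=False)["on_haart"]
                      .transform(lambda s: s.shift(fill_value=False).cummax()))
    return ~started_before


def fit_treatment_model(pp: pd.DataFrame,
                        spec: WeightModelSpec | None = None) -> FittedProcessModel:
    """Fit the HAART-initiation hazard models (numerator and denominator).

    Rows are restricted to child-months still untreated at the interval
    start; the modelled outcome is initiation during the interval.
    """
    spec = spec or WeightModelSpec()
    spec.validate()
    risk = _initiation_risk_set(pp)
    sub = pp.loc[risk]
    y = sub["on_haart"].to_numpy(dtype=float)
    if y.sum() == 0:
        raise ValueError("zero treatment initiations: cannot fit the treatment model")

    tb = time_basis(sub["t"].to_numpy(), kind=spec.time_kind, df=spec.time_df)
    Xd, dnames = design_matrix(sub, spec.denominator_covariates, tb)
    Xn, nnames = design_matrix(sub, spec.numerator_covariates, tb)
    den = _fit_logistic(y, Xd, dnames, "treatment denominator")
    num = _fit_logistic(y, Xn, nnames, "treatment numerator")

    p_num = np.ones(len(pp))
    p_den = np.ones(len(pp))
    mu_d, mu_n = den.predict(Xd), num.predict(Xn)
    obs_d = np.where(y == 1, mu_d, 1 - mu_d)
    obs_n = np.where(y == 1, mu_n, 1 - mu_n)
    p_den[risk.to_numpy()] = obs_d
    p_num[risk.to_numpy()] = obs_n
    return FittedProcessModel("treatment", p_num, p_den, num, den, nnames, dnames)


def fit_censoring_model(pp: pd.DataFrame,
                        spec: WeightModelSpec | None = None) -> FittedProcessModel:
    """Fit the censoring hazard models and return uncensored probabilities.

    All dropout causes (lost, died, transferred out) are pooled into one
    censoring indicator.  Current exposure is always included (numerator
    and denominator); the denominator adds the time-varying covariates.
    With no censoring events all probabilities are 1.
    """
    spec = spec or WeightModelSpec()
    spec.validate()
    y = pp["censored"].to_numpy(dtype=float)
    if y.sum() == 0:
        logger.info("no censoring events; censoring weights are identically 1")
        ones = np.ones(len(pp))
        return FittedProcessModel("censoring", ones, ones.copy())

    tb = time_basis(pp["t"].to_numpy(), kind=spec.time_kind, df=spec.time_df)
    num_cov = list(spec.numerator_covariates) + ["exposure"]
    den_cov = list(spec.denominator_covariates) + ["exposure"]
    Xd, dnames = design_matrix(pp, den_cov, tb)
    Xn, nnames = design_matrix(pp, num_cov, tb)
    den = _fit_logistic(y, Xd, dnames, "censoring denominator")
    num = _fit_logistic(y, Xn, nnames, "censoring numerator")
    # probability of remaining uncensored through the interval
    p_den = 1 - den.predict(Xd)
    p_num = 1 - num.predict(Xn)
    return FittedProcessModel("censoring", p_num, p_den, num, den, nnames, dnames)


def stabilized_weights(pp: pd.DataFrame,
                       treatment: FittedProcessModel | None,
                       censoring: FittedProcessModel | None = None,
                       truncation: tuple | None = None) -> pd.DataFrame:
    """Cumulative stabilized weights per person-period row.

    Returns a table aligned with ``pp`` carrying the per-interval
    numerator/denominator probabilities, the cumulative ``sw_treat`` and
    ``sw_cens``, and their product ``sw_total``.  ``truncation``, when
    given as a percentile pair such as ``(1, 99)``, clips ``sw_total`` at
    those percentiles of its own distribution.
    """
    n = len(pp)
    out = pd.DataFrame({"subject_id": pp["subject_id"].to_numpy(),
                        "t": pp["t"].to_numpy()})
    for model, stem in ((treatment, "treat"), (censoring, "cens")):
        if model is None:
            out[f"p_num_{stem}"] = 1.0
            out[f"p_den_{stem}"] = 1.0
        else:
            if (model.p_den <= 0).any():
                bad = np.nonzero(model.p_den <= 0)[0]
                raise PositivityError(
                    f"{model.process} denominator probability is 0 for rows "
                    f"{bad[:10].tolist()}")
            out[f"p_num_{stem}"] = model.p_num
            out[f"p_den_{stem}"] = model.p_den
    out["sw_treat"] = (out["p_num_treat"] / out["p_den_treat"]).groupby(
        out["subject_id"], sort=False).cumprod()
    out["sw_cens"] = (out["p_num_cens"] / out["p_den_cens"]).groupby(
        out["subject_id"], sort=False).cumprod()
    out["sw_total"] = out["sw_treat"] * out["sw_cens"]
    if truncation is not None:
        lo, hi = np.percentile(out["sw_total"], truncation)
        out["sw_total"] = out["sw_total"].clip(lo, hi)
        out.attrs["truncation"] = tuple(truncation)
    return out


def weight_diagnostics(weights: pd.DataFrame, tolerance: float = 0.1,
                       min_at_risk: int = 50) -> dict:
    """Distributional summary of the total stabilized weights.

    Reports overall mean / SD / extremes / percentiles and per-interval
    means for intervals with at least ``min_at_risk`` subjects; warns
    when the overall mean strays from 1 by more than ``tolerance``.
    """
    w = weights["sw_total"]
    pct = np.percentile(w, [1, 5, 25, 50, 75, 95, 99])
    by_t = weights.groupby("t")["sw_total"].agg(["mean", "size"])
    per_interval = by_t[by_t["size"] >= min_at_risk]["mean"]
    summary = {
        "mean": float(w.mean()), "sd": float(w.std()),
        "min": float(w.min()), "max": float(w.max()),
        "percentiles": dict(zip([1, 5, 25, 50, 75, 95, 99], map(float, pct))),
        "per_interval_mean": per_interval,
    }
    if abs(summary["mean"] - 1) > tolerance:
        logger.warning("mean stabilized weight %.3f deviates from 1 by more "
                       "than %.2f", summary["mean"], tolerance)
    return summary
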