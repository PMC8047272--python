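"""Marginal structural Cox model estimation via weighted pooled logistic fits.

With monthly event probabilities of well under 5%, the per-interval
event odds from a pooled logistic regression approximate a proportional
hazards model, so the exponentiated exposure coefficient from a
stabilized-IPTC-weighted pooled logistic fit estimates the marginal
structural Cox hazard ratio.  Variances treat the weights as fixed and
come from a subject-clustered sandwich; a subject-level bootstrap that
refits the weights per replicate is available as a cross-check.

The five-model estimation ladder reproduces the usual presentation of
such analyses: a crude fit, a baseline-adjusted fit, and three weighted
fits of increasing rigour (baseline-propensity weights, time-varying
treatment weights, total treatment-and-censoring weights).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

from .timebasis import time_basis
from .weights import (BASELINE_COVARIATES, TIME_VARYING_COVARIATES,
                      WeightModelSpec, design_matrix, fit_censoring_model,
                      fit_treatment_model, stabilized_weights)

logger = logging.getLogger(__name__)

__all__ = ["ModelFit", "fit_pooled_logistic_msm", "model_ladder",
           "cox_screening", "bootstrap_ci", "LADDER_LABELS"]

LADDER_LABELS = ["unweighted_unadjusted", "unweighted_adjusted",
                 "baseline_weighted", "time_varying_weighted", "total_weighted"]


@dataclass
class ModelFit:
    """A fitted hazard-ratio contrast for current exposure."""

    label: str
    log_hr: float
    hr: float
    se_robust: float
    ci_low: float
    ci_high: float
    p_value: float
    n_subjects: int
    n_rows: int
    n_events: int

    def to_row(self) -> dict:
        return {"model": self.label, "hr": self.hr, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "p_value": self.p_value,
                "n_events": self.n_events}


def fit_pooled_logistic_msm(pp: pd.DataFrame,
                            weights: pd.DataFrame | np.ndarray | None = None,
                            adjust_baseline: bool = False,
                            label: str = "msm",
                            time_kind: str = "spline",
                            time_df: int = 4,
                            level: float = 0.95) -> ModelFit:
    """Weighted pooled logistic regression of the TB event on exposure.

    The model is ``logit P(Y_t = 1) = b0 + psi*A_t + s(t) (+ V)`` fitted
    on person-period rows that remain uncensored through their interval
    (terminally censored rows are removed; with IPTC weights they are
    re-represented by the weighting).  ``weights`` may be a weight table
    from :func:`tbmsm.weights.stabilized_weights` (its ``sw_total``
    column is used) or a bare array aligned with ``pp``; ``None`` means
    unweighted.  Standard errors are subject-clustered sandwich
    estimates.
    """
    keep = ~pp["censored"].to_numpy(dtype=bool)
    if isinstance(weights, pd.DataFrame):
        w = weights["sw_total"].to_numpy(dtype=float)
    elif weights is None:
        w = np.ones(len(pp))
    else:
        w = np.asarray(weights, dtype=float)
    if len(w) != len(pp):
        raise ValueError("weights must align with the person-period table")
    sub, w = pp.loc[keep], w[keep]

    y = sub["event"].to_numpy(dtype=float)
    if y.sum() == 0:
        raise ValueError("zero events: cannot fit the outcome model")
    tb = time_basis(sub["t"].to_numpy(), kind=time_kind, df=time_df)
    covs = list(BASELINE_COVARIATES) if adjust_baseline else []
    Xc, names = design_matrix(sub, covs, tb)
    X = np.column_stack([Xc[:, :1], sub["exposure"].to_numpy(dtype=float),
                         Xc[:, 1:]])
    names = [names[0], "exposure", *names[1:]]

    with warnings.catch_warnings():
        # statsmodels flags cov_type with var_weights; for fixed IPW weights
        # the clustered sandwich it computes is the standard MSM variance
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit(
            cov_type="cluster",
            cov_kwds={"groups": pd.factorize(sub["subject_id"])[0]},
            maxiter=200)
    if not res.converged:
        raise RuntimeError(f"outcome model did not converge for {label!r}; "
                           "see statsmodels iteration history")
    log_hr = float(res.params[1])
    se = float(res.bse[1])
    z = stats.norm.ppf(1 - (1 - level) / 2)
    p = 2 * stats.norm.sf(abs(log_hr) / se)
    return ModelFit(
        label=label, log_hr=log_hr, hr=float(np.exp(log_hr)), se_robust=se,
        ci_low=float(np.exp(log_hr - z * se)), ci_high=float(np.exp(log_hr + z * se)),
        p_value=float(p), n_subjects=sub["subject_id"].nunique(),
        n_rows=len(sub), n_events=int(y.sum()))


def ladder_weight_sets(pp: pd.DataFrame, spec: WeightModelSpec | None = None,
                       truncation: tuple | None = None) -> dict:
    """The three weight tables the estimation ladder needs.

    * ``baseline``: propensity weights from a baseline-covariates-only
      initiation model, stabilized by the marginal (time-only) hazard;
    * ``time_varying``: stabilized treatment weights whose denominator
      adds the time-varying covariates;
    * ``total``: the time-varying treatment weights multiplied by
      stabilized censoring weights.
    """
    spec = spec or WeightModelSpec()
    base_spec = WeightModelSpec(numerator_covariates=[],
                                denominator_covariates=list(BASELINE_COVARIATES),
                                time_kind=spec.time_kind, time_df=spec.time_df)
    tm_base = fit_treatment_model(pp, base_spec)
    tm_tv = fit_treatment_model(pp, spec)
    cm = fit_censoring_model(pp, spec)
    return {
        "baseline": stabilized_weights(pp, tm_base, None, truncation),
        "time_varying": stabilized_weights(pp, tm_tv, None, truncation),
        "total": stabilized_weights(pp, tm_tv, cm, truncation),
        "models": {"treatment_baseline": tm_base, "treatment": tm_tv,
                   "censoring": cm},
    }


def model_ladder(pp: pd.DataFrame, weight_sets: dict | None = None,
                 spec: WeightModelSpec | None = None,
                 truncation: tuple | None = None,
                 time_kind: str = "spline", time_df: int = 4,
                 strict: bool = True) -> dict:
    """Fit the five-model estimation ladder.

    Returns an ordered dict ``label -> ModelFit``: crude, baseline
    adjusted, baseline weighted, time-varying treatment weighted, and
    total (treatment x censoring) weighted.  With ``strict=False``
    (degenerate inputs — a toy cohort with no initiations, say) failing
    fits are skipped with a warning instead of raised.
    """
    if weight_sets is None:
        try:
            weight_sets = ladder_weight_sets(pp, spec, truncation)
        except (ValueError, RuntimeError):
            if strict:
                raise
            logger.warning("weight fitting failed; weighted ladder rows skipped",
                           exc_info=True)
            weight_sets = {}
    kw = dict(time_kind=time_kind, time_df=time_df)
    plan = [
        ("unweighted_unadjusted", None, False),
        ("unweighted_adjusted", None, True),
        ("baseline_weighted", "baseline", False),
        ("time_varying_weighted", "time_varying", True),
        ("total_weighted", "total", True),
    ]
    fits = {}
    for label, wkey, adjust in plan:
        if wkey is not None and wkey not in weight_sets:
            continue
        w = weight_sets[wkey] if wkey is not None else None
        try:
            fits[label] = fit_pooled_logistic_msm(
                pp, w, adjust_baseline=adjust, label=label, **kw)
        except (ValueError, RuntimeError):
            if strict:
                raise
            logger.warning("ladder fit %r failed on degenerate input; skipped",
                           label, exc_info=True)
    return fits


def ladder_table(fits: dict) -> pd.DataFrame:
    """Ladder results as a tidy table (model, HR, 95% CI, p-value)."""
    return pd.DataFrame([fits[k].to_row() for k in LADDER_LABELS if k in fits])


def cox_screening(surv: pd.DataFrame, covariates: list,
                  screen_p: float = 0.2, alpha: float = 0.05):
    """Bivariable Cox screen followed by a multivariable fit.

    ``surv`` is a subject-level table with ``time`` and ``event``
    columns (see :func:`tbmsm.descriptives.subject_survival`).  Each
    candidate covariate is fitted alone (Efron ties); covariates whose
    likelihood-ratio p-value is below ``screen_p`` enter a joint model.
    Single-level covariates are skipped with a warning.  Returns
    ``(bivariable_table, multivariable_fit_or_None)``.
    """
    def encode(cols):
        cat = [c for c in cols if not pd.api.types.is_numeric_dtype(surv[c])]
        return pd.get_dummies(surv[["time", "event", *cols]], columns=cat,
                              drop_first=True, dtype=float)

    rows, passed = [], []
    for cov in covariates:
        if surv[cov].nunique() <= 1:
            logger.warning("covariate %r has a single level; skipped", cov)
            rows.append({"covariate": cov, "p_value": np.nan, "skipped": True})
            continue
        cph = CoxPHFitter()
        cph.fit(encode([cov]), duration_col="time", event_col="event")
        p = float(cph.log_likelihood_ratio_test().p_value)
        rows.append({"covariate": cov, "p_value": p, "skipped": False})
        if p < screen_p:
            passed.append(cov)
    table = pd.DataFrame(rows)
    multi = None
    if passed:
        multi = CoxPHFitter()
        multi.fit(encode(passed), duration_col="time", event_col="event")
    table.attrs["selected"] = passed
    table.attrs["alpha"] = alpha
    return table, multi


def bootstrap_ci(pp: pd.DataFrame, fit_fn, n_boot: int = 200,
                 seed: int = 0, level: float = 0.95,
                 max_dropped_frac: float = 0.2):
    """Subject-level bootstrap percentile CI for a pipeline closure.

    ``fit_fn(pp_boot) -> ModelFit`` must re-run the whole weight fitting
    and outcome estimation on the resampled person-period table.
    Replicates that fail for want of events are dropped and counted;
    more than ``max_dropped_frac`` dropped replicates is an error.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    ids = pp["subject_id"].unique()
    groups = {sid: g for sid, g in pp.groupby("subject_id", sort=False)}
    log_hrs, dropped = [], 0
    for b in range(n_boot):
        take = rng.choice(ids, size=len(ids), replace=True)
        frames = []
        for j, sid in enumerate(take):
            g = groups[sid].copy()
            g["subject_id"] = f"b{j}"
            frames.append(g)
        boot = pd.concat(frames, ignore_index=True)
        try:
            log_hrs.append(fit_fn(boot).log_hr)
        except (ValueError, RuntimeError):
            dropped += 1
    if dropped > max_dropped_frac * n_boot:
        raise RuntimeError(f"{dropped}/{n_boot} bootstrap replicates failed")
    alpha = (1 - level) / 2
    lo, hi = np.exp(np.percentile(log_hrs, [100 * alpha, 100 * (1 - alpha)]))
    return {"ci_low": float(lo), "ci_high": float(hi),
            "estimates": np.exp(log_hrs), "n_dropped": dropped}
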