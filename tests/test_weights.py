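"""Treatment/censoring process models and stabilized IPTC weights."""

import numpy as np
import pandas as pd
import pytest

from tbmsm import (SimulationConfig, build_person_period, simulate_cohort,
                   stabilized_weights, weight_diagnostics)
from tbmsm.weights import (FittedProcessModel, SeparationError,
                           WeightModelSpec, fit_censoring_model,
                           fit_treatment_model)

from conftest import make_baseline, make_visits


@pytest.fixture(scope="module")
def big_cohort():
    """n=5000 confounded cohort for coefficient-recovery checks."""
    cfg = SimulationConfig(n_subjects=5000, seed=99)
    subjects, visits = simulate_cohort(cfg)
    return cfg, build_person_period(subjects, visits)


class TestSpec:
    def test_numerator_must_be_subset(self):
        spec = WeightModelSpec(numerator_covariates=["sex", "age_years"],
                               denominator_covariates=["sex"])
        with pytest.raises(ValueError, match="subset"):
            spec.validate()


class TestTreatmentModel:
    def test_intercept_only_recovers_empirical_initiation(self):
        """Constant initiation probability: the fitted numerator equals the
        empirical initiation proportion over untreated person-months."""
        rng = np.random.default_rng(0)
        n, T, p = 600, 12, 0.07
        rows, brows = [], []
        for i in range(n):
            sid = f"S{i}"
            brows.append((sid, "", 5.0, "male", "I", "above_threshold", "haart"))
            started = False
            for m in range(T):
                if not started and rng.random() < p:
                    started = True
                rows.append((sid, float(m), started, "above_threshold", "I",
                             "good", False, "active", False))
        pp = build_person_period(make_baseline(brows), make_visits(rows))
        spec = WeightModelSpec(numerator_covariates=[],
                               denominator_covariates=[], time_kind="linear")
        fm = fit_treatment_model(pp, spec)
        risk = ~pp.groupby("subject_id")["on_haart"].transform(
            lambda s: s.shift(fill_value=False).cummax())
        emp = pp.loc[risk, "on_haart"].mean()
        init_rows = risk & pp["on_haart"]
        fitted = fm.p_den[init_rows.to_numpy()]
        assert fitted.mean() == pytest.approx(emp, abs=0.02)

    def test_recovers_initiation_coefficient(self, big_cohort):
        """Denominator coefficient on low CD4 recovers alpha_l within 2 SE."""
        cfg, pp = big_cohort
        spec = WeightModelSpec(numerator_covariates=[],
                               denominator_covariates=["cd4_class"])
        fm = fit_treatment_model(pp, spec)
        tab = fm.coefficient_table("den")
        coef = tab.loc["cd4_class[below_threshold]"]
        assert abs(coef["coef"] - cfg.alpha_l) < 2 * coef["se"]

    def test_zero_initiations_rejected(self):
        brows = [("A", "", 4.0, "male", "I", "above_threshold", "non_haart")]
        rows = [("A", float(m), False, "above_threshold", "I", "good", False,
                 "active", False) for m in range(6)]
        pp = build_person_period(make_baseline(brows), make_visits(rows))
        with pytest.raises(ValueError, match="zero treatment initiations"):
            fit_treatment_model(pp)

    def test_complete_separation_names_covariate(self):
        """A covariate that perfectly determines initiation is reported."""
        rows, brows = [], []
        for i in range(40):
            sid = f"S{i}"
            sep = i < 20  # sex perfectly predicts immediate initiation
            brows.append((sid, "", 5.0, "male" if sep else "female", "I",
                          "above_threshold", "haart"))
            for m in range(3):
                rows.append((sid, float(m), sep, "above_threshold", "I",
                             "good", False, "active", False))
        pp = build_person_period(make_baseline(brows), make_visits(rows))
        spec = WeightModelSpec(numerator_covariates=[],
                               denominator_covariates=["sex"],
                               time_kind="linear")
        with pytest.raises(SeparationError, match="sex"):
            fit_treatment_model(pp, spec)


class TestCensoringModel:
    def test_no_censoring_gives_unit_probabilities(self):
        cfg = SimulationConfig(n_subjects=150, n_intervals=24, kappa0=-50.0,
                              seed=12)
        s, v = simulate_cohort(cfg)
        pp = build_person_period(s, v)
        cm = fit_censoring_model(pp)
        assert (cm.p_num == 1).all() and (cm.p_den == 1).all()
        w = stabilized_weights(pp, None, cm)
        assert (w["sw_cens"] == 1).all()

    def test_recovers_censoring_coefficient(self, big_cohort):
        cfg, pp = big_cohort
        spec = WeightModelSpec(numerator_covariates=[],
                               denominator_covariates=["cd4_class"])
        cm = fit_censoring_model(pp, spec)
        tab = cm.coefficient_table("den")
        coef = tab.loc["cd4_class[below_threshold]"]
        assert abs(coef["coef"] - cfg.kappa_l) < 2 * coef["se"]


class TestStabilizedWeights:
    def test_identity_when_numerator_equals_denominator(self, small_cohort):
        _, _, _, pp = small_cohort
        spec = WeightModelSpec(
            numerator_covariates=list(WeightModelSpec().denominator_covariates))
        fm = fit_treatment_model(pp, spec)
        w = stabilized_weights(pp, fm)
        assert np.allclose(w["sw_treat"], 1.0, atol=1e-6)

    def test_cumulative_product_of_stated_probabilities(self):
        pp = pd.DataFrame({"subject_id": ["A"] * 3, "t": [0, 1, 2]})
        fm = FittedProcessModel("treatment",
                                p_num=np.array([1.0, 0.6, 0.55]),
                                p_den=np.array([1.0, 0.8, 0.5]))
        w = stabilized_weights(pp, fm)
        assert w["sw_treat"].iloc[2] == pytest.approx((0.6 * 0.55) / (0.8 * 0.5))
        assert w["sw_treat"].iloc[2] == pytest.approx(0.825)

    def test_positivity_error_lists_rows(self):
        pp = pd.DataFrame({"subject_id": ["A", "A"], "t": [0, 1]})
        fm = FittedProcessModel("treatment", p_num=np.array([1.0, 0.5]),
                                p_den=np.array([1.0, 0.0]))
        with pytest.raises(Exception, match="denominator probability is 0"):
            stabilized_weights(pp, fm)

    def test_mean_stabilized_weight_near_one_per_interval(self, default_cohort):
        _, _, _, pp = default_cohort
        fm = fit_treatment_model(pp)
        cm = fit_censoring_model(pp)
        w = stabilized_weights(pp, fm, cm)
        diag = weight_diagnostics(w)
        assert 0.9 < diag["mean"] < 1.1
        assert ((diag["per_interval_mean"] > 0.8)
                & (diag["per_interval_mean"] < 1.2)).all()
        assert diag["max"] < 30  # no runaway weights before truncation

    def test_truncation_clips_at_percentiles(self, small_cohort):
        _, _, _, pp = small_cohort
        fm = fit_treatment_model(pp)
        w_raw = stabilized_weights(pp, fm)
        w_trunc = stabilized_weights(pp, fm, truncation=(1, 99))
        lo, hi = np.percentile(w_raw["sw_total"], [1, 99])
        assert w_trunc["sw_total"].max() == pytest.approx(hi)
        assert w_trunc["sw_total"].min() == pytest.approx(lo)

    def test_noise_covariate_leaves_weights_unchanged(self):
        """Adding a treatment-independent covariate to both numerator and
        denominator does not move the weights beyond fit noise."""
        cfg = SimulationConfig(n_subjects=2000, seed=55)
        s, v = simulate_cohort(cfg)
        pp = build_person_period(s, v)
        rng = np.random.default_rng(1)
        pp["noise"] = rng.normal(size=len(pp))
        base = WeightModelSpec()
        noisy = WeightModelSpec(
            numerator_covariates=base.numerator_covariates + ["noise"],
            denominator_covariates=base.denominator_covariates + ["noise"])
        w0 = stabilized_weights(pp, fit_treatment_model(pp, base))
        w1 = stabilized_weights(pp, fit_treatment_model(pp, noisy))
        assert np.quantile(np.abs(w1["sw_total"] - w0["sw_total"]), 0.99) < 0.05
        assert abs(w1["sw_total"].mean() - w0["sw_total"].mean()) < 0.01


class TestDiagnostics:
    def test_all_ones(self):
        w = pd.DataFrame({"subject_id": ["A", "B"], "t": [0, 0],
                          "sw_total": [1.0, 1.0]})
        d = weight_diagnostics(w)
        assert d["mean"] == 1.0 and d["sd"] == 0.0

    def test_warns_when_mean_drifts(self, caplog):
        w = pd.DataFrame({"subject_id": list("ABCD"), "t": [0] * 4,
                          "sw_total": [2.0, 2.1, 1.9, 2.0]})
        with caplog.at_level("WARNING"):
            weight_diagnostics(w)
        assert "deviates from 1" in caplog.text
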