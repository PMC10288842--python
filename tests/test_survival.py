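"""Survival-layer tests: Cox, Schoenfeld diagnostics, KM, log-rank, ROC."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy.optimize import minimize_scalar

from netmtv import (
    PatientRecord,
    fit_cox,
    km_estimate,
    logrank,
    mannwhitney,
    records_to_frame,
    roc_fixed_horizon,
    schoenfeld_ph_test,
    survival_at,
)
from netmtv.survival import DegenerateModelError, DegenerateOutcomeError
from netmtv.synthdata import simulate_survival


def toy_frame():
    # three patients, events at t=1 (x=1) and t=2 (x=0), censored at t=3
    return pd.DataFrame(
        {"x": [1.0, 0.0, 0.5], "os_months": [1.0, 2.0, 3.0], "event": [1, 1, 0]}
    )


class TestCox:
    def test_toy_matches_partial_likelihood_grid(self):
        df = toy_frame()

        def negll(b):
            r = np.exp(b * df["x"].to_numpy())
            return -(
                b * 1.0 - np.log(r.sum()) + b * 0.0 - np.log(r[1] + r[2])
            )

        oracle = minimize_scalar(negll, bounds=(-10, 10), method="bounded").x
        fit = fit_cox(df, ["x"])
        assert fit.coef("x") == pytest.approx(oracle, abs=1e-3)
        assert fit.coef("x") == pytest.approx(1.1412, abs=1e-3)

    def test_hr_and_ci_consistent(self):
        df = simulate_survival(300, beta=0.7, seed=3)
        fit = fit_cox(df, ["x"])
        row = fit.summary.loc["x"]
        assert row["hazard_ratio"] == pytest.approx(np.exp(row["coef"]))
        assert row["ci95_low"] <= row["hazard_ratio"] <= row["ci95_high"]
        assert fit.n_events == int(df["event"].sum())

    def test_single_rep_recovery(self):
        df = simulate_survival(500, beta=0.98, seed=7)
        fit = fit_cox(df, ["x"])
        assert fit.coef("x") == pytest.approx(0.98, abs=0.2)

    def test_rescaling_covariate_rescales_beta(self):
        df = simulate_survival(400, beta=0.5, seed=11)
        fit1 = fit_cox(df, ["x"])
        df2 = df.assign(x=2.0 * df["x"])
        fit2 = fit_cox(df2, ["x"])
        assert fit2.coef("x") == pytest.approx(fit1.coef("x") / 2.0, rel=1e-4)

    def test_no_events_raises(self):
        df = toy_frame().assign(event=0)
        with pytest.raises(DegenerateModelError):
            fit_cox(df, ["x"])

    def test_constant_covariate_raises(self):
        df = toy_frame().assign(x=1.0)
        with pytest.raises(DegenerateModelError):
            fit_cox(df, ["x"])

    def test_missing_covariate_raises(self):
        with pytest.raises(KeyError):
            fit_cox(toy_frame(), ["nope"])


class TestSchoenfeld:
    def test_agrees_with_lifelines_identity_transform(self):
        rng = np.random.default_rng(42)
        n = 200
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        t = 105 * (-np.log(rng.uniform(size=n)) / np.exp(0.7 * x1 - 0.3 * x2)) ** (1 / 1.3)
        c = rng.uniform(20, 140, size=n)
        df = pd.DataFrame(
            {
                "os_months": np.minimum(t, c),
                "event": (t <= c).astype(int),
                "x1": x1,
                "x2": x2,
            }
        )
        fit = fit_cox(df, ["x1", "x2"])
        mine = schoenfeld_ph_test(fit)
        cph = CoxPHFitter().fit(df, "os_months", "event")
        ref = proportional_hazard_test(cph, df, time_transform="identity").summary
        for cov in ("x1", "x2"):
            assert mine[cov] == pytest.approx(float(ref.loc[cov, "p"]), abs=1e-6)

    def test_detects_reversing_effect(self):
        from netmtv.synthdata import simulate_reversing_effect

        df = simulate_reversing_effect(500, beta=0.7, seed=1)
        fit = fit_cox(df, ["x"])
        assert schoenfeld_ph_test(fit)["x"] < 0.05


class TestKaplanMeier:
    def test_no_censoring_equals_empirical(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert survival_at(curve, 2.5) == pytest.approx(0.5)
        assert survival_at(curve, 0.5) == 1.0
        assert survival_at(curve, 4.0) == 0.0
        np.testing.assert_allclose(curve.survival_prob, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored(self):
        curve = km_estimate([5, 10, 15], [0, 0, 0])
        assert survival_at(curve, 100.0) == 1.0

    def test_empirical_matches_ecdf_random(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(50, size=200)
        curve = km_estimate(t, np.ones_like(t))
        for q in (10.0, 40.0, 90.0):
            assert survival_at(curve, q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_weibull_closed_form(self):
        lam, k, n = 105.3, 1.3, 5000
        rng = np.random.default_rng(9)
        t = lam * (-np.log(rng.uniform(size=n))) ** (1 / k)
        curve = km_estimate(t, np.ones(n))
        s_true = np.exp(-((60.0 / lam) ** k))
        se = np.sqrt(s_true * (1 - s_true) / n)
        assert abs(survival_at(curve, 60.0) - s_true) < 2 * se

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups(self):
        t, e = [1.0, 2.0, 3.0, 4.0], [1, 0, 1, 1]
        chi2, p = logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            logrank([], [], [1.0], [1])

    def test_agrees_with_cox_on_group_indicator(self):
        rng = np.random.default_rng(4)
        n = 2000
        g = np.repeat([0.0, 1.0], n // 2)
        t = 80 * (-np.log(rng.uniform(size=n)) * np.exp(-0.3 * g)) ** (1 / 1.2)
        c = rng.uniform(30, 200, n)
        df = pd.DataFrame(
            {"os_months": np.minimum(t, c), "event": (t <= c).astype(int), "g": g}
        )
        _, p_lr = logrank(
            df.loc[g == 0, "os_months"], df.loc[g == 0, "event"],
            df.loc[g == 1, "os_months"], df.loc[g == 1, "event"],
        )
        fit = fit_cox(df, ["g"])
        assert p_lr == pytest.approx(float(fit.summary.loc["g", "p_value"]), abs=1e-2)


class TestRoc:
    def test_uninformative_marker(self):
        t = np.r_[np.full(20, 30.0), np.full(20, 90.0)]
        e = np.r_[np.ones(20), np.zeros(20)]
        r = roc_fixed_horizon(np.full(40, 7.0), t, e, horizon_months=60)
        assert r.auc == pytest.approx(0.5)

    def test_perfect_marker(self):
        t = np.r_[np.full(15, 30.0), np.full(15, 100.0)]
        e = np.r_[np.ones(15), np.zeros(15)]
        marker = np.r_[np.full(15, 10.0), np.full(15, 1.0)]
        r = roc_fixed_horizon(marker, t, e, horizon_months=60)
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert 1.0 <= r.cutoff < 10.0

    def test_censored_before_horizon_excluded(self):
        t = np.array([30.0, 30.0, 90.0, 90.0, 40.0])
        e = np.array([1, 1, 0, 0, 0])  # last patient censored at 40 -> excluded
        r = roc_fixed_horizon(np.array([5.0, 6.0, 1.0, 2.0, 100.0]), t, e, 60)
        assert r.n_cases == 2 and r.n_controls == 2
        assert r.auc == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        df = simulate_survival(300, beta=0.8, seed=6)
        marker = np.exp(df["x"].to_numpy())
        r1 = roc_fixed_horizon(marker, df["os_months"], df["event"], 60)
        r2 = roc_fixed_horizon(np.log(marker), df["os_months"], df["event"], 60)
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)
        assert r1.sensitivity == pytest.approx(r2.sensitivity)
        assert r1.specificity == pytest.approx(r2.specificity)

    def test_degenerate_outcome_raises(self):
        t = np.full(10, 100.0)
        e = np.zeros(10)
        with pytest.raises(DegenerateOutcomeError):
            roc_fixed_horizon(np.arange(10.0), t, e, 60)

    def test_small_arm_uses_bootstrap_ci(self):
        t = np.r_[np.full(5, 30.0), np.full(30, 90.0)]
        e = np.r_[np.ones(5), np.zeros(30)]
        rng = np.random.default_rng(0)
        r = roc_fixed_horizon(rng.normal(size=35) + np.r_[np.ones(5), np.zeros(30)], t, e, 60, seed=1)
        assert r.ci_method == "bootstrap"
        assert 0.0 <= r.auc_ci95[0] <= r.auc <= r.auc_ci95[1] <= 1.0


class TestMannWhitney:
    def test_identical_samples(self):
        _, p = mannwhitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.99

    def test_complete_separation_u_zero(self):
        u, _ = mannwhitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert min(u, 9 - u) == 0.0  # U for one side is 0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mannwhitney([], [1.0])


class TestRecords:
    def test_encoding(self):
        rec = PatientRecord(
            id="p1", age=64, gender="female", grading="G2", primary_site="GEP",
            cga=800.0, ldh=220.0, ggt=60.0, mtv_ml=120.0, os_months=48.0, event=True,
        )
        df = records_to_frame([rec])
        assert df.loc[0, "gender"] == 0
        assert df.loc[0, "grading"] == 2
        assert df.loc[0, "ggt_log"] == pytest.approx(np.log(60.0))

    def test_invalid_record_rejected(self):
        with pytest.raises(ValueError):
            PatientRecord(
                id="p2", age=60, gender="male", grading="G1", primary_site="CUP",
                cga=0.0, ldh=200.0, ggt=50.0, mtv_ml=10.0, os_months=12.0, event=False,
            )
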