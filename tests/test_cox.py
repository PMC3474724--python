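import numpy as np
import pandas as pd
import pytest

import rpsurv as rs
from conftest import untied_cohort


def naive_partial_loglik(beta, times, x):
    """Enumerated Breslow partial likelihood for fully observed, untied data."""
    ll = 0.0
    for i in range(len(times)):
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


class TestFitCox:
    def test_matches_dense_grid_oracle(self):
        times = [2.0, 5.0, 1.0, 7.0, 3.0, 9.0]
        x = [1.0, 0.0, 1.0, 0.0, 0.0, 1.0]
        fit = rs.fit_cox(untied_cohort(times, x), design=["x"])
        grid = np.arange(-3.0, 3.0, 1e-4)
        lls = [naive_partial_loglik(b, times, x) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert fit.beta[0] == pytest.approx(best, abs=1e-4)
        assert fit.pl_loglik == pytest.approx(max(lls), abs=1e-6)

    def test_score_zero_at_mle(self, default_cohort):
        from rpsurv.cox import _risk_sums

        fit = rs.fit_cox(default_cohort)
        X, _ = default_cohort.design_matrix()
        rsums = _risk_sums(default_cohort.time, default_cohort.event, X, fit.beta)
        assert np.max(np.abs(rsums["score"])) < 1e-6

    def test_null_loglik_closed_form(self):
        times = [4.0, 2.0, 8.0, 6.0]
        c = untied_cohort(times, [0.0, 1.0, 0.0, 1.0])
        from rpsurv.cox import _risk_sums

        X = c.data[["x"]].to_numpy()
        rsums = _risk_sums(c.time, c.event, X, np.zeros(1))
        expected = -sum(np.log(k) for k in (4, 3, 2, 1))
        assert rsums["loglik"] == pytest.approx(expected)

    def test_constant_covariate_flagged(self):
        fit = rs.fit_cox(untied_cohort([1.0, 2.0, 3.0, 4.0], [2.0] * 4), design=["x"])
        assert fit.flagged
        assert fit.beta[0] == pytest.approx(0.0)

    def test_agrees_with_sksurv_breslow_on_tied_data(self, default_cohort):
        sksurv = pytest.importorskip("sksurv.linear_model")
        ours = rs.fit_cox(default_cohort)
        X, _ = default_cohort.design_matrix()
        y = np.array(
            [(bool(e), t) for e, t in zip(default_cohort.event, default_cohort.time)],
            dtype=[("e", bool), ("t", float)],
        )
        ref = sksurv.CoxPHSurvivalAnalysis(ties="breslow").fit(X, y)
        np.testing.assert_allclose(ours.beta, ref.coef_, atol=1e-5)


class TestBreslowBaseline:
    def test_reduces_to_nelson_aalen_at_null(self, default_cohort):
        from lifelines import NelsonAalenFitter

        c = default_cohort
        fit = rs.fit_cox(untied_cohort(c.time.tolist(), [0.0] * len(c)), design=["x"])
        taus, H = rs.breslow_baseline(
            fit, untied_cohort(c.time.tolist(), [0.0] * len(c)), design=["x"]
        )
        na = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(c.time, c.event)
        ref = na.cumulative_hazard_.loc[taus, "NA_estimate"].to_numpy()
        np.testing.assert_allclose(H, ref, atol=1e-10)

    def test_hand_computed_jumps_weighted_risk_sets(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0]
        x = [1.0, 0.0, 1.0, 0.0, 1.0]
        c = untied_cohort(times, x)
        fit = rs.fit_cox(c, design=["x"])
        taus, H = rs.breslow_baseline(fit, c, design=["x"])
        w = np.exp(fit.beta[0] * np.asarray(x))
        expected = np.cumsum([1.0 / w[i:].sum() for i in range(5)])
        np.testing.assert_allclose(H, expected, atol=1e-10)

    def test_cumhaz_nondecreasing_and_stepwise(self, default_cohort):
        fit = rs.fit_cox(default_cohort)
        assert np.all(np.diff(fit.baseline_cumhaz) > 0)
        # constant between event times
        mid = (fit.baseline_times[:-1] + fit.baseline_times[1:]) / 2
        s_mid = rs.predict_survival_cox(fit, mid)
        s_left = rs.predict_survival_cox(fit, fit.baseline_times[:-1])
        np.testing.assert_allclose(s_mid, s_left)

    def test_kalbfleisch_prentice_close_to_breslow(self, default_cohort):
        fit = rs.fit_cox(default_cohort)
        taus, s_kp = rs.kalbfleisch_prentice_baseline(fit, default_cohort)
        s_breslow = np.exp(-fit.baseline_cumhaz)
        assert np.max(np.abs(s_kp - s_breslow)) < 0.05


class TestPredict:
    def test_baseline_identity_and_power_relation(self, default_cohort):
        fit = rs.fit_cox(default_cohort)
        t = np.array([1.0, 5.0, 20.0, 100.0])
        s0 = rs.predict_survival_cox(fit, t)
        x = [0.0, 0.0, 0.0, 0.0]
        np.testing.assert_allclose(rs.predict_survival_cox(fit, t, x), s0)
        # a pattern with exp(x.beta) = 2 must square the baseline
        beta_sum = fit.beta.sum()
        scale = np.log(2.0) / beta_sum
        s = rs.predict_survival_cox(fit, t, [scale] * 4)
        np.testing.assert_allclose(s, s0**2, atol=1e-12)

    def test_survival_one_before_first_event(self, default_cohort):
        fit = rs.fit_cox(default_cohort)
        assert rs.predict_survival_cox(fit, [0.5])[0] == 1.0


class TestSchoenfeld:
    def test_matches_lifelines_on_untied_data(self):
        from lifelines import CoxPHFitter
        from lifelines.statistics import proportional_hazard_test

        c = rs.generate_ph(rs.GeneratorConfig(n=300), [0.5], seed=5)
        fit = rs.fit_cox(c, design=["x0"])
        df = pd.DataFrame({"x0": c.data["x0"], "T": c.time, "E": c.event})
        ref_fit = CoxPHFitter().fit(df, "T", "E")
        for transform in ("rank", "km"):
            ours = rs.schoenfeld_test(fit, c, design=["x0"], time_transform=transform)
            ref = proportional_hazard_test(ref_fit, df, time_transform=transform)
            assert ours[0] == pytest.approx(float(np.asarray(ref.test_statistic).ravel()[0]), rel=1e-6)

    def test_transforms_reported_separately(self, default_cohort):
        fit = rs.fit_cox(default_cohort)
        out = {
            tf: rs.schoenfeld_test(fit, default_cohort, time_transform=tf)
            for tf in ("identity", "rank")
        }
        assert out["identity"][0] != out["rank"][0]
        assert all(len(v) == 3 for v in out.values())

    def test_rejects_on_nonproportional_cohort(self, default_cohort):
        fit = rs.fit_cox(default_cohort)
        chi2, df, p = rs.schoenfeld_test(fit, default_cohort)
        assert p < 0.001

    def test_too_few_events_rejected(self):
        c = untied_cohort([3.0], [1.0])
        with pytest.raises(ValueError):
            fit = rs.fit_cox(c, design=["x"])
            rs.schoenfeld_test(fit, c, design=["x"])
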