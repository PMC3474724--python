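import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

import rpsurv as rs


def _baseline_spec(family, m=0):
    return rs.RPSpec(family=family, m=m, covariates=())


class TestLinks:
    @pytest.mark.parametrize(
        "family,s,expected",
        [("probit", 0.5, 0.0), ("PH", np.exp(-1), 0.0), ("PO", 0.5, 0.0)],
    )
    def test_zero_points(self, family, s, expected):
        assert rs.link(family, s) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None)
    @given(
        st.sampled_from(rs.FAMILIES),
        st.floats(min_value=1e-6, max_value=1 - 1e-6),
    )
    def test_inverse_roundtrip(self, family, s):
        assert rs.inverse_link(family, rs.link(family, s)) == pytest.approx(s, abs=1e-9)

    def test_domain_errors(self):
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                rs.link("probit", bad)
        with pytest.raises(ValueError):
            rs.link("aranda-ordaz", 0.5)


class TestZeroKnotOracles:
    """With no interior knots the three link scales are classical families."""

    def test_probit_matches_lognormal_mle(self, lognormal_cohort):
        f = rs.fit(lognormal_cohort, _baseline_spec("probit"))
        lt = np.log(lognormal_cohort.time)
        mu, sigma = lt.mean(), lt.std()  # divisor-n MLE
        oracle = np.sum(stats.norm.logpdf(lt, mu, sigma) - lt)
        assert f.converged
        assert f.loglik == pytest.approx(oracle, rel=1e-6)

    def test_ph_matches_weibull_mle(self, lognormal_cohort):
        t = lognormal_cohort.time
        f = rs.fit(lognormal_cohort, _baseline_spec("PH"))

        def nll(p):
            shape, scale = np.exp(p)
            return -np.sum(stats.weibull_min.logpdf(t, shape, scale=scale))

        res = optimize.minimize(nll, [0.0, np.log(t.mean())], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        assert f.loglik == pytest.approx(-res.fun, rel=1e-6)

    def test_po_matches_loglogistic_mle(self, lognormal_cohort):
        t = lognormal_cohort.time
        f = rs.fit(lognormal_cohort, _baseline_spec("PO"))

        def nll(p):
            shape, scale = np.exp(p)
            return -np.sum(stats.fisk.logpdf(t, shape, scale=scale))

        res = optimize.minimize(nll, [0.0, np.log(np.median(t))], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        assert f.loglik == pytest.approx(-res.fun, rel=1e-6)

    def test_probit_gamma_reparameterizes_lognormal(self, lognormal_cohort):
        # S(t) = Phi(-(g0 + g1 ln t))  <=>  g1 = 1/sigma, g0 = -mu/sigma
        f = rs.fit(lognormal_cohort, _baseline_spec("probit"))
        lt = np.log(lognormal_cohort.time)
        assert f.gamma[1] == pytest.approx(1 / lt.std(), rel=1e-4)
        assert f.gamma[0] == pytest.approx(-lt.mean() / lt.std(), rel=1e-4)


class TestLikelihood:
    def test_adding_knots_never_hurts(self, default_cohort):
        logliks = []
        for m in range(3):
            f = rs.fit(default_cohort, rs.RPSpec(family="probit", m=m))
            assert f.converged
            logliks.append(f.loglik)
        assert np.all(np.diff(logliks) >= -1e-6)

    def test_nonmonotone_spline_penalized(self, lognormal_cohort):
        spec = _baseline_spec("probit")
        knots = rs.place_knots(np.log(lognormal_cohort.time), 0)
        good = rs.log_likelihood([0.0, 1.0], lognormal_cohort, spec, knots)
        bad = rs.log_likelihood([0.0, -1.0], lognormal_cohort, spec, knots)
        assert np.isfinite(bad) and bad < -1e7 < good

    def test_nonfinite_params_rejected(self, lognormal_cohort):
        knots = rs.place_knots(np.log(lognormal_cohort.time), 0)
        with pytest.raises(ValueError):
            rs.log_likelihood([np.nan, 1.0], lognormal_cohort, _baseline_spec("probit"), knots)

    def test_subject_order_irrelevant(self, default_cohort):
        f1 = rs.fit(default_cohort, rs.RPSpec(family="probit", m=1))
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(default_cohort))
        shuffled = default_cohort.subset(perm)
        f2 = rs.fit(shuffled, rs.RPSpec(family="probit", m=1))
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-6)

    def test_censored_contributions(self):
        # likelihood of a censored subject is ln S; check against closed form
        df = pd.DataFrame(
            {"subject_id": [1, 2], "time": [2.0, 3.0], "event": [1, 0],
             "pps_group": pd.array(["10", "10"], dtype="string")}
        )
        c = rs.SurvivalCohort(df, preprocessed=True)
        knots = rs.KnotSet(np.empty(0), 0.0, np.log(3.0))
        ll = rs.log_likelihood([0.0, 1.0], c, _baseline_spec("probit"), knots)
        lt = np.log([2.0, 3.0])
        expected = (stats.norm.logpdf(lt[0]) - lt[0]) + stats.norm.logsf(lt[1])
        assert ll == pytest.approx(expected, rel=1e-12)


class TestFitAndPredict:
    def test_hazard_ratio_agrees_with_cox_on_ph_data(self):
        c = rs.generate_ph(rs.GeneratorConfig(n=2000), [np.log(2)], seed=3)
        rp = rs.fit(c, rs.RPSpec(family="PH", m=0, covariates=("x0",)))
        cx = rs.fit_cox(c, design=["x0"])
        assert np.exp(rp.beta[0]) == pytest.approx(np.exp(cx.beta[0]), rel=0.02)

    def test_survival_monotone_and_bounded(self, default_cohort):
        f = rs.fit(default_cohort, rs.RPSpec(family="probit", m=1))
        t = np.linspace(0.5, 400, 500)
        for pattern in (None, [1, 0, 0, 0], [0, 0, 0, 1]):
            s = rs.predict_survival(f, t, pattern)
            assert np.all((s > 0) & (s < 1))
            assert np.all(np.diff(s) <= 1e-12)

    def test_survival_approaches_one_at_origin(self, default_cohort):
        f = rs.fit(default_cohort, rs.RPSpec(family="probit", m=1))
        assert rs.predict_survival(f, 1e-6)[0] == pytest.approx(1.0, abs=1e-3)

    def test_median_maps_to_half_survival(self, lognormal_cohort):
        f = rs.fit(lognormal_cohort, _baseline_spec("probit"))
        lt = np.log(lognormal_cohort.time)
        geometric_median = np.exp(lt.mean())  # log-normal median MLE
        assert rs.predict_survival(f, geometric_median)[0] == pytest.approx(0.5, abs=1e-6)

    def test_nonpositive_times_rejected(self, lognormal_cohort):
        f = rs.fit(lognormal_cohort, _baseline_spec("probit"))
        with pytest.raises(ValueError):
            rs.predict_survival(f, [1.0, 0.0])

    def test_vcov_close_to_lifelines_on_aft_case(self, lognormal_cohort):
        # probit m=0 is a log-normal AFT; lifelines gives an independent vcov
        from lifelines import LogNormalFitter

        f = rs.fit(lognormal_cohort, _baseline_spec("probit"))
        ln = LogNormalFitter().fit(lognormal_cohort.time, lognormal_cohort.event)
        # delta method: mu = -g0/g1, se via fit vcov
        g0, g1 = f.gamma
        grad = np.array([-1 / g1, g0 / g1**2])
        se_mu = np.sqrt(grad @ f.vcov[:2, :2] @ grad)
        assert se_mu == pytest.approx(ln.summary.loc["mu_", "se(coef)"], rel=0.02)


class TestInformationCriteria:
    def test_printed_formulas(self):
        knots = rs.KnotSet(np.empty(0), 0.0, 1.0)
        f = rs.RPFit(
            spec=rs.RPSpec(family="probit", m=0, covariates=("a",)),
            knots=knots, gamma=np.zeros(2), beta=np.zeros(1),
            loglik=-100.0, vcov=np.eye(3), n_events=100, converged=True, valid=True,
        )
        aic, bic = rs.information_criteria(f)
        assert aic == pytest.approx(206.0)
        assert bic == pytest.approx(200 + 3 * np.log(100))

    def test_aic_ordering_tracks_penalized_loglik(self, default_cohort):
        f0 = rs.fit(default_cohort, rs.RPSpec(family="probit", m=0))
        f1 = rs.fit(default_cohort, rs.RPSpec(family="probit", m=1))
        a0, _ = rs.information_criteria(f0)
        a1, _ = rs.information_criteria(f1)
        assert (a1 - a0) == pytest.approx(-2 * (f1.loglik - f0.loglik) + 2, abs=1e-9)
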