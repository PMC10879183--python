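"""Survival primitives: closed forms, cross-implementation oracles,
invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as lifelines_logrank

from survsig import (
    cox_univariate,
    km_estimate,
    logrank_test,
    optimal_cutpoint,
    restricted_mean_survival,
)
from survsig.survival import cox_score_test


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        curve = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve.surv_prob, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_all_censored_flat(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.event_times.size == 0
        assert curve.survival_at(10) == 1.0

    def test_hand_product_limit_with_tie_and_censor(self):
        # times [1,1,2,4], events [1,0,1,1]: S(2) = (1-1/4)(1-1/2) = 0.375
        curve = km_estimate([1, 1, 2, 4], [1, 0, 1, 1])
        assert curve.survival_at(2) == pytest.approx(0.375)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(1, 30)
        e = rng.integers(0, 2, 30)
        a = km_estimate(t, e)
        perm = rng.permutation(30)
        b = km_estimate(t[perm], e[perm])
        np.testing.assert_allclose(a.surv_prob, b.surv_prob)
        np.testing.assert_allclose(a.event_times, b.event_times)

    def test_rmst_of_exponential_sample(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1.0, 4000)
        # int_0^tau e^-t dt = 1 - e^-tau
        est = restricted_mean_survival(t, np.ones(4000, dtype=int), tau=2.0)
        assert est == pytest.approx(1 - np.exp(-2.0), abs=0.05)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogRank:
    def test_identical_groups_give_chi2_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_separated_groups_hand_tabulation(self):
        """Group A events at 1,2,3; group B at 4,5,6. The O-E/V tabulation
        over the six event times gives the expected chi-square."""
        t = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        e = np.ones(6, dtype=int)
        g = np.array([0, 0, 0, 1, 1, 1])
        # brute-force tabulation
        o_minus_e = v = 0.0
        for u in t:
            at = t >= u
            n, n1 = at.sum(), (at & (g == 1)).sum()
            d1 = float(((t == u) & (g == 1)).sum())
            o_minus_e += d1 - n1 / n
            if n > 1:  # single event per time: V_j = (n1/n)(1 - n1/n)
                v += (n1 / n) * (1 - n1 / n)
        expected_chi2 = o_minus_e**2 / v
        res = logrank_test(t, e, g)
        assert res.chi2 == pytest.approx(expected_chi2, rel=1e-12)
        assert res.p < 0.05

    def test_agrees_with_lifelines_on_random_data(self):
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 100:
            n = 40
            t = rng.exponential(1, n)
            e = rng.integers(0, 2, n)
            g = rng.integers(0, 2, n)
            if e.sum() == 0 or g.sum() in (0, n):
                continue
            mine = logrank_test(t, e, g)
            ref = lifelines_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
            assert mine.chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
            checked += 1

    def test_label_symmetry(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1, 30)
        e = rng.integers(0, 2, 30)
        e[0] = 1
        g = rng.integers(0, 2, 30)
        g[0], g[1] = 0, 1
        assert logrank_test(t, e, g).chi2 == pytest.approx(
            logrank_test(t, e, 1 - g).chi2, rel=1e-12
        )

    def test_empty_group_errors_and_zero_events_warns(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])
        with pytest.warns(UserWarning):
            res = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])
        assert res.p == 1.0


def _breslow_loglik_reference(beta, t, e, x):
    """Independent straight-from-the-definition Breslow partial likelihood."""
    ll = 0.0
    for u in np.unique(t[e == 1]):
        at_event = (t == u) & (e == 1)
        risk = t >= u
        ll += beta * x[at_event].sum() - at_event.sum() * np.log(
            np.exp(beta * x[risk]).sum()
        )
    return ll


class TestCoxUnivariate:
    def test_constant_covariate_degenerate(self):
        fit = cox_univariate([1, 2, 3, 4], [1, 1, 0, 1], [2.0, 2.0, 2.0, 2.0])
        assert fit.degenerate and fit.p == 1.0

    def test_score_statistic_equals_logrank_for_binary_covariate(self):
        t = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        e = np.ones(6, dtype=int)
        x = np.array([0, 0, 0, 1.0, 1, 1])  # perfect separator; group B protective
        fit = cox_univariate(t, e, x)
        lr = logrank_test(t, e, x.astype(int))
        assert fit.score_stat == pytest.approx(lr.chi2, abs=1e-10)
        assert fit.beta < 0  # later-failing group coded 1 => protective

    def test_score_and_information_match_finite_differences(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(1, 50)
        e = rng.integers(0, 2, 50)
        e[:5] = 1
        x = rng.normal(0, 1, 50)
        h = 1e-5
        ll = lambda b: _breslow_loglik_reference(b, t, e, x)
        U_num = (ll(h) - ll(-h)) / (2 * h)
        I_num = -(ll(h) - 2 * ll(0.0) + ll(-h)) / h**2
        chi2, _ = cox_score_test(t, e, x)
        assert chi2 == pytest.approx(U_num**2 / I_num, rel=1e-5)

    def test_beta_and_se_agree_with_lifelines(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            n = 60
            x = rng.normal(0, 1, n)
            t = rng.exponential(np.exp(-0.5 * x))
            e = (rng.random(n) < 0.8).astype(int)
            fit = cox_univariate(t, e, x)
            cph = CoxPHFitter().fit(
                pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e"
            )
            assert fit.beta == pytest.approx(float(cph.params_.iloc[0]), abs=2e-4)
            assert fit.se == pytest.approx(float(cph.standard_errors_.iloc[0]), rel=1e-3)

    @given(a=st.floats(-5, 5), b=st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_location_scale_invariance(self, a, b):
        rng = np.random.default_rng(13)
        t = rng.exponential(1, 40)
        e = rng.integers(0, 2, 40)
        e[0] = 1
        x = rng.normal(0, 1, 40)
        f1 = cox_univariate(t, e, x)
        f2 = cox_univariate(t, e, a + b * x)
        assert f2.score_stat == pytest.approx(f1.score_stat, rel=1e-8)
        assert f2.p == pytest.approx(f1.p, rel=1e-8)
        assert f2.beta == pytest.approx(f1.beta / b, rel=1e-5, abs=1e-8)


class TestOptimalCutpoint:
    def test_recovers_latent_split_for_strong_marker(self):
        rng = np.random.default_rng(21)
        n = 200
        latent = rng.random(n) < 0.5
        marker = np.where(latent, 2.0, -2.0) + rng.normal(0, 0.5, n)
        hazard = np.where(latent, 4.0, 1.0)
        t = rng.exponential(1 / hazard)
        e = np.ones(n, dtype=int)
        res = optimal_cutpoint(t, e, marker)
        called_high = marker > res.threshold
        agree = max(np.mean(called_high == latent), np.mean(called_high == ~latent))
        assert agree >= 0.95

    def test_min_p_selection_is_anticonservative_under_null(self):
        """Scanning thresholds for the minimum log-rank p inflates the
        type-I error well above nominal."""
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(100):
            n = 60
            t = rng.exponential(1, n)
            e = np.ones(n, dtype=int)
            marker = rng.normal(0, 1, n)  # independent of survival
            if optimal_cutpoint(t, e, marker).p < 0.05:
                hits += 1
        assert hits / 100 > 0.05

    def test_threshold_respects_quantile_band(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = 50
            t = rng.exponential(1, n)
            e = rng.integers(0, 2, n)
            e[0] = 1
            m = rng.normal(0, 1, n)
            res = optimal_cutpoint(t, e, m)
            lo, hi = np.quantile(m, [0.10, 0.90])
            assert lo <= res.threshold < hi

    def test_constant_marker_errors(self):
        with pytest.raises(ValueError):
            optimal_cutpoint(np.arange(1, 13), np.ones(12, dtype=int), np.ones(12))

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            optimal_cutpoint([1, 2, 3], [1, 1, 1], [1.0, 2.0, 3.0])
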