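"""Survival core: KM, Cox partial likelihood, log-rank, Fisher exact.

Each estimator is checked against an independent route: closed forms,
brute-force maximization/enumeration oracles, and the lifelines
implementations.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from ncrisk import (GeneratorConfig, GroupSurvivalAnchor, NOT_REACHED,
                    cox_fit, cox_score_test_at_zero, fisher_exact,
                    generate_cohort, km_fit, loglog_transform, logrank_test,
                    solve_weibull_anchors)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        km = km_fit([1, 2, 3, 4], [1, 1, 1, 1])
        np.testing.assert_allclose(km.surv, [0.75, 0.5, 0.25, 0.0])
        assert km.median == 2.0

    def test_all_censored_survival_stays_one(self):
        km = km_fit([5, 8, 13], [0, 0, 0])
        assert km.survival_at(100) == 1.0
        assert km.median == NOT_REACHED
        assert not km.median_reached

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_fit([], [])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.1, 500.0), min_size=1, max_size=40))
    def test_km_without_censoring_is_one_minus_ecdf(self, times):
        """Property: with every subject an event, S(t) equals the empirical
        survival function exactly."""
        t = np.asarray(times)
        km = km_fit(t, np.ones_like(t))
        for q in np.quantile(t, [0.0, 0.3, 0.7, 1.0]):
            assert km.survival_at(q) == pytest.approx((t > q).mean(),
                                                      abs=1e-12)

    def test_greenwood_and_ci_match_lifelines(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 150)
        e = (rng.random(150) < 0.7).astype(int)
        km = km_fit(t, e)
        from lifelines import KaplanMeierFitter
        kmf = KaplanMeierFitter().fit(t, e)
        for q in (2.0, 5.0, 12.0):
            s, lo, hi = km.survival_ci_at(q)
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(q).iloc[0]), abs=1e-10)
            ci = kmf.confidence_interval_survival_function_
            idx = ci.index[ci.index <= q].max()
            assert lo == pytest.approx(float(ci.loc[idx].iloc[0]), abs=1e-6)
            assert hi == pytest.approx(float(ci.loc[idx].iloc[1]), abs=1e-6)
        from lifelines.utils import median_survival_times
        assert km.median == pytest.approx(kmf.median_survival_time_)

    def test_median_ci_brackets_median(self):
        rng = np.random.default_rng(3)
        t = rng.weibull(1.2, 400) * 12
        e = (rng.random(400) < 0.8).astype(int)
        km = km_fit(t, e)
        assert km.median_ci_low <= km.median <= km.median_ci_high

    def test_calibrated_group_c_reproduces_anchors_at_large_n(self):
        cfg = GeneratorConfig(n_patients=50000, group_probs=(0.0, 0.0, 1.0),
                              censoring=None, missingness_rates={}, seed=30)
        cohort, _ = generate_cohort(cfg)
        km = km_fit(cohort.df["os_months"], cohort.df["os_event"])
        assert km.median == pytest.approx(4.4, rel=0.02)
        assert km.survival_at(24.0) == pytest.approx(0.05, abs=0.01)


class TestLogLogTransform:
    def test_finite_pairs_only(self):
        km = km_fit([1, 2, 3], [1, 1, 0])
        pairs = loglog_transform(km)
        assert pairs.shape == (2, 2)  # S hits 0.33 then stays in (0,1)
        assert np.isfinite(pairs).all()

    def test_all_censored_gives_empty_output(self):
        km = km_fit([1, 2, 3], [0, 0, 0])
        assert loglog_transform(km).size == 0

    def test_proportional_hazards_weibulls_are_parallel(self):
        """Two same-shape Weibull groups: ln(-ln S) curves differ by the
        constant shape*ln(scale ratio)."""
        shape, scale = solve_weibull_anchors(GroupSurvivalAnchor(10.0, 0.28))
        rng = np.random.default_rng(17)
        t1 = scale * rng.weibull(shape, 30000)
        t2 = 2.0 * scale * rng.weibull(shape, 30000)
        grid = np.array([3.0, 8.0, 20.0])
        km1, km2 = (km_fit(t, np.ones_like(t)) for t in (t1, t2))
        off = [math.log(-math.log(km1.survival_at(g)))
               - math.log(-math.log(km2.survival_at(g))) for g in grid]
        expected = shape * math.log(2.0)
        assert np.allclose(off, expected, atol=0.05)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def brute_force_cox_lnhr(x, times):
    """Independent oracle: maximize the hand-written all-event partial
    likelihood for one covariate by bounded scalar optimization."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(times, dtype=float)
    order = np.argsort(t)
    x = x[order]

    def neg_logpl(b):
        ll = 0.0
        for i in range(len(x)):
            risk = x[i:]  # all later or equal subjects at risk (no ties)
            ll += b * x[i] - math.log(np.exp(b * risk).sum())
        return -ll

    res = optimize.minimize_scalar(neg_logpl, bounds=(-8, 8),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x), -float(res.fun)


class TestCox:
    def test_symmetry_gives_null_estimate(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 1, 0, 1, 1, 1, 0]
        x = [0, 0, 0, 0, 1, 1, 1, 1]
        fit = cox_fit(x, t, e)
        assert fit.ln_hr[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-8)

    def test_matches_brute_force_partial_likelihood(self):
        x = [1.0, 0.0, 1.0, 0.0]
        fit = cox_fit(x, [1, 2, 3, 4], [1, 1, 1, 1])
        oracle, _ = brute_force_cox_lnhr(x, [1, 2, 3, 4])
        # closed form for this dataset: ln((1+sqrt(17))/2)
        assert oracle == pytest.approx(math.log((1 + math.sqrt(17)) / 2),
                                       abs=1e-6)
        assert fit.ln_hr[0] == pytest.approx(oracle, abs=1e-6)

    def test_monotone_likelihood_flagged_not_silent(self):
        # both covariate-positive subjects die first: perfect separation
        fit = cox_fit([1, 1, 0, 0], [1, 2, 3, 4], [1, 1, 1, 1])
        assert not fit.converged
        assert "monotone" in fit.diagnostics or "separation" in fit.diagnostics

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(5, 60)  # continuous: ties a.s. absent
        e = (rng.random(60) < 0.7).astype(int)
        x = rng.normal(size=60)
        fe = cox_fit(x, t, e, ties_method="efron")
        fb = cox_fit(x, t, e, ties_method="breslow")
        assert fe.ln_hr[0] == pytest.approx(fb.ln_hr[0], abs=1e-8)
        assert fe.log_likelihood == pytest.approx(fb.log_likelihood,
                                                  abs=1e-8)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_lifelines_with_ties(self, ties):
        import lifelines
        import pandas as pd
        rng = np.random.default_rng(12)
        n = 250
        x = rng.integers(0, 2, n).astype(float)
        z = rng.normal(size=n)
        t = np.round(rng.exponential(1 / np.exp(0.6 * x - 0.3 * z)), 1) + 0.1
        e = (rng.random(n) < 0.75).astype(int)
        ours = cox_fit(np.column_stack([x, z]), t, e, ties_method=ties)
        cph = lifelines.CoxPHFitter()
        cph.fit(pd.DataFrame({"t": t, "e": e, "x": x, "z": z}), "t", "e")
        if ties == "efron":  # lifelines implements Efron ties
            np.testing.assert_allclose(ours.ln_hr, cph.params_.values,
                                       atol=1e-6)
            np.testing.assert_allclose(ours.se,
                                       cph.standard_errors_.values,
                                       atol=1e-6)
        else:
            np.testing.assert_allclose(ours.ln_hr, cph.params_.values,
                                       atol=0.05)

    def test_optimum_beats_null_and_gradient_vanishes(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(3, 120)
        e = (rng.random(120) < 0.8).astype(int)
        x = rng.normal(size=120)
        fit = cox_fit(x, t, e)
        assert fit.converged
        assert fit.log_likelihood >= fit.log_likelihood_null

    def test_degenerate_covariate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cox_fit([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 1, 1])

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_fit([0, 1, 0], [1, 2, 3], [0, 0, 0])


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

class TestLogRank:
    def test_identical_groups_give_null_statistic(self):
        t = [1, 2, 3, 4] * 2
        e = [1, 1, 0, 1] * 2
        g = ["a"] * 4 + ["b"] * 4
        res = logrank_test(t, e, g)
        assert res.chi_square == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-10)

    def test_four_patient_hand_computation(self):
        """Frozen hand computation over the four risk sets:
        O1=2, E1=4/3, V=13/18, chi2=(2/3)^2/(13/18)=8/13."""
        res = logrank_test([1, 3, 2, 4], [1, 1, 1, 1],
                           ["g1", "g1", "g2", "g2"])
        assert res.chi_square == pytest.approx(8 / 13, abs=1e-12)
        assert res.observed.sum() == pytest.approx(res.expected.sum())

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test([1, 2], [1, 1], ["a", "a"])

    def test_distinct_weibulls_detected_at_large_n(self):
        rng = np.random.default_rng(31)
        s1 = solve_weibull_anchors(GroupSurvivalAnchor(10.0, 0.28))
        s2 = solve_weibull_anchors(GroupSurvivalAnchor(4.4, 0.05))
        t = np.concatenate([s1[1] * rng.weibull(s1[0], 800),
                            s2[1] * rng.weibull(s2[0], 800)])
        g = np.repeat([0, 1], 800)
        res = logrank_test(t, np.ones_like(t), g)
        assert res.p_value < 1e-6

    def test_matches_lifelines_three_groups(self):
        from lifelines.statistics import multivariate_logrank_test
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 300)
        e = (rng.random(300) < 0.6).astype(int)
        g = rng.integers(0, 3, 300)
        ours = logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert ours.chi_square == pytest.approx(ref.test_statistic,
                                                rel=1e-10)
        assert ours.df == 2

    def test_two_group_logrank_equals_cox_score_test(self):
        """Asymptotic identity: the two-group log-rank chi-square equals the
        Cox score statistic for the group indicator."""
        rng = np.random.default_rng(14)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / np.exp(0.4 * x))
        e = (rng.random(n) < 0.8).astype(int)
        lr = logrank_test(t, e, x)
        score, _ = cox_score_test_at_zero(x, t, e)
        assert lr.chi_square == pytest.approx(score, rel=1e-6)


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def enumerate_fisher_p(table) -> float:
    """Oracle: sum hypergeometric probabilities of all tables with the
    observed margins no more probable than the observed table."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    rv = stats.hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    ks = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    probs = rv.pmf(ks)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


class TestFisherExact:
    def test_matches_enumeration_on_unbalanced_table(self):
        assert fisher_exact([[1, 9], [9, 1]]) == pytest.approx(
            enumerate_fisher_p([[1, 9], [9, 1]]), abs=1e-12)

    def test_identical_rows_give_p_one(self):
        assert fisher_exact([[5, 7], [5, 7]]) == pytest.approx(1.0)

    def test_thoracic_metastasis_contrast_significant(self):
        # thoracic 58/62 vs nonthoracic 31/44 metastatic at baseline
        assert fisher_exact([[58, 4], [31, 13]]) < 0.01

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact([[0, 0], [3, 4]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])
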