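"""Prognostic statistics: diagnostics, concordance, survival, IDI/NRI."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines.utils import concordance_index as lifelines_cindex
from scipy import stats

from acspredict import evaluation
from acspredict.errors import EvaluationError
from acspredict.evaluation import (cox_fit, diagnostic_summary,
                                   exact_binomial_ci, harrell_c, idi_nri,
                                   km_estimate, nested_logistic_models,
                                   positive_likelihood_ratio, roc_auc,
                                   stepwise_cox, youden_threshold)


def brute_force_youden(scores, labels):
    """Independent exhaustive scan over midpoint thresholds."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    distinct = np.unique(s)
    best = None
    for t in (distinct[:-1] + distinct[1:]) / 2:
        sens = ((s > t) & (y == 1)).sum() / (y == 1).sum()
        spec = ((s <= t) & (y == 0)).sum() / (y == 0).sum()
        j = sens + spec - 1
        if best is None or (j, spec, -t) > (best[1], best[2], -best[0]):
            best = (t, j, spec)
    return best


def brute_force_harrell(scores, time, event):
    """Pair-by-pair enumeration of usable/concordant pairs."""
    n = len(scores)
    conc = usable = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = time[i], time[j]
            if ti == tj:
                if event[i] == event[j]:
                    continue
                a, b = (i, j) if event[i] else (j, i)
            elif ti < tj:
                if not event[i]:
                    continue
                a, b = i, j
            else:
                if not event[j]:
                    continue
                a, b = j, i
            usable += 1
            if scores[a] > scores[b]:
                conc += 1
            elif scores[a] == scores[b]:
                conc += 0.5
    return conc / usable, int(usable)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0

    def test_null_scores_near_half(self, rng):
        s = rng.normal(size=4000)
        y = rng.integers(0, 2, size=4000)
        auc, _ = roc_auc(s, y)
        assert abs(auc - 0.5) < 0.03

    def test_rank_sum_identity(self, rng):
        s = rng.normal(size=60)
        s[:25] += 0.8
        y = np.array([1] * 25 + [0] * 35)
        auc, _ = roc_auc(s, y)
        u = stats.mannwhitneyu(s[y == 1], s[y == 0],
                               alternative="two-sided").statistic
        assert auc == pytest.approx(u / (25 * 35), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc([1, 2], [1, 1])


class TestYouden:
    def test_clean_separation_midpoint(self):
        res = youden_threshold([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.threshold == 2.5
        assert res.youden_j == 1.0

    def test_matches_exhaustive_scan_on_random_data(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            s = np.round(rng.normal(size=n), 2)
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            res = youden_threshold(s, y)
            t_bf, j_bf, spec_bf = brute_force_youden(s, y)
            assert res.youden_j == pytest.approx(j_bf, abs=1e-12)
            assert res.threshold == pytest.approx(t_bf, abs=1e-12)

    def test_all_equal_scores_degenerate(self):
        res = youden_threshold([5, 5, 5, 5], [0, 1, 0, 1])
        assert res.degenerate
        assert res.youden_j == 0.0
        assert res.threshold == 5.0


class TestExactBinomial:
    @pytest.mark.parametrize("x,n,lo,hi", [
        (31, 42, 0.580, 0.861),
        (70, 84, 0.736, 0.906),
        (81, 84, 0.899, 0.993),
        (33, 42, 0.632, 0.897),
        (39, 42, 0.805, 0.985),
    ])
    def test_reference_intervals_3dp(self, x, n, lo, hi):
        got = exact_binomial_ci(x, n)
        assert round(got[0], 3) == lo
        assert round(got[1], 3) == hi

    def test_extremes(self):
        assert exact_binomial_ci(0, 10)[0] == 0.0
        assert exact_binomial_ci(10, 10)[1] == 1.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(5, 4)

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_coverage_at_least_nominal(self, p, rng):
        # Clopper-Pearson is conservative: empirical coverage >= 0.95
        n, reps = 42, 10_000
        x = rng.binomial(n, p, size=reps)
        cover = 0
        for xv, cnt in zip(*np.unique(x, return_counts=True)):
            lo, hi = exact_binomial_ci(int(xv), n)
            cover += cnt * (lo <= p <= hi)
        assert cover / reps >= 0.95


class TestLikelihoodRatio:
    def test_reference_values(self):
        assert positive_likelihood_ratio(0.738, 0.738) == pytest.approx(
            2.82, abs=0.005)
        assert positive_likelihood_ratio(0.786, 0.929) == pytest.approx(
            11.1, abs=0.05)

    def test_zero_specificity_returns_sensitivity(self):
        assert positive_likelihood_ratio(0.6, 0.0) == pytest.approx(0.6)

    def test_perfect_specificity_infinite(self):
        assert math.isinf(positive_likelihood_ratio(0.9, 1.0))


class TestDiagnosticSummary:
    def test_counts_and_identities(self):
        s = [0.1, 0.2, 0.8, 0.9, 0.3, 0.7]
        y = [0, 0, 1, 1, 0, 1]
        d = diagnostic_summary(s, y, threshold=0.5)
        assert (d.tp, d.fp, d.tn, d.fn) == (3, 0, 3, 0)
        assert d.sensitivity == d.tp / (d.tp + d.fn)
        assert d.sensitivity_ci[0] <= d.sensitivity <= d.sensitivity_ci[1]
        assert d.specificity_ci[0] <= d.specificity <= d.specificity_ci[1]


class TestHarrellC:
    def test_perfect_concordance_no_censoring(self):
        t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        s = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        c, ci, usable = harrell_c(s, t, np.ones(5, int))
        assert c == 1.0
        assert usable == 10

    def test_matches_pairwise_enumeration(self, rng):
        n = 20
        s = rng.normal(size=n)
        t = rng.exponential(2, size=n)
        e = rng.integers(0, 2, size=n)
        e[0] = 1
        c, ci, usable = harrell_c(s, t, e)
        c_bf, usable_bf = brute_force_harrell(s, t, e)
        assert c == pytest.approx(c_bf, abs=1e-12)
        assert usable == usable_bf

    def test_matches_lifelines_on_continuous_times(self, rng):
        n = 80
        s = rng.normal(size=n)
        t = rng.exponential(3, size=n)
        e = rng.integers(0, 2, size=n)
        e[:5] = 1
        c, _, _ = harrell_c(s, t, e)
        # lifelines orders by predicted survival (higher = later event),
        # so pass the negated risk score
        assert c == pytest.approx(lifelines_cindex(t, -s, e), abs=1e-12)

    def test_all_censored_rejected(self):
        with pytest.raises(EvaluationError):
            harrell_c([1, 2, 3], [1, 2, 3], [0, 0, 0])

    def test_reduces_to_auc_without_censoring(self, rng):
        # cases given earlier "times" than controls: usable pairs are
        # exactly the case-control pairs, so c equals the ROC AUC
        n = 50
        s = rng.normal(size=n)
        y = rng.integers(0, 2, size=n)
        y[:3] = [0, 1, 0]
        t = 2.0 - y  # cases at t=1, controls at t=2
        c, _, _ = harrell_c(s, t, np.ones(n, int) * (t == 1.0))
        auc, _ = roc_auc(s, y)
        assert c == pytest.approx(auc, abs=1e-12)

    def test_ci_brackets_point_estimate(self, rng):
        s = rng.normal(size=40)
        t = rng.exponential(2, size=40)
        e = np.ones(40, int)
        c, (lo, hi), _ = harrell_c(s, t, e)
        assert lo <= c <= hi


class TestKaplanMeier:
    def test_no_events_flat_zero(self):
        km = km_estimate([1, 2, 3, 4], [0, 0, 0, 0], ["g"] * 4)
        assert (km["g"]["cum_event_pct"] == 0).all()

    def test_no_censoring_matches_ecdf(self, rng):
        t = rng.exponential(2, size=60)
        km = km_estimate(t, np.ones(60, int), ["g"] * 60)["g"]
        with_events = km[km["events"] > 0]
        for _, row in with_events.iterrows():
            ecdf = (t <= row["time"]).mean()
            assert row["cum_event_pct"] / 100 == pytest.approx(ecdf,
                                                               abs=1e-12)

    def test_sample_order_invariance(self, rng):
        t = rng.exponential(2, size=30)
        e = rng.integers(0, 2, size=30)
        g = np.array(["a", "b"] * 15)
        perm = rng.permutation(30)
        km1 = km_estimate(t, e, g)
        km2 = km_estimate(t[perm], e[perm], g[perm])
        for key in km1:
            pd.testing.assert_frame_equal(km1[key], km2[key])


class TestCox:
    def make_two_group(self, rng, n=500, hr=3.0, censor=False):
        x = rng.integers(0, 2, size=n)
        t = rng.exponential(1.0 / (0.2 * hr ** x))
        e = np.ones(n, int)
        if censor:
            c = rng.exponential(5.0, size=n)
            e = (t <= c).astype(int)
            t = np.minimum(t, c)
        return pd.DataFrame({"time": t, "event": e, "x": x})

    def test_null_covariate_hr_near_one(self, rng):
        df = self.make_two_group(rng, hr=1.0)
        fit = cox_fit(df, "time", "event", ["x"])
        assert fit.loc["x", "hr"] == pytest.approx(1.0, abs=0.25)
        assert fit.loc["x", "p"] > 0.01

    def test_known_hazard_ratio_recovered(self, rng):
        df = self.make_two_group(rng, n=500, hr=3.0)
        fit = cox_fit(df, "time", "event", ["x"])
        assert 2.5 <= fit.loc["x", "hr"] <= 3.6
        assert fit.loc["x", "hr_lo"] <= fit.loc["x", "hr"] <= \
            fit.loc["x", "hr_hi"]

    def test_duplication_keeps_hr_halves_variance(self, rng):
        df = self.make_two_group(rng, n=200, hr=2.0)
        fit1 = cox_fit(df, "time", "event", ["x"])
        fit2 = cox_fit(pd.concat([df, df], ignore_index=True),
                       "time", "event", ["x"])
        assert fit2.loc["x", "hr"] == pytest.approx(fit1.loc["x", "hr"],
                                                    rel=1e-6)
        assert fit2.loc["x", "se"] ** 2 == pytest.approx(
            fit1.loc["x", "se"] ** 2 / 2, rel=0.02)

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0],
                           "x": [0, 1]})
        with pytest.raises(EvaluationError):
            cox_fit(df, "time", "event", ["x"])

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1],
                           "x": [1, 1]})
        with pytest.raises(EvaluationError):
            cox_fit(df, "time", "event", ["x"])


class TestStepwiseCox:
    def test_strong_covariates_all_kept(self, rng):
        n = 400
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.2 * np.exp(1.0 * x1 + 1.0 * x2)))
        df = pd.DataFrame({"time": t, "event": 1, "x1": x1, "x2": x2})
        kept, fit, trace = stepwise_cox(df, "time", "event", ["x1", "x2"])
        assert set(kept) == {"x1", "x2"}
        assert not trace

    def test_planted_predictor_survives_noise(self, rng):
        n = 500
        x = rng.normal(size=n)
        noise = {f"z{i}": rng.normal(size=n) for i in range(4)}
        t = rng.exponential(1.0 / (0.2 * np.exp(1.2 * x)))
        df = pd.DataFrame({"time": t, "event": 1, "x": x, **noise})
        kept, fit, trace = stepwise_cox(df, "time", "event",
                                        ["x"] + list(noise))
        assert "x" in kept

    def test_empty_candidates_empty_result(self, rng):
        df = pd.DataFrame({"time": rng.exponential(size=20), "event": 1,
                           "x": rng.normal(size=20)})
        kept, fit, trace = stepwise_cox(df, "time", "event", [],
                                        forced=["x"])
        assert kept == ["x"]


class TestNestedLogistic:
    def test_single_centre_terms_dropped(self, rng):
        n = 200
        f = rng.uniform(0, 1, size=n)
        y = rng.binomial(1, f)
        out = nested_logistic_models(y, ["A"] * n, f)
        assert out["p1"].shape == (n,)

    def test_collinear_extra_score_changes_nothing(self, rng):
        n = 300
        f = rng.uniform(0.05, 0.95, size=n)
        y = rng.binomial(1, f)
        out = nested_logistic_models(y, ["A"] * n, f, pattern_scores=f)
        np.testing.assert_allclose(out["p1"], out["p2"], atol=1e-4)

    def test_coefficient_recovery_within_2se(self, rng):
        n = 1500
        f = rng.normal(size=n)
        s = rng.normal(size=n)
        eta = -0.3 + 0.8 * f + 0.5 * s
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        import statsmodels.api as sm
        X = np.column_stack([np.ones(n), f, s])
        ref = sm.Logit(y, X).fit(disp=0)
        out = nested_logistic_models(y, ["A"] * n, f, pattern_scores=s)
        np.testing.assert_allclose(out["p2"], ref.predict(X), atol=1e-6)
        assert abs(ref.params[1] - 0.8) < 2 * ref.bse[1] + 0.05
        assert abs(ref.params[2] - 0.5) < 2 * ref.bse[2] + 0.05


class TestIdiNri:
    def test_no_change_is_zero(self, rng):
        p = rng.uniform(0, 1, size=40)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        rep = idi_nri(p, p, y)
        assert rep.idi == 0.0
        assert rep.nri == 0.0

    def test_nri_hand_computed_example(self):
        # events: 2 up, 1 down of 10; non-events: 1 up, 3 down of 10
        # NRI = (0.2 - 0.1) - (0.1 - 0.3) = 0.30
        p_old = np.array([0.05] * 10 + [0.15] * 10)
        p_new = p_old.copy()
        p_new[[0, 1]] = 0.15     # events up
        p_new[[2]] = 0.05        # would be same category -> keep at low
        p_old[2] = 0.15
        p_new[2] = 0.05          # event down
        p_new[[10]] = 0.25       # non-event up
        p_new[[11, 12, 13]] = 0.05  # non-events down
        y = np.array([1] * 10 + [0] * 10)
        rep = idi_nri(p_old, p_new, y)
        assert rep.nri == pytest.approx(0.30, abs=1e-12)

    def test_idi_equals_discrimination_slope_difference(self, rng):
        n = 200
        p_old = rng.uniform(0, 1, size=n)
        p_new = np.clip(p_old + rng.normal(0, 0.1, size=n), 0, 1)
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        rep = idi_nri(p_old, p_new, y)
        slope_new = p_new[y == 1].mean() - p_new[y == 0].mean()
        slope_old = p_old[y == 1].mean() - p_old[y == 0].mean()
        assert rep.idi == pytest.approx(slope_new - slope_old, abs=1e-12)

    def test_sign_flips_when_models_swapped(self, rng):
        n = 100
        p_old = rng.uniform(0, 1, size=n)
        p_new = np.clip(p_old + rng.normal(0, 0.15, size=n), 0, 1)
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        a = idi_nri(p_old, p_new, y)
        b = idi_nri(p_new, p_old, y)
        assert a.idi == pytest.approx(-b.idi)
        assert a.nri == pytest.approx(-b.nri)

    def test_movement_table_rows_sum_to_group_sizes(self, rng):
        n = 80
        p_old = rng.uniform(0, 1, size=n)
        p_new = rng.uniform(0, 1, size=n)
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        rep = idi_nri(p_old, p_new, y)
        assert rep.movement_events.to_numpy().sum() == (y == 1).sum()
        assert rep.movement_nonevents.to_numpy().sum() == (y == 0).sum()

    def test_category_boundaries_left_closed(self):
        # 0.10 is intermediate, 0.20 is high
        p_old = np.array([0.099, 0.10, 0.199, 0.20])
        from acspredict.evaluation import _category_index
        np.testing.assert_array_equal(_category_index(p_old, (0.10, 0.20)),
                                      [0, 1, 1, 2])
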