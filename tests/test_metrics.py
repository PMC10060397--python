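"""Concordance, Brier/IBS, Composite Score, Kaplan–Meier, log-rank."""

import numpy as np
import pytest

from coxfuse.metrics import (MetricsReport, StepPredictor, SurvivalCurve,
                             UndefinedMetricError, brier_score,
                             censoring_curve, composite_score,
                             concordance_index, integrated_brier_score,
                             kaplan_meier, logrank_test, median_risk_split,
                             survival_curves_from_risks)

from conftest import make_records


def enumerate_ci(scores, times, events):
    """Exhaustive admissible-pair enumeration, independent of the
    vectorized implementation."""
    conc = adm = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                adm += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    conc += 0.5
    for i in range(n):
        for j in range(i + 1, n):
            if times[i] == times[j] and events[i] == 1 and events[j] == 1:
                adm += 1
                conc += 1.0 if scores[i] == scores[j] else 0.5
    return conc / adm


class TestConcordance:
    def test_perfect_ordering_gives_one(self):
        recs = make_records([1, 2, 3, 4, 5], [1] * 5)
        assert concordance_index([-1, -2, -3, -4, -5], recs) == 1.0

    def test_reversed_ordering_gives_zero(self):
        recs = make_records([1, 2, 3, 4], [1] * 4)
        assert concordance_index([1, 2, 3, 4], recs) == 0.0

    def test_censored_example(self):
        recs = make_records([1, 2, 3, 4], [1, 0, 1, 1])
        assert concordance_index([4, 3, 1, 2], recs) == pytest.approx(0.75)

    def test_matches_exhaustive_enumerator_on_random_cohorts(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(3, 12))
            times = rng.choice([1.0, 2.0, 3.0, 3.0, 7.0], n)
            events = rng.integers(0, 2, n)
            scores = rng.choice([-1.0, 0.0, 0.5, 2.0], n)
            recs = make_records(times, events)
            try:
                got = concordance_index(scores, recs)
            except UndefinedMetricError:
                continue
            assert got == pytest.approx(
                enumerate_ci(scores, times, events), rel=1e-12)

    def test_complement_identity_without_score_ties(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(5, 25) + 0.1
        events = rng.integers(0, 2, 25)
        scores = rng.normal(0, 1, 25)
        recs = make_records(times, events)
        assert concordance_index(scores, recs) + concordance_index(
            -scores, recs) == pytest.approx(1.0)

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(5)
        n = 2000
        recs = make_records(rng.exponential(5, n) + 0.1, np.ones(n, int))
        ci = concordance_index(rng.normal(0, 1, n), recs)
        assert abs(ci - 0.5) < 0.02

    def test_no_admissible_pairs_is_an_error(self):
        recs = make_records([1.0, 2.0], [0, 0])
        with pytest.raises(UndefinedMetricError):
            concordance_index([0.1, 0.2], recs)

    def test_agrees_with_scikit_survival(self, censored_cohort):
        from sksurv.metrics import concordance_index_censored

        scores = np.random.default_rng(6).normal(0, 1, len(censored_cohort))
        events = np.array([r.event for r in censored_cohort], dtype=bool)
        times = np.array([r.time for r in censored_cohort])
        ref = concordance_index_censored(events, times, scores)[0]
        got = concordance_index(scores, censored_cohort)
        assert got == pytest.approx(ref, abs=1e-10)


class TestKaplanMeier:
    def test_uniform_product_limit_steps(self):
        curve = kaplan_meier(make_records([1, 2, 3, 4], [1] * 4))
        assert curve.survival[0] == 1.0
        np.testing.assert_allclose(
            curve.evaluate([1.0, 2.0, 3.0, 4.0]), [0.75, 0.5, 0.25, 0.0])

    def test_censoring_drops_at_risk_not_survival(self):
        # times [1, 2+, 3]: S = 2/3 after t=1, unchanged at t=2, 0 after t=3
        curve = kaplan_meier(make_records([1, 2, 3], [1, 0, 1]))
        assert curve.evaluate(1.0) == pytest.approx(2 / 3)
        assert curve.evaluate(2.5) == pytest.approx(2 / 3)
        assert curve.evaluate(3.0) == pytest.approx(0.0)

    def test_starts_at_one_and_non_increasing_on_random_cohorts(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(1, 30))
            recs = make_records(rng.exponential(3, n) + 0.05,
                                rng.integers(0, 2, n))
            curve = kaplan_meier(recs)
            assert curve.survival[0] == 1.0
            assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_matches_hand_product_limit(self):
        recs = make_records([2, 2, 4, 5, 5, 8], [1, 0, 1, 1, 0, 1])
        curve = kaplan_meier(recs)
        # hand product-limit: t=2: 1*(1-1/6)=5/6; t=4: *(1-1/4)=5/8;
        # t=5: *(1-1/3)=5/12; t=8: *(1-1/1)=0
        assert curve.evaluate(2) == pytest.approx(5 / 6)
        assert curve.evaluate(4) == pytest.approx(5 / 8)
        assert curve.evaluate(5) == pytest.approx(5 / 12)
        assert curve.evaluate(8) == pytest.approx(0.0)


class TestBrier:
    def test_indicator_predictions_are_exact(self, uncensored_cohort):
        times = np.array([r.time for r in uncensored_cohort])
        g = censoring_curve(uncensored_cohort)
        for t in np.quantile(times, [0.2, 0.5, 0.9]):
            preds = (times > t).astype(float)
            assert brier_score(t, preds, uncensored_cohort, g) == \
                pytest.approx(0.0, abs=1e-12)

    def test_constant_half_prediction_gives_quarter(self, uncensored_cohort):
        g = censoring_curve(uncensored_cohort)
        t = float(np.median([r.time for r in uncensored_cohort]))
        preds = np.full(len(uncensored_cohort), 0.5)
        assert brier_score(t, preds, uncensored_cohort, g) == \
            pytest.approx(0.25)

    def test_hand_computed_weighted_sum_with_censoring(self):
        # five patients, one censored before t; weights via censoring KM
        recs = make_records([1, 2, 3, 4, 5], [1, 0, 1, 1, 1])
        g = censoring_curve(recs)
        t = 3.5
        preds = np.array([0.1, 0.9, 0.4, 0.8, 0.7])
        # censoring KM: one censor event at t=2 with 4 at risk -> G=3/4 after 2
        # events before t: P0 (T=1, G(1-)=1): 0.1^2; P2 (T=3, G(3-)=0.75): 0.4^2/0.75
        # at risk beyond t: P3, P4 with G(3.5)=0.75: (1-0.8)^2/0.75+(1-0.7)^2/0.75
        # censored before t: P1 contributes 0
        expected = (0.01 + 0.16 / 0.75 + (0.04 + 0.09) / 0.75) / 5
        assert brier_score(t, preds, recs, g) == pytest.approx(expected)

    def test_matches_brute_force_on_small_cohorts(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            times = np.sort(rng.exponential(3, n)) + 0.1
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                continue
            recs = make_records(times, events)
            g = censoring_curve(recs)
            preds = rng.random(n)
            t = float(rng.uniform(0, times[-2]))
            try:
                got = brier_score(t, preds, recs, g)
            except UndefinedMetricError:
                continue
            total = 0.0
            for i in range(n):
                if times[i] <= t and events[i] == 1:
                    total += preds[i] ** 2 / g.evaluate_left(times[i])
                elif times[i] > t:
                    total += (1 - preds[i]) ** 2 / g.evaluate(t)
            assert got == pytest.approx(total / n, rel=1e-10)


class TestIntegratedBrier:
    def _indicator_curves(self, recs, anti=False):
        times = np.array([r.time for r in recs])
        grid = np.concatenate([[0.0], np.unique(times)])
        curves = []
        for ti in times:
            vals = (grid < ti).astype(float)
            if anti:
                vals = 1.0 - vals
            curves.append(StepPredictor(times=grid, values=vals))
        return curves

    def test_indicator_predictions_give_zero(self, uncensored_cohort):
        curves = self._indicator_curves(uncensored_cohort)
        assert integrated_brier_score(curves, uncensored_cohort) == \
            pytest.approx(0.0, abs=1e-12)

    def test_anti_indicator_predictions_give_one(self, uncensored_cohort):
        curves = self._indicator_curves(uncensored_cohort, anti=True)
        assert integrated_brier_score(curves, uncensored_cohort) == \
            pytest.approx(1.0, abs=1e-12)

    def test_constant_half_gives_quarter(self, uncensored_cohort):
        times = np.array([r.time for r in uncensored_cohort])
        grid = np.concatenate([[0.0], np.unique(times)])
        curves = [StepPredictor(times=grid, values=np.full(len(grid), 0.5))
                  for _ in uncensored_cohort]
        assert integrated_brier_score(curves, uncensored_cohort) == \
            pytest.approx(0.25)

    def test_single_time_point_is_an_error(self):
        recs = make_records([2.0, 2.0], [1, 1])
        grid = np.array([0.0, 2.0])
        curves = [StepPredictor(times=grid, values=[1.0, 0.5])] * 2
        with pytest.raises(UndefinedMetricError):
            integrated_brier_score(curves, recs)

    def test_bounded_on_random_inputs(self, censored_cohort):
        rng = np.random.default_rng(9)
        scores = rng.normal(0, 1, len(censored_cohort))
        curves = survival_curves_from_risks(censored_cohort, scores, scores)
        ibs = integrated_brier_score(curves, censored_cohort)
        assert 0.0 <= ibs <= 1.0


class TestCompositeScore:
    @pytest.mark.parametrize("ci,ibs,expected", [
        (1.0, 0.0, 1.0), (0.5, 0.5, 0.5), (0.8, 0.2, 0.8)])
    def test_formula(self, ci, ibs, expected):
        assert composite_score(ci, ibs) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            composite_score(1.2, 0.0)
        with pytest.raises(ValueError):
            composite_score(0.5, -0.1)

    def test_report_consistency_enforced(self):
        with pytest.raises(ValueError):
            MetricsReport(ci=0.7, ibs=0.1, cs=0.99, logrank_p=0.5, n=10)
        rep = MetricsReport.build(ci=0.7, ibs=0.1, logrank_p=0.5, n=10)
        assert rep.cs == pytest.approx((0.7 + 0.9) / 2, abs=1e-12)


class TestMedianSplit:
    def test_even_split(self):
        split = median_risk_split([1, 2, 3, 4], list("abcd"))
        assert split.poor_ids == {"c", "d"}
        assert split.good_ids == {"a", "b"}
        assert split.threshold == 2.5

    def test_ties_at_median_go_to_good_group(self):
        split = median_risk_split([1, 2, 2, 3], list("abcd"))
        assert split.poor_ids == {"d"}
        assert split.good_ids == {"a", "b", "c"}

    def test_partition_and_threshold_property(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(0, 1, 156)
        ids = [f"p{i}" for i in range(156)]
        split = median_risk_split(scores, ids)
        assert len(split.poor_ids) + len(split.good_ids) == 156
        assert split.poor_ids.isdisjoint(split.good_ids)
        by_id = dict(zip(ids, scores))
        assert max(by_id[i] for i in split.good_ids) <= split.threshold
        assert min(by_id[i] for i in split.poor_ids) > split.threshold

    def test_identical_scores_warn_and_fill_good(self):
        with pytest.warns(RuntimeWarning):
            split = median_risk_split([1.0, 1.0, 1.0], list("abc"))
        assert split.poor_ids == set()
        assert split.good_ids == {"a", "b", "c"}


class TestLogRank:
    def test_identical_groups(self):
        recs = make_records([1, 2, 3, 4, 5], [1] * 5)
        stat, p = logrank_test(recs, recs)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_clearly_separated_groups(self):
        a = make_records(np.full(20, 1.0), np.ones(20, int), prefix="A")
        b = make_records(np.full(20, 10.0), np.ones(20, int), prefix="B")
        stat, p = logrank_test(a, b)
        assert p < 0.001
        assert stat > 10

    def test_zero_events_is_an_error(self):
        a = make_records([1, 2], [0, 0], prefix="A")
        b = make_records([3, 4], [0, 0], prefix="B")
        with pytest.raises(UndefinedMetricError):
            logrank_test(a, b)

    def test_permutation_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(11)
        times = rng.exponential(5, 40) + 0.1
        events = rng.integers(0, 2, 40)
        ps = []
        for _ in range(500):
            labels = rng.permutation(40) < 20
            a = make_records(times[labels], events[labels], prefix="A")
            b = make_records(times[~labels], events[~labels], prefix="B")
            ps.append(logrank_test(a, b)[1])
        ps = np.array(ps)
        # under the null, P(p < q) should be about q
        for q in (0.1, 0.25, 0.5):
            assert abs(np.mean(ps < q) - q) < 0.08


class TestBreslowCurves:
    def test_homogeneous_scores_give_common_baseline(self):
        recs = make_records([1, 2, 3], [1, 0, 1])
        curves = survival_curves_from_risks(recs, [0.2, 0.2, 0.2],
                                            [0.2, 0.2])
        np.testing.assert_allclose(curves[0].survival, curves[1].survival)
        assert curves[0].survival[0] == 1.0

    def test_higher_risk_means_lower_survival_everywhere(self, censored_cohort):
        rng = np.random.default_rng(12)
        scores = rng.normal(0, 1, len(censored_cohort))
        curves = survival_curves_from_risks(censored_cohort, scores,
                                            [-1.0, 0.0, 2.0])
        s_low, s_mid, s_high = (c.survival for c in curves)
        assert np.all(s_high <= s_mid + 1e-12)
        assert np.all(s_mid <= s_low + 1e-12)

    def test_matches_independent_breslow_estimator(self):
        rng = np.random.default_rng(13)
        n = 10
        times = np.sort(rng.exponential(2, n)) + 0.1
        events = np.array([1, 1, 0, 1, 1, 0, 1, 1, 1, 0])
        scores = rng.normal(0, 0.5, n)
        recs = make_records(times, events)
        curves = survival_curves_from_risks(recs, scores, scores)
        mu = scores.mean()
        w = np.exp(scores - mu)
        for i in range(n):
            h0 = 0.0
            for k in range(n):
                if events[k] == 1 and times[k] <= times[i]:
                    h0 += 1.0 / np.sum(w[times >= times[k]])
            expected = np.exp(-h0 * w[i])
            assert curves[i].evaluate(times[i]) == pytest.approx(expected,
                                                                 abs=1e-6)
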