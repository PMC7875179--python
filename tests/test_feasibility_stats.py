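import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psyscreen.alert_workflow import AlertCase
from psyscreen.feasibility_stats import (
    adherence_proportion,
    channel_distribution,
    cumulative_incidence_at,
    fisher_exact_2x2,
    km_curve,
    logrank_test,
    t_from_summary,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def responded_case(pid="p", channel="EMAIL1"):
    return AlertCase(pid, 0, state="RESPONDED", response_channel=channel, response_week=0)


class TestAdherence:
    def test_published_counts(self, funnel_fixture):
        assert adherence_proportion(funnel_fixture.cases) == pytest.approx(
            89 / 115, abs=1e-12
        )

    def test_all_respond(self):
        cases = [responded_case(f"p{i}") for i in range(5)]
        assert adherence_proportion(cases) == 1.0

    def test_random_fixture_against_tally(self):
        cases = [responded_case(f"p{i}") for i in range(7)]
        cases += [AlertCase(f"q{i}", 0, state="NO_RESPONSE") for i in range(13)]
        cases += [AlertCase(f"r{i}", 0, state="NO_CONTACT") for i in range(3)]
        assert adherence_proportion(cases) == pytest.approx(7 / 20)

    def test_zero_prompted_signalled(self):
        with pytest.raises(ValueError, match="prompted"):
            adherence_proportion([AlertCase("p", 0, state="NO_CONTACT")])

    def test_channel_distribution_shares(self, funnel_fixture):
        dist = channel_distribution(funnel_fixture.cases)
        assert dist["EMAIL1"] == (33, pytest.approx(33 / 89))
        assert dist["PHONE"] == (30, pytest.approx(30 / 89))


class TestFisherExact:
    def test_personalization_comparison(self):
        res = fisher_exact_2x2([[44, 31], [15, 25]])
        assert round(res.estimate, 2) == 2.35
        assert round(res.ci_low, 2) == 1.00
        assert round(res.ci_high, 2) == 5.64
        assert round(res.p_value, 2) == 0.03

    def test_outreach_comparison(self):
        res = fisher_exact_2x2([[29, 5], [60, 21]])
        assert round(res.estimate, 2) == 2.02
        assert round(res.ci_low, 2) == 0.65
        assert round(res.ci_high, 2) == 7.55
        assert round(res.p_value, 2) == 0.23

    def test_balanced_table(self):
        res = fisher_exact_2x2([[10, 10], [10, 10]])
        assert res.estimate == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_margin_flagged(self):
        res = fisher_exact_2x2([[0, 10], [0, 5]])
        assert res.p_value == 1.0
        assert res.estimate is None
        assert res.note == "degenerate margin"

    @given(
        a=st.integers(0, 25),
        b=st.integers(0, 25),
        c=st.integers(0, 25),
        d=st.integers(0, 25),
    )
    def test_symmetries(self, a, b, c, d):
        tab = np.array([[a, b], [c, d]])
        if tab.sum() == 0 or a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
            return
        base = fisher_exact_2x2(tab)
        transposed = fisher_exact_2x2(tab.T)
        swapped = fisher_exact_2x2(tab[::-1])
        both = fisher_exact_2x2(tab[::-1, ::-1])
        assert base.p_value == pytest.approx(transposed.p_value, rel=1e-9)
        assert base.p_value == pytest.approx(both.p_value, rel=1e-9)
        if base.estimate is not None and swapped.estimate is not None:
            if base.estimate > 0 and np.isfinite(base.estimate):
                assert swapped.estimate == pytest.approx(
                    1 / base.estimate, rel=1e-6
                )


def brute_force_km(times, events, t):
    """Literal product over risk sets (events before censorings at ties)."""
    s = 1.0
    for et in sorted({ti for ti, ei in zip(times, events) if ei}):
        if et > t:
            break
        n = sum(ti >= et for ti in times)
        d = sum(ti == et and ei for ti, ei in zip(times, events))
        s *= 1 - d / n
    return s


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        curve = km_curve([3, 5, 8, 9, 11], [0, 0, 0, 0, 0])
        assert curve.times.size == 0
        assert curve.survival_at(10) == 1.0

    def test_hand_product_limit(self):
        curve = km_curve([1, 2, 2, 3], [1, 1, 0, 1])
        assert curve.survival == pytest.approx([0.75, 0.5, 0.0])
        # Greenwood at t=2: 0.25 * (1/12 + 1/6)
        assert curve.greenwood_var[1] == pytest.approx(0.0625)
        assert np.sqrt(curve.greenwood_var[1]) == pytest.approx(0.25)

    def test_ci_clipped_and_contains_estimate(self):
        curve = km_curve([1, 2, 2, 3], [1, 1, 0, 1])
        assert (curve.ci_low >= 0).all() and (curve.ci_high <= 1).all()
        assert (curve.ci_low <= curve.survival).all()
        assert (curve.survival <= curve.ci_high).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_curve([], [])

    @given(
        data=st.lists(
            st.tuples(st.integers(1, 15), st.booleans()), min_size=1, max_size=60
        ),
        t=st.integers(0, 16),
    )
    def test_matches_brute_force_product(self, data, t):
        times = [d[0] for d in data]
        events = [d[1] for d in data]
        curve = km_curve(times, events)
        assert curve.survival_at(t) == pytest.approx(
            brute_force_km(times, events, t), abs=1e-12
        )

    def test_no_censoring_matches_empirical_cdf(self):
        rng = np.random.default_rng(1)
        times = rng.integers(1, 50, 200)
        curve = km_curve(times, np.ones(200, bool))
        for t in (5, 10, 25, 49):
            assert 1 - curve.survival_at(t) == pytest.approx(np.mean(times <= t))

    def test_agrees_with_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        times = rng.integers(1, 30, 120)
        events = rng.random(120) < 0.6
        curve = km_curve(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for i, t in enumerate(curve.times):
            assert curve.survival[i] == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-12
            )


class TestCumulativeIncidence:
    def test_zero_before_first_event(self):
        curve = km_curve([5, 6, 7], [1, 1, 0])
        inc = cumulative_incidence_at(curve, 2)
        assert inc.incidence == 0.0
        assert inc.ci_low == 0.0 == inc.ci_high

    def test_toy_curve_at_two(self):
        curve = km_curve([1, 2, 2, 3], [1, 1, 0, 1])
        inc = cumulative_incidence_at(curve, 2, all_times=[1, 2, 2, 3])
        assert inc.incidence == pytest.approx(0.5)
        assert not inc.extrapolated

    def test_everyone_converts(self):
        curve = km_curve([1, 2, 3], [1, 1, 1])
        assert cumulative_incidence_at(curve, 3).incidence == pytest.approx(1.0)

    def test_extrapolation_flagged(self):
        curve = km_curve([1, 2], [1, 0])
        inc = cumulative_incidence_at(curve, 10)
        assert inc.extrapolated

    def test_monotone_in_time(self):
        rng = np.random.default_rng(4)
        times = rng.integers(1, 40, 100)
        events = rng.random(100) < 0.5
        curve = km_curve(times, events)
        vals = [cumulative_incidence_at(curve, t).incidence for t in range(0, 45)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


def hand_logrank(times_a, events_a, times_b, events_b):
    """O-E/V tables computed longhand over pooled event times."""
    t = list(times_a) + list(times_b)
    e = list(events_a) + list(events_b)
    g = [1] * len(times_a) + [0] * len(times_b)
    o_e, v = 0.0, 0.0
    for et in sorted({ti for ti, ei in zip(t, e) if ei}):
        n = sum(ti >= et for ti in t)
        n1 = sum(ti >= et and gi for ti, gi in zip(t, g))
        d = sum(ti == et and ei for ti, ei in zip(t, e))
        d1 = sum(ti == et and ei and gi for ti, ei, gi in zip(t, e, g))
        o_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_e**2 / v


class TestLogRank:
    def test_identical_groups_null(self):
        t = [2, 4, 6, 8]
        e = [1, 0, 1, 1]
        res = logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_hand_computation(self):
        ta, ea = [1, 4, 6], [1, 1, 0]
        tb, eb = [2, 3, 5], [1, 0, 1]
        res = logrank_test(ta, ea, tb, eb)
        assert res.statistic == pytest.approx(hand_logrank(ta, ea, tb, eb), abs=1e-6)

    def test_separated_exponentials_significant(self):
        rng = np.random.default_rng(8)
        ta = rng.exponential(1.0, 200)
        tb = rng.exponential(4.0, 200)
        res = logrank_test(ta, np.ones(200, bool), tb, np.ones(200, bool))
        assert res.p_value < 0.001

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(12)
        ta = rng.integers(1, 20, 30)
        ea = rng.random(30) < 0.7
        tb = rng.integers(1, 20, 40)
        eb = rng.random(40) < 0.7
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_agrees_with_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(13)
        ta = rng.integers(1, 25, 80)
        ea = rng.random(80) < 0.6
        tb = rng.integers(1, 20, 70)
        eb = rng.random(70) < 0.6
        ours = logrank_test(ta, ea, tb, eb)
        theirs = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert ours.statistic == pytest.approx(theirs.test_statistic, abs=1e-9)
        assert ours.p_value == pytest.approx(theirs.p_value, abs=1e-9)

    def test_no_events_signalled(self):
        with pytest.raises(ValueError, match="events"):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])


class TestTTest:
    def test_published_age_comparison(self):
        res = t_from_summary(37.51, 18.44, 3722, 39.05, 18.27, 88)
        assert round(res.statistic, 2) == -0.78
        assert res.p_value == pytest.approx(0.437, abs=0.001)

    def test_identical_summaries(self):
        res = t_from_summary(10, 2, 50, 10, 2, 50)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_raw_data_welch(self):
        from scipy import stats

        rng = np.random.default_rng(21)
        x = rng.normal(5, 2, 40)
        y = rng.normal(6, 3, 25)
        res = t_from_summary(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        raw = stats.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(raw.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(raw.pvalue, abs=1e-12)

    def test_pooled_option_matches_raw(self):
        from scipy import stats

        rng = np.random.default_rng(22)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 30)
        res = t_from_summary(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y),
            equal_var=True,
        )
        raw = stats.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(raw.statistic, abs=1e-12)
        assert res.df == len(x) + len(y) - 2

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            t_from_summary(1, 1, 1, 2, 1, 10)
        with pytest.raises(ValueError):
            t_from_summary(1, 0, 10, 2, 1, 10)
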