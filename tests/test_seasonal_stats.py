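import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from _oracles import tukey_permutation_pvalue
from seasonwave import (
    DegenerateSeriesError,
    WeeklySeries,
    anova_from_summary,
    one_way_anova,
    percent_change_year,
    season_windows_for,
    summarize_changes,
    tukey_hsd,
)


def series_from(values, start="2012-08-05"):
    weeks = pd.date_range(start, periods=len(values), freq="7D")
    return WeeklySeries("t", weeks, values)


YEAR1 = (pd.Timestamp("2012-08-05"), pd.Timestamp("2013-08-04"))


class TestPercentChange:
    def test_constant_series_changes_zero_percent(self):
        s = series_from(np.full(261, 50.0))
        assert percent_change_year(s, YEAR1) == pytest.approx(0.0)

    def test_peak_over_trough_arithmetic(self):
        # winter peak 80 vs summer trough 50 -> 60% higher in winter
        values = np.full(261, 50.0)
        weeks = pd.date_range("2012-08-05", periods=261, freq="7D")
        values[(weeks >= "2012-12-01") & (weeks < "2013-01-01")] = 80.0
        s = WeeklySeries("t", weeks, values)
        assert percent_change_year(s, YEAR1) == pytest.approx(60.0)

    def test_magnitude_matches_study_scale(self):
        # winter peak 100, summer trough 69 -> 44.9%, the scale reported
        # for the strongest seasonal terms
        values = np.full(261, 69.0)
        weeks = pd.date_range("2012-08-05", periods=261, freq="7D")
        values[(weeks >= "2013-01-01") & (weeks < "2013-02-01")] = 100.0
        s = WeeklySeries("t", weeks, values)
        assert percent_change_year(s, YEAR1) == pytest.approx(44.93, abs=0.01)

    def test_zero_trough_is_degenerate(self):
        values = np.full(261, 50.0)
        weeks = pd.date_range("2012-08-05", periods=261, freq="7D")
        values[(weeks >= "2013-05-01") & (weeks < "2013-06-01")] = 0.0
        with pytest.raises(DegenerateSeriesError):
            percent_change_year(WeeklySeries("t", weeks, values), YEAR1)

    def test_overlapping_windows_rejected(self):
        s = series_from(np.full(261, 50.0))
        with pytest.raises(ValueError):
            percent_change_year(
                s,
                YEAR1,
                winter_window=(pd.Timestamp("2012-10-01"), pd.Timestamp("2013-04-01")),
                summer_window=(pd.Timestamp("2013-03-01"), pd.Timestamp("2013-08-01")),
            )

    def test_default_season_windows_are_disjoint_and_inside(self):
        (w0, w1), (s0, s1) = season_windows_for(YEAR1)
        assert w0 == pd.Timestamp("2012-10-01")
        assert w1 == s0 == pd.Timestamp("2013-04-01")
        assert s1 == YEAR1[1]


class TestSummarizeChanges:
    @pytest.mark.parametrize(
        "mean,sd,expected",
        [
            (43.3, 10.5, (34.1, 52.5)),  # schizophrenia summary
            (31.6, 6.4, (26.0, 37.2)),  # "health" summary
            (28.7, 2.5, (26.5, 30.9)),  # depression summary
        ],
    )
    def test_normal_approximation_ci_reproduces_reported(self, mean, sd, expected):
        # construct 5 values with the exact mean and sample SD
        base = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        vals = mean + sd * base / base.std(ddof=1)
        summary = summarize_changes(vals)
        assert summary.mean_pct == pytest.approx(mean, abs=1e-9)
        assert summary.sd_pct == pytest.approx(sd, abs=1e-9)
        assert round(summary.ci95[0], 1) == expected[0]
        assert round(summary.ci95[1], 1) == expected[1]

    def test_equal_values_collapse_ci(self):
        s = summarize_changes([5.0, 5.0, 5.0])
        assert s.sd_pct == 0.0
        assert s.ci95 == (5.0, 5.0)

    def test_single_year_rejected(self):
        with pytest.raises(ValueError):
            summarize_changes([1.0])


class TestOneWayAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.f_stat == pytest.approx(0.0)
        assert res.partial_eta_sq == pytest.approx(0.0)

    def test_two_group_hand_example(self):
        # SS_between = 13.5, SS_within = 4, df = (1, 4) -> F = 13.5,
        # equal to the squared two-sample t statistic on these data
        res = one_way_anova({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res.ss_between == pytest.approx(13.5)
        assert res.ss_within == pytest.approx(4.0)
        assert res.f_stat == pytest.approx(13.5)
        t = stats.ttest_ind([1, 2, 3], [4, 5, 6])
        assert res.f_stat == pytest.approx(t.statistic**2)
        assert res.p_value == pytest.approx(t.pvalue)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(i, 1, 5) for i, k in enumerate("abcd")}
        res = one_way_anova(groups)
        ref = stats.f_oneway(*groups.values())
        assert res.f_stat == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_summary_statistics_route_agrees_with_raw(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(i, 2, 5) for i, k in enumerate("abcdefg")}
        raw = one_way_anova(groups)
        summ = anova_from_summary(
            [v.mean() for v in groups.values()],
            [v.std(ddof=1) for v in groups.values()],
            5,
        )
        assert summ.f_stat == pytest.approx(raw.f_stat, rel=1e-10)
        assert summ.partial_eta_sq == pytest.approx(raw.partial_eta_sq, rel=1e-10)
        assert (summ.df_between, summ.df_within) == (raw.df_between, raw.df_within)

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10))
    def test_f_invariant_to_affine_transform(self, shift, scale):
        groups = {"a": [1.0, 2.0, 4.0], "b": [3.0, 5.0, 6.0], "c": [2.0, 2.5, 3.0]}
        ref = one_way_anova(groups).f_stat
        moved = {
            k: [scale * x + shift for x in v] for k, v in groups.items()
        }
        assert one_way_anova(moved).f_stat == pytest.approx(ref, rel=1e-9)

    def test_partial_eta_sq_monotone_in_between_ss(self):
        etas = []
        for gap in (0.0, 1.0, 2.0, 4.0):
            groups = {"a": [0.0, 1.0, 2.0], "b": [gap, gap + 1.0, gap + 2.0]}
            etas.append(one_way_anova(groups).partial_eta_sq)
        assert all(b >= a for a, b in zip(etas, etas[1:]))
        assert all(0 <= e <= 1 for e in etas)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova({"a": [1], "b": [1, 2]})


class TestTukeyHsd:
    def test_identical_groups_not_significant(self):
        res = tukey_hsd({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res[0].p_adjusted == pytest.approx(1.0, abs=1e-6)

    def test_two_groups_reduce_to_t_test(self):
        # with k = 2 the studentized range is sqrt(2)|t|, so the adjusted
        # p equals the unadjusted two-sample p
        a, b = [1.0, 2.0, 3.0, 4.0], [2.5, 4.0, 5.0, 6.0]
        (res,) = tukey_hsd({"a": a, "b": b})
        t = stats.ttest_ind(a, b)
        assert res.p_adjusted == pytest.approx(t.pvalue, abs=1e-6)
        assert res.mean_difference == pytest.approx(np.mean(a) - np.mean(b))

    def test_matches_scipy_tukey_hsd(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(i * 0.8, 1, 5) for i, k in enumerate("abcd")}
        ours = {c.pair: c.p_adjusted for c in tukey_hsd(groups)}
        ref = stats.tukey_hsd(*groups.values())
        names = list(groups)
        for (i, ni), (j, nj) in [
            ((i, n), (j, m))
            for i, n in enumerate(names)
            for j, m in enumerate(names)
            if i < j
        ]:
            assert ours[(ni, nj)] == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_adjusted_p_exceeds_unadjusted_for_many_groups(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(0, 1, 5) for k in "abcde"}
        for comp in tukey_hsd(groups):
            a, b = comp.pair
            t = stats.ttest_ind(groups[a], groups[b])
            assert comp.p_adjusted >= t.pvalue - 1e-12

    def test_agrees_with_permutation_reference(self):
        # 3 groups of 4 with one shifted mean; the label-permutation null
        # of the max studentized range approximates the Tukey adjustment
        rng = np.random.default_rng(11)
        groups = {
            "a": rng.normal(0, 1, 4),
            "b": rng.normal(0, 1, 4),
            "c": rng.normal(1.2, 1, 4),
        }
        ours = {c.pair: c.p_adjusted for c in tukey_hsd(groups)}
        for pair in [("a", "c"), ("a", "b")]:
            p_perm = tukey_permutation_pvalue(groups, pair, 10_000, seed=7)
            se = np.sqrt(p_perm * (1 - p_perm) / 10_000)
            assert ours[pair] == pytest.approx(p_perm, abs=0.05 + 3 * se)
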