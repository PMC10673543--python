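"""Statistical machinery: volume formula, t-tests, ANOVA, normality, survival."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from acidocest.cohortstats import (
    SummaryStat,
    anova_bonferroni,
    anova_two_way,
    km_survival,
    shapiro_wilk,
    summarize,
    t_test,
    t_test_from_summary,
    tumor_volume,
    validate_cohort_table,
)


class TestTumorVolume:
    @pytest.mark.parametrize("a,b,v", [(10, 5, 125.0), (4, 4, 32.0), (7, 0, 0.0)])
    def test_direct_values(self, a, b, v):
        assert tumor_volume(a, b) == pytest.approx(v)

    def test_scale_cubic(self):
        for k in (0.5, 2.0, 3.7):
            assert tumor_volume(9 * k, 4 * k) == pytest.approx(
                k**3 * tumor_volume(9, 4)
            )

    def test_longest_shortest_order_enforced(self):
        with pytest.raises(ValueError):
            tumor_volume(3.0, 5.0)


class TestSummaryT:
    def test_identical_groups(self):
        g = SummaryStat("a", 1.0, 0.2, 6)
        r = t_test_from_summary(g, SummaryStat("b", 1.0, 0.2, 6))
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        # pooled sd = sqrt((5*0.15^2 + 5*0.09^2)/10) = 0.123693...;
        # t = 0.42 / (0.123693 * sqrt(1/3)) = 5.8810 with df = 10
        r = t_test_from_summary(
            SummaryStat("ctrl", 1.16, 0.15, 6), SummaryStat("trt", 0.74, 0.09, 6)
        )
        assert r.df == 10
        assert r.t == pytest.approx(5.8810, abs=1e-3)
        assert r.p < 0.001

    def test_matches_raw_data_t_exactly(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            x = rng.normal(0.0, 1.0, 8)
            y = rng.normal(0.4, 1.3, 11)
            r_sum = t_test_from_summary(summarize(x), summarize(y))
            r_raw = t_test(x, y)
            assert abs(r_sum.t - r_raw.t) < 1e-12
            assert abs(r_sum.p - r_raw.p) < 1e-12

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ZeroDivisionError):
            t_test_from_summary(SummaryStat("a", 1.0, 0.0, 6),
                                SummaryStat("b", 2.0, 0.0, 6))


class TestAnova:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 9), rng.normal(0.5, 1, 12)
        res = anova_bonferroni([x, y])
        t = t_test(x, y).t
        assert res["F"] == pytest.approx(t**2, abs=1e-9)

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(0, 1, 6) for _ in range(4)]
        res = anova_bonferroni(groups)
        for c in res["comparisons"]:
            assert c["p_adj"] >= c["p_raw"] - 1e-15

    def test_familywise_error_controlled_under_null(self):
        # 3 equal-mean groups; Bonferroni keeps FWE near alpha (reduced reps)
        rng = np.random.default_rng(9)
        reps, hits = 400, 0
        for _ in range(reps):
            groups = [rng.normal(0, 1, 6) for _ in range(3)]
            res = anova_bonferroni(groups)
            if any(c["p_adj"] < 0.05 for c in res["comparisons"]):
                hits += 1
        assert hits / reps <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / reps)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            anova_bonferroni([[1.0, 2.0], [3.0]])
        with pytest.raises(ValueError):
            anova_bonferroni([[1.0, 2.0, 3.0]])

    def test_two_way_detects_group_effect(self):
        rng = np.random.default_rng(10)
        rows = []
        for g, mu in (("ctrl", 0.0), ("trt", 1.5)):
            for day in (7, 14):
                for _ in range(6):
                    rows.append(dict(group=g, day=day,
                                     y=mu + 0.1 * day + rng.normal(0, 0.5)))
        tab = anova_two_way(pd.DataFrame(rows), "y", "group", "day")
        assert tab.loc["C(group)", "PR(>F)"] < 1e-6


class TestShapiroWilk:
    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.full(10, 3.0))

    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])

    def test_null_p_uniform(self):
        # under normal data the p-value is U(0,1): KS check over 200 reps
        rng = np.random.default_rng(11)
        ps = [shapiro_wilk(rng.normal(0, 1, 20))[1] for _ in range(200)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_detects_exponential(self):
        rng = np.random.default_rng(12)
        rej = sum(shapiro_wilk(rng.exponential(1.0, 50))[1] < 0.05 for _ in range(150))
        assert rej / 150 > 0.5


def _survival_table(times_a, flags_a, times_b, flags_b):
    rows = []
    for g, times, flags in (("A", times_a, flags_a), ("B", times_b, flags_b)):
        for i, (t, f) in enumerate(zip(times, flags)):
            rows.append(dict(animal_id=f"{g}{i}", group=g, event_time=t,
                             event_flag=f))
    return pd.DataFrame(rows)


def _logrank_statistic(times, events, groups):
    """Independent log-rank implementation for the permutation oracle."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == groups[0])).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (groups == groups[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0


class TestSurvival:
    def test_km_estimate_hand_computed(self):
        # 6 animals, events at 10, 12 (x2), 15; censored at 14, 20:
        # S(10)=5/6, S(12)=5/6*3/5=1/2, S(15)=1/2*1/2=1/4
        tab = _survival_table([10, 12, 12, 14, 15, 20],
                              [True, True, True, False, True, False],
                              [30], [False])
        res = km_survival(tab)
        km = res["curves"]["A"].survival_function_
        assert km.loc[10].iloc[0] == pytest.approx(5 / 6)
        assert km.loc[12].iloc[0] == pytest.approx(0.5)
        assert km.loc[15].iloc[0] == pytest.approx(0.25)

    def test_identical_event_times_give_p_one(self):
        tab = _survival_table([10, 12, 14], [True] * 3, [10, 12, 14], [True] * 3)
        assert km_survival(tab)["p"] == pytest.approx(1.0, abs=1e-9)

    def test_clearly_separated_groups_significant(self):
        tab = _survival_table([8, 9, 10, 10, 11, 12], [True] * 6,
                              [20, 21, 22, 23, 24, 25], [True] * 6)
        assert km_survival(tab)["p"] < 0.05

    def test_all_censored_group_flagged_unstable(self):
        tab = _survival_table([10, 12, 14], [True] * 3, [20, 22, 24], [False] * 3)
        assert km_survival(tab)["unstable"]

    def test_logrank_close_to_exact_permutation(self):
        # moderately separated 6 v 6 cohort: the asymptotic chi-square p
        # must sit within small-sample error of the exact permutation null
        times = np.array([9.0, 12, 14, 16, 19, 23, 12, 16, 19, 23, 26, 28])
        events = np.ones(12, bool)
        events[[10, 11]] = False
        groups = np.array(["A"] * 6 + ["B"] * 6)
        obs = _logrank_statistic(times, events, groups)
        null = []
        for comb in itertools.combinations(range(12), 6):
            g = np.full(12, "B")
            g[list(comb)] = "A"
            null.append(_logrank_statistic(times, events, g))
        p_exact = np.mean(np.asarray(null) >= obs - 1e-12)
        tab = _survival_table(times[:6], events[:6], times[6:], events[6:])
        p_asym = km_survival(tab)["p"]
        assert p_asym == pytest.approx(p_exact, abs=0.05)


class TestTableValidation:
    def test_malformed_row_reported_with_line_number(self):
        df = pd.DataFrame(
            dict(animal_id=["a", "b"], group=["g", "g"], day=[0, 1],
                 diameter_A=[5.0, 3.0], diameter_B=[4.0, 4.0],
                 body_weight=[20, 20], event_time=[10, 10],
                 event_flag=[True, True])
        )
        with pytest.raises(ValueError, match="line 3"):
            validate_cohort_table(df)

    def test_missing_column_reported(self):
        with pytest.raises(ValueError, match="lacks columns"):
            validate_cohort_table(pd.DataFrame(dict(animal_id=["a"])))
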