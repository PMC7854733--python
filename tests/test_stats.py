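"""Group statistics: t-tests, ANOVA, effect sizes, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from restconn.stats import (
    GroupSummary,
    mixed_anova,
    n_per_group,
    one_way_anova,
    partial_eta_from_F,
    pearson_r,
    summarize,
    t_from_samples,
    t_from_summary,
)


def long_table(values, groups, levels):
    """values: (G, n, J) array -> long-format frame."""
    rows = []
    for gi, g in enumerate(groups):
        for si in range(values.shape[1]):
            for ji, lev in enumerate(levels):
                rows.append(
                    {"subject": f"{g}{si}", "group": g, "level": lev,
                     "value": values[gi, si, ji]}
                )
    return pd.DataFrame(rows)


class TestTwoSampleT:
    @pytest.mark.parametrize(
        "a, b, expected_t",
        [
            # seed-seed and seed-whole-brain group contrasts, printed summaries
            (GroupSummary(23, 0.16, 0.16), GroupSummary(23, 0.43, 0.26), -4.2),
            (GroupSummary(23, 1.05, 0.22), GroupSummary(23, 1.24, 0.15), -3.4),
        ],
    )
    def test_reported_group_contrasts(self, a, b, expected_t):
        res = t_from_summary(a, b)
        assert res.df == (44,)
        assert round(res.statistic, 1) == expected_t
        assert res.p < 0.01

    def test_identical_summaries_give_zero(self):
        s = GroupSummary(10, 1.0, 0.5)
        res = t_from_summary(s, s)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            t_from_summary(GroupSummary(5, 1.0, 0.0), GroupSummary(5, 1.0, 0.0))

    def test_summary_route_equals_sample_route(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(20) + 0.3, rng.standard_normal(25)
        direct = t_from_samples(x, y)
        via_summary = t_from_summary(summarize(x), summarize(y))
        assert direct.statistic == pytest.approx(via_summary.statistic, abs=1e-10)
        scipy_t, scipy_p = sps.ttest_ind(x, y)
        assert direct.statistic == pytest.approx(scipy_t, abs=1e-10)
        assert direct.p == pytest.approx(scipy_p, abs=1e-10)


class TestOneWayAnova:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(12), rng.standard_normal(12) + 0.5
        t_res = t_from_samples(x, y)
        f_res = one_way_anova([x, y])
        assert f_res.statistic == pytest.approx(t_res.statistic**2, abs=1e-10)
        assert f_res.effect_size == pytest.approx(
            t_res.statistic**2 / (t_res.statistic**2 + t_res.df[0]), abs=1e-10
        )

    def test_equal_values_give_zero_f(self):
        res = one_way_anova([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        assert res.statistic == 0.0

    def test_hand_worked_three_group_fixture(self):
        groups = [[3.0, 5.0, 4.0, 4.0], [6.0, 8.0, 7.0, 7.0], [9.0, 11.0, 10.0, 10.0]]
        # grand mean 7; SSB = 4*(9+0+9) = 72; SSW = 2+2+2 = 6
        res = one_way_anova(groups)
        assert res.statistic == pytest.approx((72 / 2) / (6 / 9), abs=1e-12)
        assert res.df == (2, 9)
        assert res.effect_size == pytest.approx(72 / 78, abs=1e-12)
        scipy_f, scipy_p = sps.f_oneway(*groups)
        assert res.statistic == pytest.approx(scipy_f, abs=1e-10)
        assert res.p == pytest.approx(scipy_p, abs=1e-10)

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0, 3.0]])


class TestPartialEta:
    @pytest.mark.parametrize(
        "f, df1, df2, expected",
        [(8.17, 2, 68, 0.19), (64.6, 1, 61, 0.51), (0.0, 2, 40, 0.0)],
    )
    def test_reported_values(self, f, df1, df2, expected):
        assert round(partial_eta_from_F(f, df1, df2), 2) == expected


class TestMixedAnova:
    def _random_table(self, seed=0, effect=0.0):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal((2, 6, 4))
        y[1] += effect
        return long_table(y, ["ctl", "pat"], [10, 15, 20, 25])

    def test_matches_scalar_loop_ss_decomposition(self):
        # textbook split-plot sums of squares, written as explicit loops
        rng = np.random.default_rng(17)
        y = rng.standard_normal((2, 3, 2)) + np.array([0.0, 1.0])[None, None, :]
        G, n, J = y.shape
        grand = y.mean()
        ss_group = sum(
            n * J * (y[g].mean() - grand) ** 2 for g in range(G)
        )
        ss_subj = sum(
            J * (y[g, s].mean() - y[g].mean()) ** 2
            for g in range(G) for s in range(n)
        )
        ss_level = sum(
            G * n * (y[:, :, j].mean() - grand) ** 2 for j in range(J)
        )
        ss_inter = sum(
            n * (y[g, :, j].mean() - y[g].mean() - y[:, :, j].mean() + grand) ** 2
            for g in range(G) for j in range(J)
        )
        ss_err = sum(
            (y[g, s, j] - y[g, s].mean() - y[g, :, j].mean() + y[g].mean()) ** 2
            for g in range(G) for s in range(n) for j in range(J)
        )
        res = mixed_anova(long_table(y, ["a", "b"], ["L1", "L2"]))
        assert res["group"].statistic == pytest.approx(
            (ss_group / (G - 1)) / (ss_subj / (G * (n - 1))), abs=1e-10
        )
        assert res["within"].statistic == pytest.approx(
            (ss_level / (J - 1)) / (ss_err / (G * (n - 1) * (J - 1))), abs=1e-10
        )
        assert res["interaction"].statistic == pytest.approx(
            (ss_inter / ((G - 1) * (J - 1))) / (ss_err / (G * (n - 1) * (J - 1))),
            abs=1e-10,
        )
        assert res["group"].effect_size == pytest.approx(
            ss_group / (ss_group + ss_subj), abs=1e-10
        )
        assert res["group"].df == (1, 4)

    def test_matches_pingouin_on_random_tables(self):
        pingouin = pytest.importorskip("pingouin")
        table = self._random_table(seed=3, effect=0.4)
        ours = mixed_anova(table)
        theirs = pingouin.mixed_anova(
            data=table, dv="value", within="level", subject="subject",
            between="group",
        ).set_index("Source")
        assert ours["group"].statistic == pytest.approx(
            theirs.loc["group", "F"], rel=1e-8
        )
        assert ours["within"].statistic == pytest.approx(
            theirs.loc["level", "F"], rel=1e-8
        )
        assert ours["interaction"].statistic == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-8
        )
        assert ours["group"].effect_size == pytest.approx(
            theirs.loc["group", "np2"], abs=1e-8
        )

    def test_location_invariance(self):
        table = self._random_table(seed=5)
        shifted = table.assign(value=table["value"] + 100.0)
        a, b = mixed_anova(table), mixed_anova(shifted)
        for key in a:
            assert a[key].statistic == pytest.approx(b[key].statistic, abs=1e-8)

    def test_level_relabeling_invariance(self):
        table = self._random_table(seed=6)
        relabeled = table.assign(level=table["level"].map({10: "a", 15: "b",
                                                           20: "c", 25: "d"}))
        a, b = mixed_anova(table), mixed_anova(relabeled)
        for key in a:
            assert a[key].statistic == pytest.approx(b[key].statistic, abs=1e-10)

    def test_incomplete_table_raises(self):
        table = self._random_table(seed=7).iloc[:-1]
        with pytest.raises(ValueError, match="level"):
            mixed_anova(table)

    def test_unbalanced_groups_raise(self):
        table = self._random_table(seed=8)
        table = table[table["subject"] != "pat0"]
        with pytest.raises(ValueError, match="balanced"):
            mixed_anova(table)

    def test_null_type_one_error_rate(self):
        """Without a planted group effect the group test rejects at
        about the nominal rate."""
        rejections = 0
        n_reps = 300
        for seed in range(n_reps):
            rng = np.random.default_rng(10_000 + seed)
            y = rng.standard_normal((3, 8, 5))
            table = long_table(y, ["a", "b", "c"], list(range(5)))
            if mixed_anova(table)["group"].p < 0.05:
                rejections += 1
        assert abs(rejections / n_reps - 0.05) <= 0.04


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_fixture(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        y = np.array([2.1, 1.9, 3.5, 4.0, 4.4, 6.2, 5.8, 8.1, 8.0, 9.9])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        r, p = pearson_r(x, y)
        assert r == pytest.approx(expected, abs=1e-12)
        assert 0 < p < 1

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPower:
    def test_reported_sample_size(self):
        assert n_per_group(0.92, alpha=0.05, power=0.90) == 25

    def test_medium_effect_eighty_percent_power(self):
        # the classic benchmark is 64/group; the normal approximation
        # and the exact noncentral-t route may differ by one
        assert abs(n_per_group(0.5, alpha=0.05, power=0.80) - 64) <= 1
        assert n_per_group(0.5, alpha=0.05, power=0.80, method="exact") == 64

    def test_monotone_decreasing_in_effect_size(self):
        assert n_per_group(1.84) < n_per_group(0.92) < n_per_group(0.46)

    def test_zero_effect_raises(self):
        with pytest.raises(ValueError):
            n_per_group(0.0)

    def test_power_recovery_by_simulation(self):
        """Simulated studies at the returned n reject at close to the
        requested power."""
        d, alpha, power = 0.92, 0.05, 0.90
        n = n_per_group(d, alpha=alpha, power=power)
        rng = np.random.default_rng(123)
        reps = 1000
        x = rng.standard_normal((reps, n)) + d
        y = rng.standard_normal((reps, n))
        rate = np.mean(
            [t_from_samples(x[i], y[i]).p < alpha for i in range(reps)]
        )
        assert abs(rate - power) <= 0.03
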