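"""Group statistics: t-tests, split-plot ANOVA, Greenhouse-Geisser, SME."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ergflux.stats import (
    GroupSummary,
    greenhouse_geisser_epsilon,
    mixed_anova,
    pooled_t_from_summary,
    reproduce_reference_tests,
    shapiro_wilk,
    simple_main_effects,
    t_test_raw,
    welch_t_from_summary,
)
from ergflux.synth import make_group_samples


def g(mean, sem, n, label=""):
    return GroupSummary(label, mean, sem, n)


class TestPooledT:
    @pytest.mark.parametrize(
        "g1, g2, t_expect, df_expect",
        [
            ((65.78, 2.72, 7), (53.60, 2.02, 6), -3.488, 11),
            ((126.31, 4.42, 14), (83.89, 7.92, 11), -4.939, 23),
        ],
    )
    def test_reported_comparisons(self, g1, g2, t_expect, df_expect):
        res = pooled_t_from_summary(g(*g1), g(*g2))
        assert res.t == pytest.approx(t_expect, abs=0.005)
        assert res.df == df_expect
        assert res.pooled

    def test_identical_groups_give_zero(self):
        res = pooled_t_from_summary(g(5, 1, 10), g(5, 1, 10))
        assert res.t == 0.0 and res.p == 1.0

    def test_zero_variance_unequal_means_flagged(self):
        res = pooled_t_from_summary(g(5, 0, 10), g(6, 0, 10))
        assert np.isinf(res.t)
        assert "infinite-t" in res.flags

    def test_orientation_is_second_minus_first(self):
        res = pooled_t_from_summary(g(10, 1, 5), g(12, 1, 5))
        assert res.t > 0 and res.mean_diff == pytest.approx(2.0)


class TestWelchT:
    def test_equal_n_equal_sem_matches_pooled_with_smaller_df(self):
        a, b = g(10, 1.5, 8), g(12, 1.5, 8)
        pooled = pooled_t_from_summary(a, b)
        welch = welch_t_from_summary(a, b)
        assert welch.t == pytest.approx(pooled.t, abs=1e-12)
        assert welch.df <= pooled.df + 1e-9

    def test_group_swap_negates_t(self):
        a, b = g(10, 1.1, 7), g(13, 2.3, 9)
        r1 = welch_t_from_summary(a, b)
        r2 = welch_t_from_summary(b, a)
        assert r2.t == pytest.approx(-r1.t, abs=1e-12)
        assert r2.df == pytest.approx(r1.df, abs=1e-12)

    def test_degenerate_first_group_reduces_to_one_sample_t(self):
        # sem1 = 0: Welch t equals the one-sample t of group 2 vs mean1
        a, b = g(10, 0.0, 5), g(13, 1.2, 9)
        res = welch_t_from_summary(a, b)
        assert res.t == pytest.approx((13 - 10) / 1.2, abs=1e-12)
        assert res.df == pytest.approx(b.n - 1, abs=1e-9)


class TestRawVsSummary:
    def test_raw_equals_summary_closure(self):
        x = make_group_samples(122.76, 7.93, 5, seed=1)
        y = make_group_samples(75.29, 6.75, 7, seed=2)
        raw = t_test_raw(x, y)
        summ = pooled_t_from_summary(g(122.76, 7.93, 5), g(75.29, 6.75, 7))
        assert raw.t == pytest.approx(summ.t, abs=1e-9)
        assert raw.df == summ.df

    def test_matches_scipy_ttest_ind(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1.3, 9)
        mine = t_test_raw(x, y)
        ref = sps.ttest_ind(y, x, equal_var=True)
        assert mine.t == pytest.approx(ref.statistic, abs=1e-9)
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-9)
        mine_w = t_test_raw(x, y, welch=True)
        ref_w = sps.ttest_ind(y, x, equal_var=False)
        assert mine_w.t == pytest.approx(ref_w.statistic, abs=1e-9)
        assert mine_w.p == pytest.approx(ref_w.pvalue, abs=1e-9)

    def test_identical_samples_give_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert t_test_raw(x, x).t == 0.0

    def test_too_small_sample_errors(self):
        with pytest.raises(ValueError):
            t_test_raw(np.array([1.0]), np.array([1.0, 2.0]))


class TestShapiroWilk:
    def test_normal_quantile_sample_has_w_near_one(self):
        n = 50
        x = sps.norm.ppf((np.arange(1, n + 1) - 3 / 8) / (n + 1 / 4))
        w, _ = shapiro_wilk(x)
        assert w == pytest.approx(1.0, abs=2e-3)

    def test_constant_sample_errors(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.full(10, 3.0))

    def test_two_point_mixture_rejected(self):
        x = np.concatenate([np.zeros(25), np.ones(25)])
        _, p = shapiro_wilk(x)
        assert p < 0.01

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.array([1.0, 2.0]))


def _toy_table():
    """Balanced 2 groups x 3 times x 4 subjects with fixed values."""
    rng = np.random.default_rng(99)
    rows = []
    for gi, grp in enumerate(("ctrl", "dis")):
        for s in range(4):
            base = rng.normal(0, 2)
            for ti, tv in enumerate((9, 13, 17)):
                rows.append(
                    {
                        "subject": f"{grp}{s}",
                        "group": grp,
                        "time": tv,
                        "value": base + 1.5 * ti + 3.0 * gi + 0.4 * gi * ti
                        + rng.normal(0, 1),
                    }
                )
    return pd.DataFrame(rows)


def _anova_oracle(df):
    """Definitional cell-means sums of squares, computed with plain loops."""
    groups = sorted(df.group.unique())
    times = sorted(df.time.unique())
    subjects = sorted(df.subject.unique())
    k, grand = len(times), df.value.mean()
    cell = {
        (gr, t): df[(df.group == gr) & (df.time == t)].value.mean()
        for gr in groups
        for t in times
    }
    gmean = {gr: df[df.group == gr].value.mean() for gr in groups}
    tmean = {t: df[df.time == t].value.mean() for t in times}
    smean = {s: df[df.subject == s].value.mean() for s in subjects}
    ngrp = {gr: df[df.group == gr].subject.nunique() for gr in groups}
    nsub = len(subjects)

    ss_group = k * sum(ngrp[gr] * (gmean[gr] - grand) ** 2 for gr in groups)
    ss_bs = k * sum((smean[s] - grand) ** 2 for s in subjects)
    ss_sw = ss_bs - ss_group
    ss_time = nsub * sum((tmean[t] - grand) ** 2 for t in times)
    ss_int = sum(
        ngrp[gr] * (cell[(gr, t)] - gmean[gr] - tmean[t] + grand) ** 2
        for gr in groups
        for t in times
    )
    ss_tot = sum((v - grand) ** 2 for v in df.value)
    ss_err = ss_tot - ss_group - ss_sw - ss_time - ss_int
    a = len(groups)
    f_group = (ss_group / (a - 1)) / (ss_sw / (nsub - a))
    f_time = (ss_time / (k - 1)) / (ss_err / ((nsub - a) * (k - 1)))
    f_int = (ss_int / ((a - 1) * (k - 1))) / (ss_err / ((nsub - a) * (k - 1)))
    return f_group, f_time, f_int


class TestMixedAnova:
    def test_all_equal_values_give_zero_f(self):
        df = _toy_table()
        df["value"] = 7.0
        res = mixed_anova(df)
        assert res.f_group == res.f_time == res.f_interaction == 0.0

    def test_matches_definitional_oracle(self):
        df = _toy_table()
        res = mixed_anova(df)
        fg, ft, fi = _anova_oracle(df)
        assert res.f_group == pytest.approx(fg, abs=1e-9)
        assert res.f_time == pytest.approx(ft, abs=1e-9)
        assert res.f_interaction == pytest.approx(fi, abs=1e-9)
        total = sum(
            res.ss[key]
            for key in ("group", "subject_within_group", "time", "interaction", "error_within")
        )
        assert total == pytest.approx(res.ss["total"], abs=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        df = _toy_table()
        res = mixed_anova(df)
        aov = pg.mixed_anova(
            data=df, dv="value", within="time", subject="subject", between="group"
        ).set_index("Source")
        assert res.f_group == pytest.approx(aov.loc["group", "F"], rel=1e-9)
        assert res.f_time == pytest.approx(aov.loc["time", "F"], rel=1e-9)
        assert res.f_interaction == pytest.approx(aov.loc["Interaction", "F"], rel=1e-9)

    def test_epsilon_near_one_for_exchangeable_covariance(self):
        # exchangeable (compound-symmetric) data satisfy sphericity, so
        # epsilon -> 1; average over replicate cohorts of 200 subjects
        nsub, k = 200, 4
        eps = []
        for rep in range(10):
            rng = np.random.default_rng(rep)
            y = rng.normal(0, 1, (nsub, 1)) + rng.normal(0, 1, (nsub, k))
            rows = [
                {"subject": s, "group": "a" if s < nsub // 2 else "b",
                 "time": t, "value": y[s, t]}
                for s in range(nsub)
                for t in range(k)
            ]
            eps.append(mixed_anova(pd.DataFrame(rows)).epsilon_gg)
        assert np.mean(eps) == pytest.approx(1.0, abs=0.05)

    def test_missing_cell_errors(self):
        df = _toy_table().iloc[:-1]
        with pytest.raises(ValueError, match="missing cells"):
            mixed_anova(df)

    def test_single_timepoint_errors(self):
        df = _toy_table()
        with pytest.raises(ValueError):
            mixed_anova(df[df.time == 9])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_epsilon_bounds_on_random_covariances(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 7))
        a = rng.normal(size=(k + 3, k))
        eps = greenhouse_geisser_epsilon(a.T @ a)
        assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12


class TestSimpleMainEffects:
    def test_f_equals_t_squared_per_timepoint(self):
        df = _toy_table()
        res = simple_main_effects(df, at=13)
        x = df[(df.time == 13) & (df.group == "ctrl")].value.to_numpy()
        y = df[(df.time == 13) & (df.group == "dis")].value.to_numpy()
        tt = t_test_raw(x, y)
        assert res.f == pytest.approx(tt.t**2, abs=1e-9)
        assert res.p == pytest.approx(tt.p, abs=1e-12)

    def test_equal_group_means_give_zero_f(self):
        df = _toy_table()
        df.loc[df.time == 9, "value"] = 1.0
        assert simple_main_effects(df, at=9).f == 0.0

    def test_matches_one_way_anova_oracle(self):
        df = _toy_table()
        sub = df[df.time == 17]
        res = simple_main_effects(df, at=17)
        ref = sps.f_oneway(
            *[grp.value.to_numpy() for _, grp in sub.groupby("group")]
        )
        assert res.f == pytest.approx(ref.statistic, abs=1e-9)

    def test_omnibus_error_term_variant(self):
        df = _toy_table()
        res = simple_main_effects(df, at=13, error="omnibus")
        omni = mixed_anova(df)
        assert res.df2 == omni.df_group[1]
        assert res.f > 0

    def test_unknown_timepoint_errors(self):
        with pytest.raises(ValueError):
            simple_main_effects(_toy_table(), at=99)


class TestReferenceReproduction:
    def test_all_reported_comparisons_reproduce(self):
        report = reproduce_reference_tests()
        assert len(report) == 12
        assert report["passed"].all()
        assert report["delta_t"].max() <= 0.05
        assert (report["df_recomputed"] == report["df_reported"]).all()
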