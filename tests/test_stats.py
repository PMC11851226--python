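"""Statistical battery vs closed-form, brute-force and library oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from lesionconn.stats import (
    adjust_p,
    bonferroni,
    multivariate_group_test,
    partial_correlation,
    rm_ancova,
    winsorize_group,
)


class TestWinsorize:
    def test_hand_worked_example(self):
        """[0,1,2,3,10]: mean 3.2, sample SD sqrt(15.7) → upper bound 9.143."""
        out = winsorize_group([0, 1, 2, 3, 10])
        assert out[:4] == [0, 1, 2, 3]
        assert out[4] == pytest.approx(3.2 + 1.5 * np.sqrt(15.7))
        assert out[4] == pytest.approx(9.143, abs=5e-4)

    def test_data_within_own_bounds_unchanged(self):
        data = [1.0, 2.0, 3.0, 4.0, 5.0]  # max deviation 2 < 1.5 * SD (2.37)
        assert winsorize_group(data) == data

    def test_symmetric_inliers_unchanged(self):
        data = [-1.0, 0.0, 1.0]
        assert winsorize_group(data) == data

    def test_zero_sd_returned_unchanged(self):
        assert winsorize_group([2.0, 2.0, 2.0]) == [2.0, 2.0, 2.0]

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=40).filter(
            lambda xs: np.std(xs, ddof=1) > 1e-9
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_bounds_and_order_preserved(self, xs):
        out = np.asarray(winsorize_group(xs))
        x = np.asarray(xs)
        lo = x.mean() - 1.5 * x.std(ddof=1)
        hi = x.mean() + 1.5 * x.std(ddof=1)
        assert out.shape == x.shape
        inside = (x >= lo) & (x <= hi)
        assert np.array_equal(out[inside], x[inside])  # inliers untouched
        assert (out >= lo - 1e-9).all() and (out <= hi + 1e-9).all()


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.standard_normal((2, 25))
        res = partial_correlation(x, y)
        r, p = scipy.stats.pearsonr(x, y)
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.p == pytest.approx(p, rel=1e-9)
        assert res.df == 23

    def test_orthogonal_covariate_leaves_r(self, rng):
        x, y = rng.standard_normal((2, 40))
        # project a random covariate onto the orthogonal complement of {1, x, y}
        q, _ = np.linalg.qr(np.column_stack([np.ones(40), x, y]))
        cov = rng.standard_normal(40)
        cov -= q @ (q.T @ cov)
        res = partial_correlation(x, y, cov)
        plain = np.corrcoef(x, y)[0, 1]
        assert res.r == pytest.approx(plain, abs=1e-10)

    def test_matches_inverse_correlation_identity(self, rng):
        """Closed-form oracle: partial r from the inverse of the 4x4
        correlation matrix of (x, y, c1, c2)."""
        x, y = rng.standard_normal((2, 10))
        cov = rng.standard_normal((10, 2))
        res = partial_correlation(x, y, cov)
        R = np.corrcoef(np.column_stack([x, y, cov]), rowvar=False)
        P = np.linalg.inv(R)
        expected = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
        assert res.r == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = pd.DataFrame(
            rng.standard_normal((18, 4)), columns=["x", "y", "age", "vol"]
        )
        res = partial_correlation(df["x"], df["y"], df[["age", "vol"]].to_numpy())
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["age", "vol"])
        assert res.r == pytest.approx(ref["r"].iloc[0], abs=1e-9)
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.p == pytest.approx(ref[pcol].iloc[0], rel=1e-6)

    def test_symmetric_in_x_y(self, rng):
        x, y = rng.standard_normal((2, 15))
        cov = rng.standard_normal((15, 1))
        a = partial_correlation(x, y, cov)
        b = partial_correlation(y, x, cov)
        assert a.r == pytest.approx(b.r, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_y_equal_to_covariate_rejected(self, rng):
        x = rng.standard_normal(12)
        cov = rng.standard_normal(12)
        with pytest.raises(ValueError, match="covariate"):
            partial_correlation(x, cov, cov)

    def test_rank_deficient_covariates_rejected(self, rng):
        x, y = rng.standard_normal((2, 12))
        c = rng.standard_normal(12)
        with pytest.raises(ValueError, match="rank"):
            partial_correlation(x, y, np.column_stack([c, 2 * c]))

    def test_perfect_correlation_underflow_safe(self):
        x = np.arange(10.0)
        res = partial_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert 0 < res.p < 1e-30

    def test_null_p_uniform(self):
        """x, y, covariates independent normal (n=18): KS over 5000 reps."""
        rng = np.random.default_rng(2718)
        ps = np.empty(5000)
        for i in range(5000):
            x, y = rng.standard_normal((2, 18))
            cov = rng.standard_normal((18, 2))
            ps[i] = partial_correlation(x, y, cov).p
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01


class TestBonferroni:
    def test_single_test_unchanged(self):
        assert bonferroni(0.05, 1) == 0.05

    def test_fifteen_tests(self):
        assert bonferroni(0.05, 15) == pytest.approx(0.00333, abs=5e-5)

    def test_adjusted_p_capped_at_one(self):
        assert adjust_p([0.02, 0.2], 10) == [0.2, 1.0]

    def test_default_m_is_family_size(self):
        assert adjust_p([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.06, 0.09])


def _rm_table(y1, y2, group, age=None):
    df = pd.DataFrame({"initial": y1, "followup": y2, "group": group})
    df["age"] = age if age is not None else 0.0
    return df


def _mixed_anova_oracle(y1, y2, group):
    """Brute-force sums-of-squares two-way mixed ANOVA (2 groups x 2 times)."""
    y = np.column_stack([y1, y2])
    groups = np.unique(group)
    N = len(y1)
    gm = y.mean()
    subj_mean = y.mean(axis=1)
    ss_between_subj = 2 * ((subj_mean - gm) ** 2).sum()
    ss_group = 2 * sum(
        (group == g).sum() * (subj_mean[group == g].mean() - gm) ** 2 for g in groups
    )
    ss_subj_within = ss_between_subj - ss_group
    time_mean = y.mean(axis=0)
    ss_time = N * ((time_mean - gm) ** 2).sum()
    ss_cells = 0.0
    ss_wse = 0.0
    for g in groups:
        sel = group == g
        cell = y[sel].mean(axis=0)
        gmean = y[sel].mean()
        ss_cells += sel.sum() * ((cell - gm - (time_mean - gm) - (gmean - gm)) ** 2).sum()
        ss_wse += ((y[sel] - cell[None, :] - subj_mean[sel][:, None] + gmean) ** 2).sum()
    F_group = (ss_group / 1) / (ss_subj_within / (N - 2))
    F_time = (ss_time / 1) / (ss_wse / (N - 2))
    F_inter = (ss_cells / 1) / (ss_wse / (N - 2))
    return F_group, F_time, F_inter


class TestRmAncova:
    def test_planted_group_offset_no_noise(self):
        y1 = np.r_[np.zeros(5), np.ones(5) * 3]
        y2 = y1.copy()
        group = np.r_[["a"] * 5, ["b"] * 5]
        age = np.arange(10.0)
        eff = {e.name: e for e in rm_ancova(_rm_table(y1, y2, group, age))}
        assert eff["group"].F > 1e10 or np.isinf(eff["group"].F)
        assert eff["group"].p <= 1e-12
        assert eff["time"].F == pytest.approx(0.0, abs=1e-8)
        assert eff["group_x_time"].F == pytest.approx(0.0, abs=1e-8)

    def test_matches_brute_force_mixed_anova(self, rng):
        """Zero-effect covariate, balanced design: equals the classical
        sums-of-squares mixed ANOVA (covariate constant is dropped)."""
        n = 12
        y1 = rng.standard_normal(2 * n) + np.r_[np.zeros(n), 0.8 * np.ones(n)]
        y2 = y1 + rng.standard_normal(2 * n) * 0.7
        group = np.r_[["a"] * n, ["b"] * n]
        eff = {e.name: e for e in rm_ancova(
            _rm_table(y1, y2, group), covariate_cols=())}
        Fg, Ft, Fi = _mixed_anova_oracle(y1, y2, group)
        assert eff["group"].F == pytest.approx(Fg, abs=1e-8)
        assert eff["time"].F == pytest.approx(Ft, abs=1e-8)
        assert eff["group_x_time"].F == pytest.approx(Fi, abs=1e-8)
        assert eff["group"].df_den == 2 * n - 2

    def test_matches_pingouin_mixed_anova(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 10
        y1 = rng.standard_normal(2 * n)
        y2 = rng.standard_normal(2 * n) + 0.4
        group = np.r_[["a"] * n, ["b"] * n]
        eff = {e.name: e for e in rm_ancova(
            _rm_table(y1, y2, group), covariate_cols=())}
        long = pd.DataFrame({
            "subject": np.tile(np.arange(2 * n), 2),
            "group": np.tile(group, 2),
            "time": np.r_[["t1"] * 2 * n, ["t2"] * 2 * n],
            "y": np.r_[y1, y2],
        })
        ref = pingouin.mixed_anova(long, dv="y", within="time", between="group",
                                   subject="subject").set_index("Source")
        assert eff["group"].F == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert eff["time"].F == pytest.approx(ref.loc["time", "F"], rel=1e-6)
        assert eff["group_x_time"].F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6)

    def test_group_effect_matches_statsmodels_ancova_on_means(self, rng):
        """Covariate case: the between-subject F equals a Type III ANCOVA on
        the per-subject means (independent statsmodels route)."""
        smf = pytest.importorskip("statsmodels.formula.api")
        anova_lm = pytest.importorskip("statsmodels.stats.anova").anova_lm
        n = 9
        age = rng.uniform(30, 60, 2 * n)
        y1 = rng.standard_normal(2 * n) + 0.05 * age
        y2 = rng.standard_normal(2 * n) + 0.05 * age + 0.5
        group = np.r_[["a"] * n, ["b"] * n]
        eff = {e.name: e for e in rm_ancova(_rm_table(y1, y2, group, age))}
        df = pd.DataFrame({"avg": (y1 + y2) / 2, "group": group, "age": age})
        fit = smf.ols("avg ~ C(group, Sum) + age", data=df).fit()
        tab = anova_lm(fit, typ=3)
        assert eff["group"].F == pytest.approx(
            tab.loc["C(group, Sum)", "F"], rel=1e-8)

    def test_affine_rescaling_invariance(self, rng):
        n = 8
        y1 = rng.standard_normal(2 * n)
        y2 = rng.standard_normal(2 * n)
        group = np.r_[["a"] * n, ["b"] * n]
        age = rng.uniform(20, 70, 2 * n)
        base = rm_ancova(_rm_table(y1, y2, group, age))
        scaled = rm_ancova(_rm_table(7.3 * y1 - 2, 7.3 * y2 - 2, group, age))
        for b, s in zip(base, scaled):
            assert s.F == pytest.approx(b.F, rel=1e-8)

    def test_incomplete_cases_dropped_listwise(self, rng):
        n = 8
        y1 = rng.standard_normal(2 * n)
        y2 = rng.standard_normal(2 * n)
        group = np.r_[["a"] * n, ["b"] * n]
        df = _rm_table(y1, y2, group, rng.uniform(20, 60, 2 * n))
        df.loc[3, "followup"] = np.nan
        full = rm_ancova(df.drop(index=3))
        with_nan = rm_ancova(df)
        for a, b in zip(full, with_nan):
            assert a.F == pytest.approx(b.F, abs=1e-12)

    def test_small_group_rejected(self):
        df = _rm_table([1.0, 2, 3, 4], [1.0, 2, 3, 4],
                       np.array(["a", "a", "a", "b"]))
        with pytest.raises(ValueError, match="fewer than 3"):
            rm_ancova(df)


class TestMultivariateGroupTest:
    def test_df_bookkeeping_f5_17(self, rng):
        """24 complete cases, 5 measures, 1 covariate → F(5, 17)."""
        y = rng.standard_normal((24, 5))
        group = np.r_[["p"] * 12, ["c"] * 12]
        eff = multivariate_group_test(y, group, rng.uniform(20, 70, 24))
        assert (eff.df_num, eff.df_den) == (5, 17)

    def test_identical_group_means_small_f(self, rng):
        base = rng.standard_normal((15, 3))
        y = np.vstack([base, base])  # both groups share the same distribution
        group = np.r_[["a"] * 15, ["b"] * 15]
        eff = multivariate_group_test(y, group)
        assert eff.F == pytest.approx(0.0, abs=1e-10)
        assert eff.p == pytest.approx(1.0, abs=1e-6)

    def test_huge_separation_dominates(self, rng):
        y = rng.standard_normal((20, 3))
        y[10:, 0] += 100.0
        group = np.r_[["a"] * 10, ["b"] * 10]
        eff = multivariate_group_test(y, group)
        assert eff.F > 1000
        assert eff.p < 1e-12

    def test_matches_statsmodels_manova(self, rng):
        MANOVA = pytest.importorskip("statsmodels.multivariate.manova").MANOVA
        n = 24
        y = rng.standard_normal((n, 4))
        group = np.r_[["p"] * 12, ["c"] * 12]
        age = rng.uniform(30, 60, n)
        y[group == "p"] += 0.8
        eff = multivariate_group_test(y, group, age)
        df = pd.DataFrame(y, columns=[f"m{i}" for i in range(4)])
        df["group"] = group
        df["age"] = age
        mv = MANOVA.from_formula("m0 + m1 + m2 + m3 ~ age + C(group)", data=df)
        tab = mv.mv_test().results["C(group)"]["stat"]
        assert eff.F == pytest.approx(tab.loc["Wilks' lambda", "F Value"], rel=1e-6)
        assert eff.p == pytest.approx(tab.loc["Wilks' lambda", "Pr > F"], rel=1e-4)

    def test_singular_covariance_rejected(self, rng):
        y = rng.standard_normal((12, 3))
        y[:, 2] = y[:, 0] + y[:, 1]  # linearly dependent measures
        group = np.r_[["a"] * 6, ["b"] * 6]
        with pytest.raises(ValueError, match="singular"):
            multivariate_group_test(y, group)
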