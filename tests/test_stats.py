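import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from emowm.stats import (
    cohens_d_ci,
    eta_sq_ci,
    mixed_ancova,
    one_sample_t,
    paired_t,
    welch_t,
)


def _welch_oracle(a, b):
    """Naive Welch formula, written independently of the implementation."""
    ma, mb = sum(a) / len(a), sum(b) / len(b)
    va = sum((x - ma) ** 2 for x in a) / (len(a) - 1)
    vb = sum((x - mb) ** 2 for x in b) / (len(b) - 1)
    se2 = va / len(a) + vb / len(b)
    t = (ma - mb) / se2 ** 0.5
    df = se2 ** 2 / ((va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1))
    return t, df


class TestTTests:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_welch_matches_formula_oracle(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(0, 1, 12), r.normal(0.4, 2, 17)
        res = welch_t(a, b)
        t, df = _welch_oracle(list(a), list(b))
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)
        sp_t, sp_p = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(sp_t, abs=1e-10)
        assert res.p == pytest.approx(sp_p, abs=1e-10)

    def test_identical_groups_give_zero(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = welch_t(a, a)
        assert res.statistic == 0.0 and res.effect_size == 0.0

    def test_equal_variance_equal_n_reduces_to_pooled(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        # equalize the sample variances exactly
        b = (b - b.mean()) / b.std(ddof=1) * a.std(ddof=1) + b.mean()
        res = welch_t(a, b)
        assert res.df == pytest.approx(18.0, abs=1e-10)
        pooled_t, _ = sps.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(pooled_t, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0, 1.0], [2.0, 2.0])

    def test_one_sample_symmetric_sample(self):
        res = one_sample_t([1.0, 2.0, 3.0], mu0=2.0)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_one_sample_matches_scipy(self, rng):
        x = rng.normal(0.5, 1, 20)
        res = one_sample_t(x, 0.0)
        sp_t, sp_p = sps.ttest_1samp(x, 0.0)
        assert res.statistic == pytest.approx(sp_t, abs=1e-10)
        assert res.p == pytest.approx(sp_p, abs=1e-10)
        assert res.effect_size == pytest.approx(x.mean() / x.std(ddof=1), abs=1e-12)

    def test_paired_matches_scipy_and_reports_both_d(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0.3, 1, 15)
        res = paired_t(a, b)
        sp_t, sp_p = sps.ttest_rel(a, b)
        assert res.statistic == pytest.approx(sp_t, abs=1e-10)
        assert res.p == pytest.approx(sp_p, abs=1e-10)
        assert "cohen_d_pooled" in res.extra

    def test_paired_zero_variance_differences_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


class TestEffectSizeCIs:
    def test_d_zero_equal_n_symmetric(self):
        lo, hi = cohens_d_ci(0.0, 20, 20)
        assert lo == pytest.approx(-hi, abs=1e-8)

    def test_f_zero_lower_bound_zero(self):
        lo, hi = eta_sq_ci(0.0, 1, 50)
        assert lo == 0.0 and hi == 0.0

    def test_ci_brackets_point_estimate(self):
        # eta from F: eta = F*df1 / (F*df1 + df2)
        F, df1, df2 = 9.0, 2, 60
        lo, hi = eta_sq_ci(F, df1, df2, 90)
        eta = F * df1 / (F * df1 + df2)
        assert lo < eta < hi

    def test_d_ci_contains_d_and_shrinks_with_n(self):
        wide = cohens_d_ci(0.5, 10, 10)
        narrow = cohens_d_ci(0.5, 100, 100)
        assert wide[0] < 0.5 < wide[1]
        assert (narrow[1] - narrow[0]) < (wide[1] - wide[0])

    def test_eta_ci_shrinks_with_df(self):
        wide = eta_sq_ci(5.0, 1, 20, 90)
        narrow = eta_sq_ci(5.0, 1, 200, 90)
        assert (narrow[1] - narrow[0]) < (wide[1] - wide[0])

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_ci(0.5, 10, 10, level=0)


def _split_plot_oracle(y):
    """Classical balanced split-plot sums of squares from cell means.

    y: array (groups g, subjects n, within p).
    Returns F ratios for group, within, interaction.
    """
    g, n, p = y.shape
    grand = y.mean()
    m_g = y.mean(axis=(1, 2))
    m_j = y.mean(axis=(0, 1))
    m_gj = y.mean(axis=1)
    m_gs = y.mean(axis=2)
    ss_group = n * p * ((m_g - grand) ** 2).sum()
    ss_subj = p * ((m_gs - m_g[:, None]) ** 2).sum()
    ss_within = g * n * ((m_j - grand) ** 2).sum()
    ss_inter = n * ((m_gj - m_g[:, None] - m_j[None, :] + grand) ** 2).sum()
    ss_werr = ((y - m_gs[:, :, None] - m_gj[:, None, :] + m_g[:, None, None]) ** 2).sum()
    df_subj, df_w = g * n - g, (g * n - g) * (p - 1)
    return {
        "group": (ss_group / (g - 1)) / (ss_subj / df_subj),
        "within": (ss_within / (p - 1)) / (ss_werr / df_w),
        "interaction": (ss_inter / ((g - 1) * (p - 1))) / (ss_werr / df_w),
        "ss": (ss_group, ss_subj, ss_within, ss_inter, ss_werr),
    }


def _long_from_cube(y):
    g, n, p = y.shape
    rows = []
    for gi in range(g):
        for si in range(n):
            for pi in range(p):
                rows.append({"subject": f"g{gi}s{si}", "grp": f"g{gi}",
                             "w": f"w{pi}", "y": y[gi, si, pi]})
    return pd.DataFrame(rows)


class TestMixedAncova:
    def test_matches_split_plot_oracle_balanced_2x2(self, rng):
        y = rng.normal(0, 1, size=(2, 8, 2))
        oracle = _split_plot_oracle(y)
        tab = mixed_ancova(_long_from_cube(y), "y", "subject",
                           within=["w"], between=["grp"]).set_index("effect")
        assert tab.loc["grp", "F"] == pytest.approx(oracle["group"], abs=1e-10)
        assert tab.loc["w", "F"] == pytest.approx(oracle["within"], abs=1e-10)
        assert tab.loc["grp × w", "F"] == pytest.approx(oracle["interaction"], abs=1e-10)

    def test_matches_pingouin_three_level_within(self, rng):
        y = rng.normal(0, 1, size=(2, 10, 3))
        df = _long_from_cube(y)
        ours = mixed_ancova(df, "y", "subject", within=["w"], between=["grp"],
                            gg="never").set_index("effect")
        ref = pg.mixed_anova(df, dv="y", within="w", subject="subject",
                             between="grp").set_index("Source")
        assert ours.loc["grp", "F"] == pytest.approx(ref.loc["grp", "F"], abs=1e-8)
        assert ours.loc["w", "F"] == pytest.approx(ref.loc["w", "F"], abs=1e-8)
        assert ours.loc["w", "p"] == pytest.approx(ref.loc["w", "p_unc"], abs=1e-8)
        assert ours.loc["grp × w", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], abs=1e-8)
        assert ours.loc["w", "partial_eta_sq"] == pytest.approx(
            ref.loc["w", "np2"], abs=1e-8)

    def test_constant_covariate_reduces_to_anova(self, rng):
        y = rng.normal(0, 1, size=(2, 8, 2))
        df = _long_from_cube(y)
        df["cov"] = 3.0
        plain = mixed_ancova(df, "y", "subject", within=["w"], between=["grp"])
        with_cov = mixed_ancova(df, "y", "subject", within=["w"], between=["grp"],
                                covariates=["cov"])
        pd.testing.assert_frame_equal(plain, with_cov)

    def test_covariate_consumes_error_df(self, rng):
        y = rng.normal(0, 1, size=(2, 10, 2))
        df = _long_from_cube(y)
        cov = rng.normal(size=20)
        df["cov"] = df["subject"].map(dict(zip(df["subject"].unique(), cov)))
        tab = mixed_ancova(df, "y", "subject", within=["w"], between=["grp"],
                           covariates=["cov"]).set_index("effect")
        assert tab.loc["grp", "df_den"] == 17  # n - rank(intercept+grp+cov)
        assert "cov" in tab.index and "cov × w" in tab.index

    def test_two_level_within_never_corrected(self, rng):
        y = rng.normal(0, 1, size=(2, 8, 2))
        tab = mixed_ancova(_long_from_cube(y), "y", "subject",
                           within=["w"], between=["grp"], gg="always")
        within_rows = tab[tab["effect"].isin(["w", "grp × w"])]
        assert not within_rows["sphericity_corrected"].any()
        assert within_rows["gg_epsilon"].isna().all()

    def test_gg_correction_never_lowers_p(self, rng):
        y = rng.normal(0, 1, size=(2, 12, 4))
        y[:, :, 3] += y[:, :, 2] * 2  # induce nonsphericity
        df = _long_from_cube(y)
        raw = mixed_ancova(df, "y", "subject", within=["w"], between=["grp"],
                           gg="never").set_index("effect")
        corr = mixed_ancova(df, "y", "subject", within=["w"], between=["grp"],
                            gg="always").set_index("effect")
        for eff in ("w", "grp × w"):
            assert corr.loc[eff, "p"] >= raw.loc[eff, "p"] - 1e-12
            eps = corr.loc[eff, "gg_epsilon"]
            assert 1 / 3 < eps <= 1 + 1e-12

    def test_epsilon_matches_pingouin_without_between(self, rng):
        y = rng.normal(0, 1, size=(1, 15, 4))
        df = _long_from_cube(y)
        tab = mixed_ancova(df, "y", "subject", within=["w"], gg="always")
        wide = df.pivot(index="subject", columns="w", values="y")
        assert tab.set_index("effect").loc["w", "gg_epsilon"] == pytest.approx(
            pg.epsilon(wide, correction="gg"), abs=1e-10)

    def test_two_within_factors_effects_enumerated(self, rng):
        y = rng.normal(0, 1, size=(2, 10, 10))
        df = _long_from_cube(y)
        labels = [(f"e{i // 5}", f"b{i % 5}") for i in range(10)]
        df["emo"] = [labels[int(w[1:])][0] for w in df["w"]]
        df["bin"] = [labels[int(w[1:])][1] for w in df["w"]]
        tab = mixed_ancova(df.drop(columns="w"), "y", "subject",
                           within=["emo", "bin"], between=["grp"])
        effects = set(tab["effect"])
        assert {"grp", "emo", "bin", "emo × bin", "grp × emo",
                "grp × bin", "grp × emo × bin"} <= effects

    def test_missing_cell_rejected(self, rng):
        y = rng.normal(0, 1, size=(2, 6, 2))
        df = _long_from_cube(y).iloc[:-1]
        with pytest.raises(ValueError, match="missing|complete"):
            mixed_ancova(df, "y", "subject", within=["w"], between=["grp"])

    def test_collinear_covariates_rejected(self, rng):
        y = rng.normal(0, 1, size=(2, 8, 2))
        df = _long_from_cube(y)
        cov = {s: v for s, v in zip(df["subject"].unique(),
                                    np.random.default_rng(0).normal(size=16))}
        df["c1"] = df["subject"].map(cov)
        df["c2"] = 2 * df["c1"]
        with pytest.raises(ValueError, match="collinear"):
            mixed_ancova(df, "y", "subject", within=["w"], between=["grp"],
                         covariates=["c1", "c2"])

    def test_between_only_single_factor_equals_pooled_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 12)
        df = pd.DataFrame({"subject": [f"s{i}" for i in range(24)],
                           "grp": ["a"] * 12 + ["b"] * 12,
                           "y": np.concatenate([a, b])})
        tab = mixed_ancova(df, "y", "subject", between=["grp"]).set_index("effect")
        t_pooled, _ = sps.ttest_ind(a, b, equal_var=True)
        assert tab.loc["grp", "F"] == pytest.approx(t_pooled ** 2, abs=1e-10)
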