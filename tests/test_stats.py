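"""Inferential layer: ANOVA oracle equivalence, t-tests, gated correlations."""

import numpy as np
import pandas as pd
import pytest

from moodcue import gated_correlation, mixed_anova, two_sample_t


def direct_ss_oracle(df, dv, within, between, subject):
    """Independent mixed-ANOVA sums of squares by explicit enumeration."""
    grand = df[dv].mean()
    k = df[within].nunique()
    subj = df.groupby(subject)[dv].mean()
    grp_of = df.drop_duplicates(subject).set_index(subject)[between]
    ss_between_subj = k * ((subj - grand) ** 2).sum()
    ss_group = 0.0
    for g, members in grp_of.groupby(grp_of):
        ss_group += k * len(members) * (subj[members.index].mean() - grand) ** 2
    ss_total = ((df[dv] - grand) ** 2).sum()
    ss_level = 0.0
    n_subjects = df[subject].nunique()
    for _, cell in df.groupby(within, observed=True):
        ss_level += n_subjects * (cell[dv].mean() - grand) ** 2
    ss_inter = 0.0
    for (g, w), cell in df.groupby([between, within], observed=True):
        gm = subj[grp_of[grp_of == g].index].mean()
        wm = df[df[within] == w][dv].mean()
        ss_inter += cell[subject].nunique() * (cell[dv].mean() - gm - wm + grand) ** 2
    return {"group": ss_group, "err_between": ss_between_subj - ss_group,
            "level": ss_level, "inter": ss_inter,
            "err_within": ss_total - ss_between_subj - ss_level - ss_inter}


def make_design(n_groups, k, n_per_group, rng, effect=0.0):
    rows = []
    for g in range(n_groups):
        for s in range(n_per_group):
            sid = f"g{g}s{s}"
            base = rng.normal(0, 1)
            for w in range(k):
                rows.append((sid, f"G{g}", w,
                             base + rng.normal(0, 1) + effect * w * g))
    return pd.DataFrame(rows, columns=["subj", "grp", "cond", "y"])


class TestMixedAnova:
    def test_toy_2x2_against_hand_oracle(self):
        # group A subjects (1,3) and (2,4); group B (5,5) and (6,6)
        df = pd.DataFrame({
            "subj": ["a1", "a1", "a2", "a2", "b1", "b1", "b2", "b2"],
            "grp": ["A"] * 4 + ["B"] * 4,
            "cond": [0, 1] * 4,
            "y": [1, 3, 2, 4, 5, 5, 6, 6]})
        res = mixed_anova(df, "y", "cond", "grp", "subj")
        # hand sums of squares: SS_group 18, error 2 -> F = 18, eta_p^2 = .9
        assert res.between.ss == pytest.approx(18.0)
        assert res.between.F == pytest.approx(18.0)
        assert res.between.partial_eta_sq == pytest.approx(0.9)
        assert res.within.ss == pytest.approx(2.0)
        assert res.interaction.ss == pytest.approx(2.0)
        # within-error SS is exactly zero here: degenerate within effects
        assert res.within.degenerate and res.within.F == 0.0

    def test_exhaustive_small_designs_match_oracle(self):
        """Direct-SS oracle agreement on all balanced designs up to
        3 groups x 4 levels x 4 subjects."""
        rng = np.random.default_rng(11)
        for n_groups in (2, 3):
            for k in (2, 3, 4):
                for n in (2, 3, 4):
                    df = make_design(n_groups, k, n, rng, effect=0.2)
                    res = mixed_anova(df, "y", "cond", "grp", "subj")
                    ss = direct_ss_oracle(df, "y", "cond", "grp", "subj")
                    n_subj = n_groups * n
                    f_group = (ss["group"] / (n_groups - 1)) / (
                        ss["err_between"] / (n_subj - n_groups))
                    f_level = (ss["level"] / (k - 1)) / (
                        ss["err_within"] / ((n_subj - n_groups) * (k - 1)))
                    assert res.between.F == pytest.approx(f_group, rel=1e-10)
                    assert res.within.F == pytest.approx(f_level, rel=1e-10)
                    assert res.interaction.ss == pytest.approx(ss["inter"], rel=1e-9)
                    for eff in res.effects():
                        assert 0.0 <= eff.partial_eta_sq <= 1.0

    def test_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        df = make_design(3, 4, 5, np.random.default_rng(5), effect=0.3)
        res = mixed_anova(df, "y", "cond", "grp", "subj")
        ref = pg.mixed_anova(data=df, dv="y", within="cond", subject="subj",
                             between="grp", correction=True)
        ref = ref.set_index("Source")
        assert res.between.F == pytest.approx(ref.loc["grp", "F"], rel=1e-9)
        assert res.within.F == pytest.approx(ref.loc["cond", "F"], rel=1e-9)
        assert res.interaction.F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9)
        assert res.within.partial_eta_sq == pytest.approx(
            ref.loc["cond", "np2"], rel=1e-9)
        # epsilon conventions differ (pooled within-group vs grand covariance)
        assert res.within.eps == pytest.approx(ref.loc["cond", "eps"], abs=0.05)

    def test_two_level_epsilon_is_one(self):
        df = make_design(2, 2, 6, np.random.default_rng(2))
        res = mixed_anova(df, "y", "cond", "grp", "subj")
        assert res.within.eps == 1.0
        assert res.sphericity_p == 1.0

    def test_epsilon_bounds(self):
        for seed in range(5):
            df = make_design(2, 5, 6, np.random.default_rng(seed))
            res = mixed_anova(df, "y", "cond", "grp", "subj")
            assert 1.0 / 4 <= res.within.eps <= 1.0

    def test_identical_observations_degenerate(self):
        df = make_design(2, 3, 3, np.random.default_rng(0))
        df["y"] = 4.2
        res = mixed_anova(df, "y", "cond", "grp", "subj")
        for eff in res.effects():
            assert eff.F == 0.0 and eff.degenerate

    def test_unbalanced_rejected(self):
        df = make_design(2, 3, 3, np.random.default_rng(0)).iloc[:-1]
        with pytest.raises(ValueError):
            mixed_anova(df, "y", "cond", "grp", "subj")

    def test_gg_always_flag(self):
        df = make_design(2, 4, 6, np.random.default_rng(8))
        res = mixed_anova(df, "y", "cond", "grp", "subj", correction="always")
        assert res.within.gg_applied
        assert res.within.p == res.within.p_gg


class TestTwoSampleT:
    def test_hand_computation(self):
        # means 2 vs 5, pooled SD 1 -> d = -3, t = -3 / sqrt(2/3)
        res = two_sample_t([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert res.t == pytest.approx(-3 / np.sqrt(2 / 3), rel=1e-12)
        assert res.cohens_d == pytest.approx(-3.0, rel=1e-12)
        assert res.df == 4

    def test_equal_means_zero_d(self):
        res = two_sample_t([1, 2, 1, 2], ["a", "a", "b", "b"])
        assert res.cohens_d == 0.0 and res.t == 0.0

    def test_scale_invariance(self):
        v = [1.0, 2.5, 3.0, 4.0, 5.5, 7.0]
        g = ["a", "a", "a", "b", "b", "b"]
        r1, r2 = two_sample_t(v, g), two_sample_t(np.multiply(2.0, v), g)
        assert r1.t == pytest.approx(r2.t, rel=1e-12)
        assert r1.cohens_d == pytest.approx(r2.cohens_d, rel=1e-12)

    def test_student_df_matches_group_sizes(self):
        rng = np.random.default_rng(0)
        res = two_sample_t(rng.normal(size=74),
                           ["a"] * 37 + ["b"] * 37)
        assert res.df == 72


class TestGatedCorrelation:
    def test_monotone_transform_selects_spearman(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(0, 1.2, 80)
        y = np.exp(x / x.max() * 4)
        res = gated_correlation(x, y)
        assert res.method == "spearman"
        assert res.coefficient == pytest.approx(1.0)

    def test_bivariate_normal_selects_pearson(self):
        rng = np.random.default_rng(2)
        n, r = 500, 0.5
        x = rng.normal(size=n)
        y = r * x + np.sqrt(1 - r ** 2) * rng.normal(size=n)
        res = gated_correlation(x, y)
        assert res.method == "pearson"
        assert res.coefficient == pytest.approx(0.5, abs=0.1)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = 0.6 * x + rng.normal(size=40)
        res = gated_correlation(x, y)
        res_neg = gated_correlation(-x, y)
        assert res_neg.coefficient == pytest.approx(-res.coefficient, rel=1e-9)

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError):
            gated_correlation([1, 1, 1, 1], [1, 2, 3, 4])
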