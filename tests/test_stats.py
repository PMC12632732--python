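"""Split-plot ANOVA, effect sizes, and summary-statistic tests."""

import numpy as np
import pandas as pd
import pytest

from mobikit.stats import (
    cohens_d_pooled, cv_percent, mph_to_mps, pairwise_bonferroni,
    partial_eta_sq, rm_anova, ttest_from_summary,
)
from tests.conftest import make_mixed_table


# ---------------------------------------------------------------------------
# brute-force split-plot oracle (balanced designs, classic mean formulas)


def splitplot_oracle(df, dv, within, subject, between):
    """F statistics from direct cell-mean sums of squares.

    Valid for balanced designs only (equal group sizes, complete
    crossing); serves as the independent check on the projection-based
    implementation.
    """
    within = [within] if isinstance(within, str) else list(within)
    levels = {w: sorted(df[w].unique()) for w in within}
    subj = sorted(df[subject].unique())
    grp = df.groupby(subject)[between].first()
    g_levels = sorted(grp.unique())
    n_per = len(subj) // len(g_levels)
    a = len(levels[within[0]])
    b = len(levels[within[1]]) if len(within) > 1 else 1
    g = len(g_levels)

    m = df[dv].mean()
    mg = df.groupby(between)[dv].mean()
    mgi = df.groupby(subject)[dv].mean()
    out = {}

    def ss(x):
        return float(np.sum(np.square(x)))

    # between stratum
    ss_g = a * b * n_per * ss([mg[gl] - m for gl in g_levels])
    ss_sg = a * b * ss([mgi[s] - mg[grp[s]] for s in subj])
    out[between] = (ss_g / (g - 1)) / (ss_sg / (g * (n_per - 1)))

    def within_stratum(fac):
        k = len(levels[fac])
        other = a * b // k
        mf = df.groupby(fac)[dv].mean()
        mgf = df.groupby([between, fac])[dv].mean()
        mif = df.groupby([subject, fac])[dv].mean()
        ss_f = g * n_per * other * ss([mf[l] - m for l in levels[fac]])
        ss_fg = n_per * other * ss(
            [mgf[(gl, l)] - mg[gl] - mf[l] + m
             for gl in g_levels for l in levels[fac]])
        ss_err = other * ss(
            [mif[(s, l)] - mgi[s] - mgf[(grp[s], l)] + mg[grp[s]]
             for s in subj for l in levels[fac]])
        df_err = g * (n_per - 1) * (k - 1)
        return (ss_f / (k - 1)) / (ss_err / df_err), \
            (ss_fg / ((k - 1) * (g - 1))) / (ss_err / df_err)

    f_a, f_ag = within_stratum(within[0])
    out[within[0]] = f_a
    out[f"{within[0]} * {between}"] = f_ag
    if len(within) == 2:
        f_b, f_bg = within_stratum(within[1])
        out[within[1]] = f_b
        out[f"{within[1]} * {between}"] = f_bg
        A, B = within
        mab = df.groupby([A, B])[dv].mean()
        mgab = df.groupby([between, A, B])[dv].mean()
        ma = df.groupby(A)[dv].mean()
        mb = df.groupby(B)[dv].mean()
        mga = df.groupby([between, A])[dv].mean()
        mgb = df.groupby([between, B])[dv].mean()
        mia = df.groupby([subject, A])[dv].mean()
        mib = df.groupby([subject, B])[dv].mean()
        y = df.set_index([subject, A, B])[dv]
        ss_ab = g * n_per * ss(
            [mab[(x, z)] - ma[x] - mb[z] + m
             for x in levels[A] for z in levels[B]])
        ss_abg = n_per * ss(
            [mgab[(gl, x, z)] - mga[(gl, x)] - mgb[(gl, z)] - mab[(x, z)]
             + mg[gl] + ma[x] + mb[z] - m
             for gl in g_levels for x in levels[A] for z in levels[B]])
        ss_err = ss(
            [y[(s, x, z)] - mia[(s, x)] - mib[(s, z)] - mgab[(grp[s], x, z)]
             + mgi[s] + mga[(grp[s], x)] + mgb[(grp[s], z)] - mg[grp[s]]
             for s in subj for x in levels[A] for z in levels[B]])
        df_err = g * (n_per - 1) * (len(levels[A]) - 1) * (len(levels[B]) - 1)
        d1 = (len(levels[A]) - 1) * (len(levels[B]) - 1)
        out[f"{A} * {B}"] = (ss_ab / d1) / (ss_err / df_err)
        out[f"{A} * {B} * {between}"] = (ss_abg / (d1 * (g - 1))) / (ss_err / df_err)
    return out


class TestRmAnova:
    def test_two_level_within_factor_has_epsilon_one(self, rng):
        df = make_mixed_table(rng, levels=("c1", "c2"))
        res = rm_anova(df, dv="value", within="cond", subject="participant",
                       between="group")
        eps = res.set_index("effect")["gg_epsilon"]
        assert eps["cond"] == 1.0
        assert eps["cond * group"] == 1.0

    def test_printed_f_gives_printed_partial_eta(self):
        # reaction-time condition effect: F = 8.157 with error df 72
        assert partial_eta_sq(8.157, 2, 72) == pytest.approx(0.185, abs=5e-4)

    def test_matches_mean_based_oracle_one_within(self, rng):
        df = make_mixed_table(rng, n_a=8, n_b=8, effect=0.5)
        mine = rm_anova(df, dv="value", within="cond", subject="participant",
                        between="group").set_index("effect")["F"]
        oracle = splitplot_oracle(df, "value", "cond", "participant", "group")
        for effect, f in oracle.items():
            assert mine[effect] == pytest.approx(f, abs=1e-8)

    def test_matches_mean_based_oracle_three_by_two(self, rng):
        rows = []
        for g in ("A", "B"):
            for i in range(6):
                base = rng.standard_normal()
                for x in ("a1", "a2", "a3"):
                    for z in ("b1", "b2"):
                        rows.append({
                            "participant": f"{g}{i}", "group": g,
                            "A": x, "B": z,
                            "value": base + rng.standard_normal(),
                        })
        df = pd.DataFrame(rows)
        mine = rm_anova(df, dv="value", within=["A", "B"],
                        subject="participant",
                        between="group").set_index("effect")["F"]
        oracle = splitplot_oracle(df, "value", ["A", "B"], "participant",
                                  "group")
        for effect, f in oracle.items():
            assert mine[effect] == pytest.approx(f, abs=1e-8)

    def test_frozen_r_car_cross_check(self):
        # deterministic dataset; reference values computed once with
        # R car::Anova (type 3, Greenhouse-Geisser)
        rng = np.random.default_rng(0)
        rows = []
        for g, gi in [("A", range(10)), ("B", range(10, 20))]:
            for i in gi:
                base = rng.normal(0, 1)
                for j, c in enumerate(["c1", "c2", "c3"]):
                    rows.append(dict(participant=f"s{i}", group=g, cond=c,
                                     value=base + 0.4 * j + rng.normal(0, 1)))
        res = rm_anova(pd.DataFrame(rows), dv="value", within="cond",
                       subject="participant", between="group")
        r = res.set_index("effect")
        assert r.loc["group", "F"] == pytest.approx(4.750917, abs=1e-5)
        assert r.loc["cond", "F"] == pytest.approx(5.641266, abs=1e-5)
        assert r.loc["cond * group", "F"] == pytest.approx(0.706267, abs=1e-5)
        assert r.loc["cond", "gg_epsilon"] == pytest.approx(0.9385366, abs=1e-6)
        assert r.loc["cond", "p_gg"] == pytest.approx(0.008728737, abs=1e-6)

    def test_matches_pingouin_on_balanced_mixed_design(self, rng):
        # independent implementation route: pingouin's mixed ANOVA
        # (weighted decomposition) coincides with ours when group
        # sizes are equal
        pg = pytest.importorskip("pingouin")
        df = make_mixed_table(rng, n_a=9, n_b=9, effect=0.4)
        mine = rm_anova(df, dv="value", within="cond",
                        subject="participant",
                        between="group").set_index("effect")["F"]
        ref = pg.mixed_anova(data=df, dv="value", within="cond",
                             subject="participant",
                             between="group").set_index("Source")["F"]
        assert mine["group"] == pytest.approx(ref["group"], abs=1e-9)
        assert mine["cond"] == pytest.approx(ref["cond"], abs=1e-9)
        assert mine["cond * group"] == pytest.approx(ref["Interaction"],
                                                     abs=1e-9)

    def test_epsilon_bounds_and_eta_identity(self, rng):
        df = make_mixed_table(rng, levels=("c1", "c2", "c3", "c4"),
                              effect=0.3)
        res = rm_anova(df, dv="value", within="cond", subject="participant",
                       between="group")
        k = 4
        for _, row in res.iterrows():
            if row["effect"].startswith("cond"):
                assert 1.0 / (k - 1) <= row["gg_epsilon"] <= 1.0
            assert row["partial_eta_sq"] == pytest.approx(
                partial_eta_sq(row["F"], row["df1"], row["df2"]), abs=1e-12)

    def test_epsilon_near_one_under_compound_symmetry(self, rng):
        # exchangeable errors: epsilon should sit close to its upper bound
        eps = []
        for seed in range(20):
            df = make_mixed_table(np.random.default_rng(seed), n_a=30, n_b=30,
                                  subject_sd=2.0, noise_sd=1.0)
            res = rm_anova(df, dv="value", within="cond",
                           subject="participant", between="group")
            eps.append(res.set_index("effect").loc["cond", "gg_epsilon"])
        assert np.mean(eps) > 0.9

    def test_pure_within_design_without_group(self, rng):
        df = make_mixed_table(rng).drop(columns="group")
        res = rm_anova(df, dv="value", within="cond", subject="participant")
        assert list(res["effect"]) == ["cond"]
        assert res.loc[0, "df2"] == (20 - 1) * 2

    def test_incomplete_design_rejected(self, rng):
        df = make_mixed_table(rng)
        df = df[~((df["participant"] == "A00") & (df["cond"] == "c3"))]
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova(df, dv="value", within="cond", subject="participant",
                     between="group")

    def test_duplicate_cell_rejected(self, rng):
        df = make_mixed_table(rng)
        df = pd.concat([df, df.iloc[[0]]])
        with pytest.raises(ValueError, match="more than one value"):
            rm_anova(df, dv="value", within="cond", subject="participant",
                     between="group")


class TestPairwise:
    def test_three_levels_three_comparisons(self, rng):
        df = make_mixed_table(rng, effect=0.8)
        res = pairwise_bonferroni(df, dv="value", factor="cond",
                                  subject="participant")
        assert len(res) == 3
        assert (res["n_comparisons"] == 3).all()
        assert res["paired"].all()
        np.testing.assert_allclose(
            np.minimum(res["p_raw"] * 3, 1.0), res["p_bonferroni"])

    def test_large_raw_p_caps_at_one(self, rng):
        df = make_mixed_table(rng, effect=0.0)
        res = pairwise_bonferroni(df, dv="value", factor="cond",
                                  subject="participant")
        assert (res["p_bonferroni"] <= 1.0).all()

    def test_identical_levels_give_p_one(self):
        rows = [{"participant": f"s{i}", "cond": c, "value": float(i)}
                for i in range(8) for c in ("c1", "c2")]
        res = pairwise_bonferroni(pd.DataFrame(rows), dv="value",
                                  factor="cond", subject="participant")
        assert res.loc[0, "p_bonferroni"] == 1.0
        assert res.loc[0, "cohens_d"] == 0.0

    def test_between_factor_uses_independent_test(self, rng):
        df = make_mixed_table(rng)
        agg = df.groupby(["participant", "group"], as_index=False)["value"].mean()
        res = pairwise_bonferroni(agg, dv="value", factor="group",
                                  subject="participant", paired=False)
        assert res.loc[0, "df"] == 18


class TestSummaryStatistics:
    def test_cv_examples(self):
        assert cv_percent([5.0, 5.0, 5.0]) == 0.0
        assert cv_percent([1.0, 2.0, 3.0]) == pytest.approx(50.0)
        assert cv_percent(np.array([1.0, 2.0, 3.0]) * 7.3) == pytest.approx(50.0)

    def test_cohens_d_null_and_unit(self):
        assert cohens_d_pooled(5.0, 1.0, 10, 5.0, 1.0, 10) == 0.0
        assert cohens_d_pooled(6.0, 1.0, 50, 5.0, 1.0, 50) == pytest.approx(1.0)

    def test_cohens_d_reported_group_difference(self):
        # stride-time variability: TD 2.599 +- 1.41 (n 18) vs ASD
        # 3.830 +- 1.41 (n 17)
        d = cohens_d_pooled(2.599, 1.41, 18, 3.830, 1.41, 17)
        assert d == pytest.approx(-0.873, abs=0.01)

    def test_ttest_reported_walking_speeds(self):
        t, df, p = ttest_from_summary(1.47, 0.531, 11, 1.89, 0.329, 12)
        assert df == 21
        assert t == pytest.approx(-2.296, abs=0.01)
        assert p == pytest.approx(0.032, abs=0.002)

    def test_ttest_identical_summaries_not_significant(self):
        t, df, p = ttest_from_summary(3.0, 1.0, 10, 3.0, 1.0, 10)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_p_matches_student_quantile(self):
        # |t| = 2.0796 at df = 21 sits exactly at two-tailed p = .05
        se = np.sqrt((1 / 12 + 1 / 11))
        t, df, p = ttest_from_summary(2.0796 * se, 1.0, 12, 0.0, 1.0, 11)
        assert df == 21
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_pooled(1.0, 0.0, 5, 2.0, 0.0, 5)
        with pytest.raises(ValueError):
            ttest_from_summary(1.0, 0.0, 5, 2.0, 0.0, 5)

    def test_mph_conversion(self):
        assert mph_to_mps(1.89) == pytest.approx(0.845, abs=0.001)
        assert mph_to_mps(1.47) == pytest.approx(0.657, abs=0.001)
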