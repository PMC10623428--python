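"""Group-statistics layer: Levene gating, factorial and split-plot
ANOVA, Games-Howell, Dunn, and multiplicity adjustments."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glucodyn.inference import (
    bh_fdr,
    bonferroni_adjust,
    dunn_bonferroni,
    games_howell,
    kruskal_wallis,
    levene_test,
    rm_three_way_anova,
    select_posthoc,
    two_way_anova,
)


def _factorial_frame(rng, cell_means, n=6, sd=1.0):
    rows = []
    for (sex, interv), mu in cell_means.items():
        for _ in range(n):
            rows.append({"sex": sex, "intervention": interv,
                         "value": mu + rng.normal(0, sd)})
    return pd.DataFrame(rows)


class TestLevene:
    def test_identical_groups_zero_statistic(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = levene_test([g, g])
        assert res.statistic == pytest.approx(0.0)

    def test_all_equal_degenerate(self):
        res = levene_test([[5.0, 5.0], [5.0, 5.0]])
        assert res.p_value == 1.0
        assert "degenerate" in res.flag

    def test_detects_variance_ratio_nine(self):
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(200):
            a = rng.normal(0, 1, 50)
            b = rng.normal(0, 3, 50)
            if levene_test([a, b]).p_value < 0.05:
                rejections += 1
        assert rejections / 200 > 0.9

    def test_mean_center_matches_scipy(self):
        rng = np.random.default_rng(1)
        gs = [rng.normal(0, s, 12) for s in (1.0, 2.0)]
        res = levene_test(gs)
        stat, p = stats.levene(*gs, center="mean")
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)


class TestTwoWayAnova:
    def test_balanced_toy_against_hand_computed_ss(self):
        """Balanced 2x2 with two replicates: F ratios from explicitly
        hand-computed sums of squares."""
        # cells: (F,STD)=10,12  (F,HF)=20,22  (M,STD)=30,32  (M,HF)=44,46
        df = pd.DataFrame({
            "sex": ["F", "F", "F", "F", "M", "M", "M", "M"],
            "intervention": ["STD", "STD", "HF", "HF", "STD", "STD", "HF", "HF"],
            "value": [10.0, 12.0, 20.0, 22.0, 30.0, 32.0, 44.0, 46.0],
        })
        y = df["value"].to_numpy()
        grand = y.mean()
        mean_sex = df.groupby("sex")["value"].mean()
        mean_int = df.groupby("intervention")["value"].mean()
        mean_cell = df.groupby(["sex", "intervention"])["value"].mean()
        ss_sex = 4 * ((mean_sex - grand) ** 2).sum()
        ss_int = 4 * ((mean_int - grand) ** 2).sum()
        ss_cells = 2 * ((mean_cell - grand) ** 2).sum()
        ss_inter = ss_cells - ss_sex - ss_int
        ss_err = sum((g - g.mean()).pow(2).sum()
                     for _, g in df.groupby(["sex", "intervention"])["value"])
        ms_err = ss_err / 4
        out = two_way_anova(df).set_index("effect")
        assert out.loc["sex", "F"] == pytest.approx(ss_sex / 1 / ms_err)
        assert out.loc["intervention", "F"] == pytest.approx(ss_int / 1 / ms_err)
        assert out.loc["sex:intervention", "F"] == pytest.approx(ss_inter / 1 / ms_err)

    def test_constant_response_all_zero_f(self):
        df = pd.DataFrame({"sex": ["F", "F", "M", "M"] * 2,
                           "intervention": ["A", "B"] * 4,
                           "value": 7.0})
        out = two_way_anova(df)
        assert (out["F"] == 0.0).all()
        assert (out["p_value"] == 1.0).all()

    def test_within_cell_permutation_invariance(self):
        rng = np.random.default_rng(2)
        df = _factorial_frame(rng, {("F", "A"): 0, ("F", "B"): 1,
                                    ("M", "A"): 2, ("M", "B"): 0})
        out1 = two_way_anova(df)
        out2 = two_way_anova(df.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(out1, out2.reset_index(drop=True))

    def test_affine_response_invariance(self):
        rng = np.random.default_rng(3)
        df = _factorial_frame(rng, {("F", "A"): 0, ("F", "B"): 1,
                                    ("M", "A"): 2, ("M", "B"): 0})
        out1 = two_way_anova(df)
        df2 = df.assign(value=3.0 * df["value"] + 10.0)
        out2 = two_way_anova(df2)
        np.testing.assert_allclose(out1["p_value"], out2["p_value"], rtol=1e-9)

    def test_empty_cell_named_in_error(self):
        df = pd.DataFrame({"sex": ["F", "F", "M"],
                           "intervention": ["A", "B", "A"],
                           "value": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="empty design cell"):
            two_way_anova(df)


class TestGamesHowell:
    def test_equal_groups_large_n_p_near_one(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"group": ["a"] * 200 + ["b"] * 200,
                           "value": rng.normal(0, 1, 400)})
        out = games_howell(df)
        assert out["p_value"].iloc[0] > 0.5

    def test_matches_pingouin_reference(self):
        """Three unequal-variance groups: agree with an independent
        implementation to 1e-3."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "group": ["a"] * 10 + ["b"] * 14 + ["c"] * 8,
            "value": np.concatenate([rng.normal(0, 1, 10),
                                     rng.normal(1.0, 3, 14),
                                     rng.normal(2.0, 0.5, 8)]),
        })
        ours = games_howell(df).set_index(["group_a", "group_b"])
        ref = pingouin.pairwise_gameshowell(data=df, dv="value", between="group")
        for _, r in ref.iterrows():
            key = (r["A"], r["B"]) if (r["A"], r["B"]) in ours.index else (r["B"], r["A"])
            assert ours.loc[key, "p_value"] == pytest.approx(r["pval"], abs=1e-3)
            assert abs(ours.loc[key, "df"] - r["df"]) < 1e-6

    def test_k2_reduces_to_welch(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 2, 9)
        df = pd.DataFrame({"group": ["a"] * 12 + ["b"] * 9,
                           "value": np.concatenate([a, b])})
        out = games_howell(df)
        _, p_welch = stats.ttest_ind(a, b, equal_var=False)
        assert out["p_value"].iloc[0] == pytest.approx(p_welch, abs=1e-6)

    def test_zero_variance_pair_flagged(self):
        df = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3,
                           "value": [2.0, 2.0, 2.0, 2.0, 2.0, 2.0]})
        out = games_howell(df)
        assert out["p_value"].iloc[0] == 1.0
        assert "degenerate" in out["flag"].iloc[0]

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"group": ["x"] * 8 + ["y"] * 8,
                           "value": rng.normal(0, 1, 16)})
        p1 = games_howell(df)["p_value"].iloc[0]
        df2 = df.assign(group=df["group"].map({"x": "y", "y": "x"}))
        p2 = games_howell(df2)["p_value"].iloc[0]
        assert p1 == pytest.approx(p2)


class TestAdjustments:
    def test_bonferroni_examples(self):
        np.testing.assert_allclose(bonferroni_adjust([0.01]), [0.01])
        np.testing.assert_allclose(bonferroni_adjust([0.03, 0.04]), [0.06, 0.08])
        assert bonferroni_adjust([0.9, 0.9, 0.9]).max() == 1.0

    def test_bh_step_up_hand_example(self):
        adj = bh_fdr([0.01, 0.02, 0.04, 0.9])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.0533333333, 0.9], rtol=1e-6)

    def test_bh_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_bh_monotone_and_dominated_by_bonferroni(self):
        rng = np.random.default_rng(8)
        p = np.sort(rng.uniform(0, 1, 20))
        bh = bh_fdr(p)
        assert (np.diff(bh) >= -1e-12).all()
        assert (bh <= bonferroni_adjust(p) + 1e-12).all()
        assert (bh >= p - 1e-12).all()


class TestKruskalDunn:
    def test_hand_rank_oracle(self):
        """H for {1,2,3} vs {4,5,6} from the rank-sum formula."""
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]
        n, N = 3, 6
        rbars = [2.0, 5.0]
        H = 12.0 / (N * (N + 1)) * sum(n * r**2 for r in rbars) - 3 * (N + 1)
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(H)

    def test_identical_groups_p_one(self):
        res = kruskal_wallis([[3.0, 3.0], [3.0, 3.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_dunn_two_groups_matches_normal_rank_sum(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        out = dunn_bonferroni([a, b])
        # z from the two-sample rank-sum normal approximation
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        ra = ranks[:10].mean()
        rb = ranks[10:].mean()
        N = 22
        z = (ra - rb) / math.sqrt(N * (N + 1) / 12 * (1 / 10 + 1 / 12))
        assert out["z"].iloc[0] == pytest.approx(z)

    def test_all_tied_degenerate(self):
        out = dunn_bonferroni([[1.0, 1.0], [1.0, 1.0]])
        assert out["p_value"].iloc[0] == 1.0

    def test_rank_statistics_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(10)
        gs = [rng.normal(0, 1, 8), rng.normal(1, 1, 8), rng.normal(2, 1, 8)]
        gs_t = [np.exp(g) for g in gs]
        assert kruskal_wallis(gs).statistic == pytest.approx(
            kruskal_wallis(gs_t).statistic)
        pd.testing.assert_series_equal(dunn_bonferroni(gs)["p_value"],
                                       dunn_bonferroni(gs_t)["p_value"])


class TestPosthocSelector:
    def test_heteroscedastic_routes_to_games_howell(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"group": ["a"] * 30 + ["b"] * 30,
                           "value": np.concatenate([rng.normal(0, 1, 30),
                                                    rng.normal(0, 6, 30)])})
        out = select_posthoc(df)
        assert (out["method"] == "games-howell").all()

    def test_homoscedastic_routes_to_bonferroni(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"group": ["a"] * 30 + ["b"] * 30,
                           "value": rng.normal(0, 1, 60)})
        out = select_posthoc(df)
        assert (out["method"] == "welch-bonferroni").all()
        assert (out["adjusted_p"] >= out["p_value"] - 1e-12).all()


def _split_plot_frame(rng, n_per_cell=4, period_shift=0.0):
    rows = []
    sid = 0
    for sex in ("F", "M"):
        for interv in ("A", "B"):
            for _ in range(n_per_cell):
                sid += 1
                subj_eff = rng.normal(0, 1)
                for k, period in enumerate(("pre", "early", "late")):
                    rows.append({
                        "subject": f"s{sid}", "sex": sex, "intervention": interv,
                        "period": period,
                        "value": subj_eff + k * period_shift + rng.normal(0, 0.5),
                    })
    return pd.DataFrame(rows)


class TestSplitPlotAnova:
    def test_detects_within_subject_shift(self):
        rng = np.random.default_rng(13)
        df = _split_plot_frame(rng, period_shift=2.0)
        out = rm_three_way_anova(df).set_index("effect")
        assert out.loc["period", "p_value"] < 1e-4

    def test_matches_pingouin_mixed_anova_with_combined_between(self):
        """With the two between factors combined into one, the period
        effect and the subject-error decomposition match an independent
        mixed-ANOVA implementation."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(14)
        df = _split_plot_frame(rng, period_shift=0.8)
        ours = rm_three_way_anova(df, gg_correct=False).set_index("effect")
        df2 = df.assign(grp=df["sex"] + df["intervention"])
        ref = pingouin.mixed_anova(data=df2, dv="value", within="period",
                                   subject="subject", between="grp",
                                   correction=False).set_index("Source")
        assert ours.loc["period", "F"] == pytest.approx(
            ref.loc["period", "F"], rel=1e-6)
        assert ours.loc["period", "df_den"] == ref.loc["period", "DF2"]

    def test_incomplete_subject_dropped_with_warning(self):
        rng = np.random.default_rng(15)
        df = _split_plot_frame(rng)
        df = df.drop(df[(df["subject"] == "s1") & (df["period"] == "late")].index)
        with pytest.warns(UserWarning, match="listwise"):
            out = rm_three_way_anova(df)
        assert not out["F"].isna().any()

    def test_gg_epsilon_bounds(self):
        rng = np.random.default_rng(16)
        df = _split_plot_frame(rng, period_shift=0.3)
        out = rm_three_way_anova(df)
        eps = out.loc[out["effect"] == "period", "gg_epsilon"].iloc[0]
        assert 0.5 <= eps <= 1.0  # lower bound 1/(k-1) with k=3

    def test_between_effect_tested_against_subject_ms(self):
        """A pure between-group shift shows in the between effect, not
        the within effects."""
        rng = np.random.default_rng(17)
        df = _split_plot_frame(rng)
        df.loc[df["intervention"] == "B", "value"] += 6.0
        out = rm_three_way_anova(df).set_index("effect")
        assert out.loc["intervention", "p_value"] < 0.01
        assert out.loc["intervention:period", "p_value"] > 0.05
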