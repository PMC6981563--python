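"""Split-plot ANOVA, ANCOVA, post hoc contrasts and baseline tests.

The toy-design expectations below were computed with an exact rational
(Fraction-based) projection oracle and frozen; cross-checks against
pingouin and statsmodels serve as independent implementations.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from officeactivity.anova import (
    AliasedCovariateError,
    DegenerateDesignError,
    NotApplicableError,
    baseline_tests,
    bonferroni_posthoc,
    mixed_ancova,
    mixed_anova,
    split_plot_anova,
)

# 2 groups x 2 times, 3 subjects/group; exact-fraction oracle gives
# SS = {between 75, subjects 6, time 3, interaction 12, within-error 2}
# and F = {between 50, time 6, interaction 24}.
TOY_Y = np.array([[10, 12], [11, 14], [9, 13], [16, 15], [18, 16], [17, 17]], float)
TOY_G = np.array(["a", "a", "a", "b", "b", "b"])


def toy_long():
    rows = []
    for i, (g, (pre, post)) in enumerate(zip(TOY_G, TOY_Y)):
        rows += [
            dict(subject=f"s{i}", group=g, time="pre", y=pre),
            dict(subject=f"s{i}", group=g, time="post", y=post),
        ]
    return pd.DataFrame(rows)


def random_design(rng, n_per_group=(5, 7), t=2, effect=0.0):
    rows = []
    sid = 0
    for gi, n in enumerate(n_per_group):
        for _ in range(n):
            base = rng.normal(0, 1)
            for ti in range(t):
                rows.append(
                    dict(
                        subject=f"s{sid}",
                        group=f"g{gi}",
                        time=f"t{ti}",
                        y=base + effect * gi * ti + rng.normal(0, 1),
                    )
                )
            sid += 1
    return pd.DataFrame(rows)


class TestSplitPlot:
    def test_matches_hand_computed_toy_design(self):
        table = split_plot_anova(TOY_Y, TOY_G).set_index("source")
        expect = {
            "between": (75.0, 1, 50.0),
            "subjects_within_groups": (6.0, 4, np.nan),
            "within": (3.0, 1, 6.0),
            "interaction": (12.0, 1, 24.0),
            "within_error": (2.0, 4, np.nan),
        }
        for src, (ss, df, f) in expect.items():
            assert table.loc[src, "SS"] == pytest.approx(ss, abs=1e-10)
            assert table.loc[src, "df"] == df
            if not np.isnan(f):
                assert table.loc[src, "F"] == pytest.approx(f, abs=1e-10)

    def test_ss_partition_on_balanced_designs(self):
        rng = np.random.default_rng(1)
        for t in (2, 3, 5):
            y = rng.normal(size=(8, t))
            g = np.repeat(["a", "b"], 4)
            table = split_plot_anova(y, g)
            ss_total = float(np.sum((y - y.mean()) ** 2))
            assert table["SS"].sum() == pytest.approx(ss_total, rel=1e-9)

    @pytest.mark.parametrize("n_per_group,t", [((5, 9), 2), ((4, 7), 4), ((6, 6), 3)])
    def test_matches_pingouin(self, n_per_group, t):
        pg = pytest.importorskip("pingouin")
        df = random_design(np.random.default_rng(3), n_per_group, t, effect=0.4)
        mine = mixed_anova(df, "y", "subject", "group", "time").table.set_index("source")
        theirs = pg.mixed_anova(
            data=df, dv="y", within="time", subject="subject", between="group",
            correction=False,
        )
        for src, row in zip(["between", "within", "interaction"], range(3)):
            assert mine.loc[src, "SS"] == pytest.approx(theirs.at[row, "SS"], rel=1e-10)
            assert mine.loc[src, "F"] == pytest.approx(theirs.at[row, "F"], rel=1e-10)
            assert mine.loc[src, "p"] == pytest.approx(theirs.at[row, "p_unc"], rel=1e-9)

    def test_identical_responses_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            split_plot_anova(np.full((6, 2), 3.0), TOY_G)

    def test_single_subject_group_not_applicable(self):
        with pytest.raises(NotApplicableError):
            split_plot_anova(TOY_Y, np.array(["a", "a", "a", "a", "a", "b"]))

    def test_listwise_deletion_with_warning(self):
        df = toy_long().drop(index=1)  # s0 missing post
        with pytest.warns(UserWarning, match="listwise"):
            res = mixed_anova(df, "y", "subject", "group", "time")
        assert res.design_info["n_subjects"] == 5

    def test_between_p_uniform_under_null(self):
        # Null split-plot designs: the between-effect p follows U(0,1).
        rng = np.random.default_rng(2026)
        ps = []
        for _ in range(2000):
            y = rng.normal(size=(12, 2))
            g = np.repeat(["a", "b"], 6)
            table = split_plot_anova(y, g).set_index("source")
            ps.append(table.loc["between", "p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_interaction_power_on_default_cohort(self):
        # With the generator's 25-min SB shift and n=13/29, the group x time
        # interaction is detected in a majority of replicates.
        from officeactivity.accelerometry import summarize_days, summarize_phase
        from officeactivity.synthetic import (
            AccelSimConfig,
            GROUP_BASELINE_MEANS,
            generate_epoch_series,
        )

        detected = 0
        for seed in (101, 102, 103):
            frames = []
            for group in ("control", "renovation"):
                sb, lpa, mvpa = GROUP_BASELINE_MEANS[group]
                cfg = AccelSimConfig(
                    seed=seed, working_sb_min=sb, working_lpa_min=lpa,
                    working_mvpa_min=mvpa, effect_sb_change=25.0,
                )
                for phase in ("pre", "post"):
                    frames.append(
                        summarize_phase(
                            summarize_days(generate_epoch_series(cfg, group, phase))
                        )
                    )
            ph = pd.concat(frames, ignore_index=True)
            res = mixed_anova(
                ph, "sb_min_norm", "participant_id", "group", "phase",
                within_order=["pre", "post"],
            )
            detected += res.p("interaction") < 0.05
        assert detected >= 2


class TestAncova:
    def test_orthogonal_covariate_leaves_between_ss_unchanged(self):
        # covariate orthogonal to both the group factor and the group-centred
        # response: adjusted between SS equals the unadjusted SS (the F moves
        # marginally because the covariate consumes one error df)
        ybar = np.array([1.0, 2.0, 3.0, 2.0, 5.0, 6.0, 7.0, 6.0])
        cov = np.array([0.0, 1.0, 0.0, -1.0, 0.0, 1.0, 0.0, -1.0])
        bump = np.array([1.0, 0.0, -1.0, 0.0, 1.0, 0.0, -1.0, 0.0])  # _|_ cov
        g = np.repeat(["a", "b"], 4)
        rows = [
            dict(subject=f"s{i}", group=g[i], time=t,
                 y=ybar[i] + ((0.5 + 0.3 * bump[i]) if t == "t1" else 0.0),
                 cov=cov[i])
            for i in range(8)
            for t in ("t0", "t1")
        ]
        df = pd.DataFrame(rows)
        adj = mixed_ancova(df, "y", "subject", "group", "time", "cov").table.set_index("source")
        unadj = mixed_anova(df, "y", "subject", "group", "time").table.set_index("source")
        assert adj.loc["between", "SS"] == pytest.approx(unadj.loc["between", "SS"], rel=1e-9)
        assert adj.loc["covariate", "SS"] == pytest.approx(0.0, abs=1e-9)
        assert adj.loc["within", "F"] == pytest.approx(unadj.loc["within", "F"], rel=1e-12)

    def test_matches_statsmodels_subject_level_ancova(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(9)
        n, t = 14, 2
        g = np.repeat(["a", "b"], 7)
        cov = rng.normal(0, 1, n)
        base = (g == "b") * 1.2 + 1.8 * cov + rng.normal(0, 1, n)
        rows = [
            dict(subject=f"s{i}", group=g[i], time=f"t{j}",
                 y=base[i] + 0.4 * j + rng.normal(0, 0.3), cov=cov[i])
            for i in range(n)
            for j in range(t)
        ]
        df = pd.DataFrame(rows)
        mine = mixed_ancova(df, "y", "subject", "group", "time", "cov").table.set_index("source")
        subj = df.groupby(["subject", "group", "cov"], as_index=False)["y"].mean()
        fit = smf.ols("y ~ cov + C(group)", data=subj).fit()
        aov = anova_lm(fit, typ=2)
        assert mine.loc["between", "SS"] / t == pytest.approx(
            aov.loc["C(group)", "sum_sq"], rel=1e-9
        )
        assert mine.loc["covariate", "SS"] / t == pytest.approx(
            aov.loc["cov", "sum_sq"], rel=1e-9
        )
        assert mine.loc["between", "F"] == pytest.approx(aov.loc["C(group)", "F"], rel=1e-9)
        assert mine.loc["between", "p"] == pytest.approx(
            aov.loc["C(group)", "PR(>F)"], rel=1e-9
        )

    def test_group_aligned_covariate_raises_aliasing(self):
        df = toy_long()
        df["cov"] = (df["group"] == "b").astype(float)
        with pytest.raises(AliasedCovariateError):
            mixed_ancova(df, "y", "subject", "group", "time", "cov")

    def test_covariate_must_be_subject_constant(self):
        df = toy_long()
        df["cov"] = np.arange(len(df), dtype=float)
        with pytest.raises(ValueError, match="constant within subject"):
            mixed_ancova(df, "y", "subject", "group", "time", "cov")


class TestPosthoc:
    def test_adjustment_arithmetic_and_cap(self):
        assert min(1.0, 0.002 * 2) == pytest.approx(0.004)
        assert min(1.0, 0.9 * 2) == 1.0
        df = toy_long()  # interaction F = 24, p < 0.05
        res = mixed_anova(df, "y", "subject", "group", "time", within_order=["pre", "post"])
        records = bonferroni_posthoc(
            res, df, "y", "subject", "group", "time", within_order=["pre", "post"]
        )
        assert len(records) == 2
        for _, row in records.iterrows():
            assert row["m"] == 2
            assert row["p_adj"] == pytest.approx(min(1.0, row["p_raw"] * 2))

    def test_posthoc_matches_scipy_paired_t(self):
        df = toy_long()
        res = mixed_anova(df, "y", "subject", "group", "time", within_order=["pre", "post"])
        records = bonferroni_posthoc(
            res, df, "y", "subject", "group", "time", within_order=["pre", "post"]
        ).set_index("between_level")
        a = TOY_Y[TOY_G == "a"]
        t_ref, p_ref = sps.ttest_rel(a[:, 0], a[:, 1])
        assert records.loc["a", "p_raw"] == pytest.approx(p_ref)

    def test_nonsignificant_interaction_gives_empty_set(self):
        rng = np.random.default_rng(4)
        df = random_design(rng, (6, 6), 2, effect=0.0)
        res = mixed_anova(df, "y", "subject", "group", "time")
        if res.p("interaction") < 0.05:  # extremely unlikely at this seed
            pytest.skip("random null design produced a significant interaction")
        records = bonferroni_posthoc(res, df, "y", "subject", "group", "time")
        assert records.empty
        assert "posthoc_note" in res.design_info


class TestBaseline:
    def test_identical_groups_give_t0_p1(self):
        df = pd.DataFrame(
            dict(group=["a"] * 3 + ["b"] * 3, x=[1.0, 2.0, 3.0] * 2)
        )
        out = baseline_tests(df, "group", continuous=["x"])
        assert out["statistic"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_chi2_matches_textbook_formula(self):
        # direct sum((O-E)^2/E) on a hand-built 2x2 table
        table = np.array([[10, 20], [30, 15]], float)
        rows = []
        for gi, g in enumerate("ab"):
            for ci, c in enumerate("xy"):
                rows += [dict(group=g, var=c)] * int(table[gi, ci])
        df = pd.DataFrame(rows)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2_ref = float(((table - expected) ** 2 / expected).sum())
        out = baseline_tests(df, "group", categorical=["var"])
        assert out["statistic"].iloc[0] == pytest.approx(chi2_ref, rel=1e-12)

    def test_job_type_margin_is_significant(self):
        # 2x3 occupation table: control 12/13/4, renovation 7/1/5
        counts = {"control": [12, 13, 4], "renovation": [7, 1, 5]}
        rows = [
            dict(group=g, job=j)
            for g, ns in counts.items()
            for j, n in zip(("manager", "clerk", "sales"), ns)
            for _ in range(n)
        ]
        out = baseline_tests(pd.DataFrame(rows), "group", categorical=["job"])
        chi2_ref, p_ref, _, _ = sps.chi2_contingency(
            np.array([counts["control"], counts["renovation"]]), correction=False
        )
        assert out["statistic"].iloc[0] == pytest.approx(chi2_ref)
        assert out["p"].iloc[0] == pytest.approx(p_ref)
        assert out["p"].iloc[0] < 0.05

    def test_zero_variance_rejected(self):
        df = pd.DataFrame(dict(group=["a"] * 2 + ["b"] * 2, x=[1.0, 1.0, 2.0, 2.0]))
        with pytest.raises(ValueError):
            baseline_tests(df, "group", continuous=["x"])
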