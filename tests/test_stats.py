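import numpy as np
import pandas as pd
import pytest
from scipy import special, stats as sps

from mmnkit.stats import (
    SummaryGroup,
    independent_t,
    mixed_anova_2x2,
    mixed_anova_core,
    paired_t,
    t_from_summary,
)


def _long_table(y1, y2, group, within=("simple", "pattern")):
    rows = []
    for i, (a, b, g) in enumerate(zip(y1, y2, group)):
        rows.append({"subject_id": f"s{i}", "gender": g,
                     "condition": within[0], "v": a})
        rows.append({"subject_id": f"s{i}", "gender": g,
                     "condition": within[1], "v": b})
    return pd.DataFrame(rows)


class TestTFromSummary:
    def test_gender_latency_contrast_simple_condition(self):
        """Female vs male simple-condition peak latencies recomputed from the
        printed group summaries."""
        r = t_from_summary(SummaryGroup(173.55, 9.06, 14),
                           SummaryGroup(142.58, 6.76, 15))
        assert r.df == 27
        assert round(r.t, 2) == 2.76
        assert round(r.p, 2) == 0.01
        assert r.d == pytest.approx(1.02, abs=0.02)

    def test_gender_latency_contrast_pattern_condition(self):
        r = t_from_summary(SummaryGroup(150.11, 8.32, 14),
                           SummaryGroup(158.08, 7.49, 15))
        assert round(r.t, 2) == -0.71
        assert round(r.p, 2) == 0.48
        assert r.d == pytest.approx(0.26, abs=0.02)

    def test_equal_means_give_zero(self):
        r = t_from_summary(SummaryGroup(5.0, 1.0, 10), SummaryGroup(5.0, 2.0, 12))
        assert r.t == pytest.approx(0.0)
        assert r.d == pytest.approx(0.0)

    def test_degenerate_sems_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            t_from_summary(SummaryGroup(1.0, 0.0, 5), SummaryGroup(2.0, 0.0, 5))


class TestPairedT:
    def test_identical_samples(self):
        x = np.arange(5.0)
        r = paired_t(x, x.copy())
        assert (r.t, r.p, r.d) == (0.0, 1.0, 0.0)
        assert r.df == 4

    def test_constant_shift_undefined(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError, match="zero variance"):
            paired_t(x + 2.0, x)

    def test_simulated_effect_recovery(self):
        """Mean recovered paired d over 1000 replicates matches the
        configured standardized effect 0.65 after the known small-sample
        bias of the d estimator (Hedges factor) is accounted for."""
        rng = np.random.default_rng(0)
        n, d_true, reps = 14, 0.65, 1000
        ds = np.empty(reps)
        for i in range(reps):
            diff = rng.normal(d_true, 1.0, size=n)
            ds[i] = paired_t(diff, np.zeros(n)).d
        df = n - 1
        log_j = (special.gammaln(df / 2) - special.gammaln((df - 1) / 2)
                 - 0.5 * np.log(df / 2))
        expected = d_true / np.exp(log_j)
        se = ds.std(ddof=1) / np.sqrt(reps)
        assert abs(ds.mean() - expected) < 3 * se


class TestIndependentT:
    def test_identical_groups(self):
        x = np.arange(6.0)
        r = independent_t(x, x.copy())
        assert r.t == 0.0 and r.d == 0.0
        assert r.df == 10

    def test_matches_summary_route_exactly(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 9), rng.normal(0.5, 2, 12)
        raw = independent_t(x, y)
        summ = t_from_summary(
            SummaryGroup(x.mean(), x.std(ddof=1) / np.sqrt(len(x)), len(x)),
            SummaryGroup(y.mean(), y.std(ddof=1) / np.sqrt(len(y)), len(y)),
        )
        assert raw.t == pytest.approx(summ.t, abs=1e-12)
        assert raw.p == pytest.approx(summ.p, abs=1e-12)
        assert abs(raw.d) == pytest.approx(summ.d, abs=1e-12)

    def test_textbook_formula_oracle(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=8), rng.normal(size=11)
        n1, n2 = len(x), len(y)
        sp = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1))
                     / (n1 + n2 - 2))
        t_hand = (x.mean() - y.mean()) / (sp * np.sqrt(1 / n1 + 1 / n2))
        p_hand = 2 * sps.t.sf(abs(t_hand), n1 + n2 - 2)
        r = independent_t(x, y)
        assert r.t == pytest.approx(t_hand, abs=1e-10)
        assert r.p == pytest.approx(p_hand, abs=1e-10)


class TestMixedAnova:
    def test_denominator_df_is_27_for_the_study_roster(self):
        rng = np.random.default_rng(3)
        g = ["female"] * 14 + ["male"] * 15
        t = mixed_anova_core(rng.normal(size=29), rng.normal(size=29), g)
        for e in t.effects.values():
            assert (e.df_num, e.df_den) == (1, 27)

    def test_all_equal_values_flagged(self):
        t = mixed_anova_core(np.ones(8), np.ones(8), ["a"] * 4 + ["b"] * 4)
        assert any(f.startswith("zero_variance") for f in t.flags)
        for e in t.effects.values():
            assert e.F == 0.0 and e.eta_p2 == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_balanced_design_matches_pingouin(self, seed):
        import pingouin as pg
        rng = np.random.default_rng(seed)
        df = _long_table(rng.normal(size=8), rng.normal(size=8),
                         ["female"] * 4 + ["male"] * 4)
        mine = mixed_anova_2x2(df, dv="v", within="condition",
                               between="gender")
        ref = pg.mixed_anova(df, dv="v", within="condition",
                             between="gender", subject="subject_id")
        ref = ref.set_index(ref["Source"].str.lower())
        for ours, theirs in [("gender", "gender"),
                             ("condition", "condition"),
                             ("interaction", "interaction")]:
            e = mine[ours]
            row = ref.loc[theirs]
            assert e.F == pytest.approx(row["F"], abs=1e-8)
            assert e.p == pytest.approx(row["p_unc"], abs=1e-8)
            assert e.eta_p2 == pytest.approx(row["np2"], abs=1e-8)
            assert e.ss == pytest.approx(row["SS"], abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_unbalanced_design_matches_glm_oracle(self, seed):
        """Unweighted-marginal-means tests against an independent OLS route:
        difference scores regressed on effect-coded group (intercept ->
        within effect, slope -> interaction) and subject means on group."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(100 + seed)
        n1, n2 = 5, 8
        y1, y2 = rng.normal(size=n1 + n2), rng.normal(size=n1 + n2)
        g = np.array(["f"] * n1 + ["m"] * n2)
        mine = mixed_anova_core(y1, y2, g, within_name="cond",
                                between_name="grp")
        aux = pd.DataFrame({"d": y1 - y2, "m": (y1 + y2) / 2, "g": g})
        fit = smf.ols("d ~ C(g, Sum)", data=aux).fit()
        assert mine["cond"].F == pytest.approx(fit.tvalues.iloc[0] ** 2, abs=1e-8)
        assert mine["cond"].p == pytest.approx(fit.pvalues.iloc[0], abs=1e-8)
        assert mine["interaction"].F == pytest.approx(
            fit.tvalues.iloc[1] ** 2, abs=1e-8)
        between = sm.stats.anova_lm(smf.ols("m ~ C(g)", data=aux).fit())
        assert mine["grp"].F == pytest.approx(between.loc["C(g)", "F"], abs=1e-8)

    def test_sum_of_squares_decomposition_balanced(self):
        rng = np.random.default_rng(4)
        y1, y2 = rng.normal(size=10), rng.normal(size=10)
        g = ["a"] * 5 + ["b"] * 5
        t = mixed_anova_core(y1, y2, np.array(g))
        y = np.concatenate([y1, y2])
        ss_total = ((y - y.mean()) ** 2).sum()
        parts = (sum(e.ss for e in t.effects.values())
                 + t.ss_error_between + t.ss_error_within)
        assert parts == pytest.approx(ss_total, abs=1e-8)

    def test_between_effect_equals_squared_t_on_subject_means(self):
        rng = np.random.default_rng(5)
        y1, y2 = rng.normal(size=12), rng.normal(size=12)
        g = np.array(["a"] * 5 + ["b"] * 7)
        t = mixed_anova_core(y1, y2, g)
        m = (y1 + y2) / 2
        r = independent_t(m[g == "a"], m[g == "b"])
        assert t.effects["between"].F == pytest.approx(r.t ** 2, abs=1e-10)

    def test_eta_p2_within_unit_interval(self):
        rng = np.random.default_rng(6)
        t = mixed_anova_core(rng.normal(size=9), rng.normal(size=9),
                             np.array(["a"] * 4 + ["b"] * 5))
        for e in t.effects.values():
            assert 0.0 <= e.eta_p2 <= 1.0

    def test_incomplete_design_names_subject(self):
        df = _long_table(np.zeros(4), np.zeros(4), ["a"] * 2 + ["b"] * 2)
        df = df.drop(df[(df.subject_id == "s2")
                        & (df.condition == "pattern")].index)
        with pytest.raises(ValueError, match="s2"):
            mixed_anova_2x2(df, dv="v")

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mixed_anova_core(np.zeros(3), np.ones(3), np.array(["a", "b", "b"]))


def test_type_i_error_calibrated_under_null():
    """Simulating the null, each ANOVA effect rejects at 0.05 with a rate
    inside the binomial 95% CI."""
    rng = np.random.default_rng(7)
    g = np.array(["female"] * 14 + ["male"] * 15)
    reject = {"between": 0, "within": 0, "interaction": 0}
    n_sim = 10_000
    for _ in range(n_sim):
        t = mixed_anova_core(rng.normal(size=29), rng.normal(size=29), g)
        for name in reject:
            reject[name] += t.effects[name].p < 0.05
    half = 1.96 * np.sqrt(0.05 * 0.95 / n_sim)
    for name, k in reject.items():
        assert abs(k / n_sim - 0.05) < half, (name, k / n_sim)
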