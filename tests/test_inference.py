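import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from watermaze import inference


class TestOneSampleT:
    def test_d_equals_t_over_sqrt_n(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.4, 1.0, 15)
        res = inference.one_sample_t(x, 0.5)
        assert res.df == 14
        assert res.d == pytest.approx(res.t / math.sqrt(15))

    def test_reflection_antisymmetry(self):
        x = np.array([0.2, 0.5, 0.9, 1.4])
        mu0 = 0.6
        a = inference.one_sample_t(x, mu0)
        b = inference.one_sample_t(2 * mu0 - x, mu0)
        assert b.t == pytest.approx(-a.t)
        assert b.p == pytest.approx(a.p)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            inference.one_sample_t([1.0, 1.0, 1.0], 0.5)

    def test_matches_scipy(self):
        x = np.array([0.31, 0.52, 0.47, 0.55, 0.38])
        res = inference.one_sample_t(x, 0.5)
        ref = stats.ttest_1samp(x, 0.5)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


class TestWelch:
    def test_identical_samples_give_zero_t(self):
        x = np.array([1.0, 2.0, 3.5])
        res = inference.welch_two_sample_t(x, x.copy())
        assert res.t == pytest.approx(0.0)

    def test_hand_computed_small_case(self):
        res = inference.welch_two_sample_t([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.224744871, abs=1e-8)
        assert res.df == pytest.approx(4.0)
        assert res.d == pytest.approx(1.0)  # |2-3| / pooled sd 1

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 2, 11)
        a = inference.welch_two_sample_t(x, y)
        b = inference.welch_two_sample_t(y, x)
        assert b.t == pytest.approx(-a.t)
        assert b.p == pytest.approx(a.p)
        assert b.d == pytest.approx(a.d)

    def test_p_close_to_permutation_p(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 9), rng.normal(0.8, 1, 9)
        res = inference.welch_two_sample_t(x, y)
        perm = stats.permutation_test(
            (x, y), lambda a, b, axis=-1: stats.ttest_ind(a, b, equal_var=False, axis=axis).statistic,
            permutation_type="independent", n_resamples=20000, random_state=0)
        assert res.p == pytest.approx(perm.pvalue, abs=0.05)


class TestPartialEtaSquared:
    @pytest.mark.parametrize("F,df1,df2,expected,nd", [
        (7.72, 1, 24, 0.243, 3),
        (8.05, 1, 24, 0.25, 2),
        (0.99, 1, 24, 0.04, 2),
        (12.65, 1, 25, 0.34, 2),
        (0.05, 1, 25, 0.002, 3),
        (0.20, 1, 25, 0.008, 3),
    ])
    def test_printed_identities(self, F, df1, df2, expected, nd):
        assert round(inference.partial_eta_squared(F, df1, df2), nd) == expected

    def test_zero_F(self):
        assert inference.partial_eta_squared(0.0, 1, 24) == 0.0


def _projection_ss(df):
    """Brute-force mixed-ANOVA strata via projection (hat) matrices."""
    y = df["value"].to_numpy()

    def X(cols):
        return pd.get_dummies(df[cols].astype(str).agg("|".join, axis=1)).to_numpy(float)

    def fit(Xm):
        beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        return Xm @ beta

    ones = np.ones((len(y), 1))
    p1 = fit(ones)
    pg = fit(X(["group"]))
    pc = fit(X(["condition"]))
    pgc = fit(X(["group", "condition"]))
    ps = fit(X(["subject"]))
    psc = fit(np.hstack([X(["subject"]), X(["group", "condition"])]))
    ss = dict(
        between_group=np.sum((pg - p1) ** 2),
        subjects_within_group=np.sum((ps - pg) ** 2),
        within_condition=np.sum((pc - p1) ** 2),
        interaction=np.sum((pgc - pg - pc + p1) ** 2),
        condition_x_subjects=np.sum((y - psc) ** 2),
    )
    return ss


def _random_design(rng, nA, nB):
    rows = []
    for g, n in (("A", nA), ("B", nB)):
        for i in range(n):
            base = rng.normal(0, 1)
            for c in ("c1", "c2"):
                rows.append(dict(subject=f"{g}{i}", group=g, condition=c,
                                 value=base + rng.normal(0, 1)
                                 + (0.5 if c == "c2" else 0)
                                 + (0.3 if g == "B" else 0)))
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_constant_data_gives_zero_F(self):
        df = _random_design(np.random.default_rng(0), 3, 3)
        df["value"] = 1.0
        res = inference.mixed_anova_2x2(df)
        assert res.between.F == pytest.approx(0.0)
        assert res.within.F == pytest.approx(0.0)
        assert res.interaction.F == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_balanced_ss_match_projection_oracle(self, seed):
        df = _random_design(np.random.default_rng(seed), 6, 6)
        res = inference.mixed_anova_2x2(df)
        oracle = _projection_ss(df)
        for k, (ss, _) in res.ss_table.items():
            assert ss == pytest.approx(oracle[k], abs=1e-8), k

    def test_hand_decomposed_toy_case(self):
        # 2 subjects per group; SS worked out by hand from cell means
        rows = [
            ("A1", "A", "c1", 1.0), ("A1", "A", "c2", 2.0),
            ("A2", "A", "c1", 2.0), ("A2", "A", "c2", 3.0),
            ("B1", "B", "c1", 3.0), ("B1", "B", "c2", 5.0),
            ("B2", "B", "c1", 4.0), ("B2", "B", "c2", 6.0),
        ]
        df = pd.DataFrame(rows, columns=["subject", "group", "condition", "value"])
        res = inference.mixed_anova_2x2(df)
        # subject means: A 1.5, 2.5; B 4, 5  -> group delta 2.5, pooled var 0.5
        assert res.between.F == pytest.approx(2.5 ** 2 / (0.5 * 1.0))
        # difference scores c1-c2: A -1, -1; B -2, -2 -> zero variance strata
        assert res.ss_table["condition_x_subjects"][0] == pytest.approx(0.0)
        oracle = _projection_ss(df)
        for k, (ss, _) in res.ss_table.items():
            assert ss == pytest.approx(oracle[k], abs=1e-8), k

    def test_interaction_equals_squared_t_on_difference_scores(self):
        rng = np.random.default_rng(5)
        df = _random_design(rng, 5, 8)
        res = inference.mixed_anova_2x2(df)
        wide = df.pivot_table(index=["subject", "group"], columns="condition",
                              values="value")
        d = (wide["c1"] - wide["c2"]).reset_index(level="group")
        a = d[d.group == "A"][0].to_numpy()
        b = d[d.group == "B"][0].to_numpy()
        t = stats.ttest_ind(a, b, equal_var=True).statistic
        assert res.interaction.F == pytest.approx(t ** 2)

    def test_matches_pingouin_on_balanced_data(self):
        pg = pytest.importorskip("pingouin")
        df = _random_design(np.random.default_rng(9), 7, 7)
        res = inference.mixed_anova_2x2(df)
        ref = pg.mixed_anova(df, dv="value", within="condition",
                             between="group", subject="subject").set_index("Source")
        assert res.between.F == pytest.approx(ref.loc["group", "F"])
        assert res.within.F == pytest.approx(ref.loc["condition", "F"])
        assert res.interaction.F == pytest.approx(ref.loc["Interaction", "F"])
        assert res.between.partial_eta_sq == pytest.approx(ref.loc["group", "np2"])

    def test_group_and_interaction_match_pingouin_unbalanced(self):
        # with unequal groups the within main effect is Type III here
        # (unweighted means) while pingouin weights by group size, so only
        # the group and interaction effects are compared
        pg = pytest.importorskip("pingouin")
        df = _random_design(np.random.default_rng(10), 5, 9)
        res = inference.mixed_anova_2x2(df)
        ref = pg.mixed_anova(df, dv="value", within="condition",
                             between="group", subject="subject").set_index("Source")
        assert res.between.F == pytest.approx(ref.loc["group", "F"])
        assert res.interaction.F == pytest.approx(ref.loc["Interaction", "F"])

    def test_missing_cell_rejected(self):
        df = _random_design(np.random.default_rng(0), 3, 3).iloc[:-1]
        with pytest.raises(ValueError):
            inference.mixed_anova_2x2(df)


class TestRankSum:
    def test_hand_ranked_extremes(self):
        assert inference.wilcoxon_rank_sum([1, 2], [3, 4]).w == 0
        assert inference.wilcoxon_rank_sum([3, 4], [1, 2]).w == 4

    def test_rank_identity(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=6), rng.normal(size=9)
        wxy = inference.wilcoxon_rank_sum(x, y).w
        wyx = inference.wilcoxon_rank_sum(y, x).w
        assert wxy + wyx == len(x) * len(y)

    def test_exact_vs_normal_approximation_agree_roughly(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        pe = inference.wilcoxon_rank_sum(x, y, exact=True).p
        pa = inference.wilcoxon_rank_sum(x, y, exact=False).p
        assert pe == pytest.approx(pa, abs=0.05)

    def test_tied_large_samples_use_asymptotic(self):
        x = [1.0] * 15
        y = [1.0] * 10 + [2.0] * 5
        res = inference.wilcoxon_rank_sum(x, y)
        assert not res.exact
        assert 0 <= res.p <= 1


class TestJZSBayesFactor:
    def test_monotone_in_t(self):
        ts = [0.0, 0.5, 1.0, 2.0, 3.0, 5.0, 8.0]
        bfs = [inference.jzs_bayes_factor(t, 12).bf10 for t in ts]
        assert all(b > a for a, b in zip(bfs, bfs[1:]))
        assert bfs[-1] > 1000

    def test_null_favoured_at_zero_evidence(self):
        bf = inference.jzs_bayes_factor(0.0, 10)
        assert bf.bf10 < 1

    def test_zero_t_pinned_by_monte_carlo_oracle(self):
        # marginal likelihood under H1 by direct Monte-Carlo over the
        # Cauchy effect prior, vs the quadrature implementation
        rng = np.random.default_rng(0)
        n = 10
        deltas = rng.standard_cauchy(400_000) * inference.DEFAULT_R_SCALE
        t_obs = 0.0
        like = stats.nct.pdf(t_obs, n - 1, deltas * np.sqrt(n)).mean()
        mc_bf10 = like / stats.t.pdf(t_obs, n - 1)
        bf = inference.jzs_bayes_factor(t_obs, n)
        assert bf.bf10 == pytest.approx(mc_bf10, rel=0.02)

    def test_reciprocal_invariant(self):
        bf = inference.jzs_bayes_factor(2.2, 14)
        assert bf.bf10 * bf.bf01 == pytest.approx(1.0, abs=1e-9)

    def test_two_sample_effective_n(self):
        pg = pytest.importorskip("pingouin")
        bf = inference.jzs_bayes_factor(2.1, 12, 15)
        ref = float(pg.bayesfactor_ttest(2.1, 12, 15))
        assert bf.bf10 == pytest.approx(ref, rel=1e-4)

    def test_one_sample_matches_independent_port(self):
        pg = pytest.importorskip("pingouin")
        for t, n in [(3.52, 15), (1.40, 12), (-2.0, 20)]:
            bf = inference.jzs_bayes_factor(t, n)
            ref = float(pg.bayesfactor_ttest(t, n, paired=True))
            assert bf.bf10 == pytest.approx(ref, rel=1e-4)

    def test_sign_symmetry(self):
        a = inference.jzs_bayes_factor(2.5, 9).bf10
        b = inference.jzs_bayes_factor(-2.5, 9).bf10
        assert a == pytest.approx(b, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            inference.jzs_bayes_factor(float("nan"), 10)
        with pytest.raises(ValueError):
            inference.jzs_bayes_factor(1.0, 1)


class TestInterpretBF:
    def test_strong_for_alternative(self):
        bf = inference.BFResult(bf10=13.68, r_scale=inference.DEFAULT_R_SCALE,
                                method="one_sample_t")
        assert inference.interpret_bf(bf) == "strong for H1"

    def test_anecdotal_for_null(self):
        bf = inference.BFResult(bf10=1 / 2.71, r_scale=inference.DEFAULT_R_SCALE,
                                method="two_sample_t")
        assert inference.interpret_bf(bf) == "anecdotal for H0"

    def test_substantial_for_null(self):
        bf = inference.BFResult(bf10=1 / 3.63, r_scale=inference.DEFAULT_R_SCALE,
                                method="one_sample_t")
        assert inference.interpret_bf(bf) == "substantial for H0"

    def test_unity_has_no_direction(self):
        bf = inference.BFResult(bf10=1.0, r_scale=inference.DEFAULT_R_SCALE,
                                method="one_sample_t")
        assert inference.interpret_bf(bf) == "anecdotal"
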