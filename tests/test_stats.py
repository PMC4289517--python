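"""Screens, ANOVA, Tukey HSD, correlation clustering — with independent
oracles for every closed-form check."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
from scipy.integrate import quad

from metabodrift._utils import ValidationError
from metabodrift.preprocess import Autoscaler, autoscale, impute_missing
from metabodrift.stats import (
    correlation_cluster,
    tukey_hsd,
    two_way_anova,
    univariate_screen,
)


# ------------------------------------------------------------------ oracles

def mannwhitney_exact_p_oracle(x, y):
    """Two-sided exact Mann-Whitney p by exhaustive enumeration of all
    C(n, n1) group assignments of the pooled sample (tie-free data)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(a_idx):
        a = pooled[list(a_idx)]
        b = np.delete(pooled, list(a_idx))
        return sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)

    u_obs = u_stat(range(n1))
    us = np.array(
        [u_stat(c) for c in itertools.combinations(range(len(pooled)), n1)]
    )
    mu = len(x) * len(y) / 2.0
    # two-sided: total mass of assignments at least as extreme as observed
    p = np.mean(np.abs(us - mu) >= np.abs(u_obs - mu) - 1e-12)
    return float(p)


def kruskal_h_oracle(groups):
    """Direct rank-sum evaluation of the Kruskal-Wallis H statistic."""
    pooled = np.concatenate(groups)
    ranks = ss.rankdata(pooled)
    n = len(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


def anova_2x2_oracle(y, a, b):
    """Hand-worked sums-of-squares decomposition for a balanced 2x2 design."""
    y, a, b = np.asarray(y, float), np.asarray(a), np.asarray(b)
    grand = y.mean()
    ss_a = sum(
        (y[a == lv].mean() - grand) ** 2 * (a == lv).sum() for lv in np.unique(a)
    )
    ss_b = sum(
        (y[b == lv].mean() - grand) ** 2 * (b == lv).sum() for lv in np.unique(b)
    )
    cell_means = {}
    ss_err = 0.0
    for la in np.unique(a):
        for lb in np.unique(b):
            cell = y[(a == la) & (b == lb)]
            cell_means[(la, lb)] = cell.mean()
            ss_err += ((cell - cell.mean()) ** 2).sum()
    ss_ab = sum(
        ((a == la) & (b == lb)).sum()
        * (cell_means[(la, lb)]
           - y[a == la].mean() - y[b == lb].mean() + grand) ** 2
        for la in np.unique(a) for lb in np.unique(b)
    )
    df_err = len(y) - len(np.unique(a)) * len(np.unique(b))
    ms_err = ss_err / df_err
    return {
        "A": (ss_a / 1) / ms_err,
        "B": (ss_b / 1) / ms_err,
        "A:B": (ss_ab / 1) / ms_err,
        "df_err": df_err,
    }


def studentized_range_sf_oracle(q, k, df):
    """P(Q > q) for the studentized range by direct numeric integration of
    the classical double integral (normal-range form integrated against the
    chi distribution of the pooled SD)."""
    def inner(u):
        # P(range of k std normals <= q*u)
        def f(z):
            return ss.norm.pdf(z) * (
                ss.norm.cdf(z + q * u) - ss.norm.cdf(z)
            ) ** (k - 1)
        val, _ = quad(f, -8, 8, limit=200)
        return k * val

    # density of u = s/sigma where s^2 ~ chi2_df/df
    def outer(u):
        return inner(u) * ss.chi.pdf(u * np.sqrt(df), df) * np.sqrt(df)

    cdf, _ = quad(outer, 1e-9, 8, limit=200)
    return 1.0 - cdf


# -------------------------------------------------------------- screens

class TestUnivariateScreen:
    def test_exact_p_small_groups(self):
        """{1,2} vs {3,4}: U = 0, exact two-sided p = 1/3."""
        m = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]})
        labels = pd.Series(["a", "a", "b", "b"])
        res = univariate_screen(m, labels)
        assert res.loc["f", "pvalue"] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 3), (3, 4), (4, 4), (2, 5)])
    def test_exact_p_matches_exhaustive_permutation(self, n1, n2):
        """Exact MW p equals exhaustive enumeration for all n <= 8 splits."""
        rng = np.random.default_rng(n1 * 10 + n2)
        x = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # distinct values
        a, b = x[:n1], x[n1:]
        res = ss.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.pvalue == pytest.approx(mannwhitney_exact_p_oracle(a, b))
        m = pd.DataFrame({"f": np.concatenate([a, b])})
        labels = pd.Series(["g1"] * n1 + ["g2"] * n2)
        out = univariate_screen(m, labels)
        assert out.loc["f", "pvalue"] == pytest.approx(
            mannwhitney_exact_p_oracle(a, b)
        )

    def test_identical_groups_p_one(self):
        m = pd.DataFrame({"f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        labels = pd.Series(["a"] * 3 + ["b"] * 3)
        assert univariate_screen(m, labels).loc["f", "pvalue"] == pytest.approx(1.0)

    def test_kruskal_matches_rank_formula(self):
        groups = [np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.array([5.0, 6.0])]
        m = pd.DataFrame({"f": np.concatenate(groups)})
        labels = pd.Series(["a", "a", "b", "b", "c", "c"])
        res = univariate_screen(m, labels)
        assert res.loc["f", "statistic"] == pytest.approx(kruskal_h_oracle(groups))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        m1 = pd.DataFrame({"f": x})
        m2 = pd.DataFrame({"f": np.exp(x)})  # strictly monotone transform
        labels = pd.Series(["a"] * 20 + ["b"] * 20)
        p1 = univariate_screen(m1, labels).loc["f", "pvalue"]
        p2 = univariate_screen(m2, labels).loc["f", "pvalue"]
        assert p1 == pytest.approx(p2)

    def test_null_pvalues_uniform(self):
        """Under permuted labels the screen's p-values are U(0,1): KS test
        not rejected at alpha = 0.01 across 2,000 null features."""
        rng = np.random.default_rng(17)
        n = 60
        m = pd.DataFrame(rng.normal(size=(n, 2000)))
        m.columns = [f"f{j}" for j in range(2000)]
        labels = pd.Series(rng.permutation(["a"] * 30 + ["b"] * 30))
        res = univariate_screen(m, labels)
        ks = ss.kstest(res["pvalue"], "uniform")
        assert ks.pvalue > 0.01


# ---------------------------------------------------------------- ANOVA

class TestTwoWayAnova:
    def test_null_case_balanced(self):
        y = np.tile([1.0, 2.0], 8)  # identical cell distributions
        a = np.repeat(["a1", "a2"], 8)
        b = np.tile(np.repeat(["b1", "b2"], 4), 2)
        res = two_way_anova(y, a, b)
        assert res.factor_a.pvalue > 0.9
        assert res.factor_b.pvalue > 0.9

    def test_balanced_2x2_matches_hand_worked_ss(self):
        rng = np.random.default_rng(3)
        a = np.repeat(["a1", "a2"], 10)
        b = np.tile(np.repeat(["b1", "b2"], 5), 2)
        y = (
            rng.normal(size=20)
            + np.where(a == "a2", 1.0, 0.0)
            + np.where(b == "b2", 0.5, 0.0)
        )
        res = two_way_anova(y, a, b)
        oracle = anova_2x2_oracle(y, a, b)
        assert res.factor_a.F == pytest.approx(oracle["A"], abs=1e-8)
        assert res.factor_b.F == pytest.approx(oracle["B"], abs=1e-8)
        assert res.interaction.F == pytest.approx(oracle["A:B"], abs=1e-8)
        assert res.factor_a.df_den == oracle["df_err"]

    def test_type_ii_equals_sequential_on_balanced_data(self):
        """On balanced data Type II SS coincide with sequential SS, so the
        F statistics match statsmodels' typ=1 results."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(4)
        a = np.repeat(["a1", "a2"], 12)
        b = np.tile(np.repeat(["b1", "b2", "b3"], 4), 2)
        y = rng.normal(size=24) + np.where(a == "a2", 0.7, 0)
        res = two_way_anova(y, a, b)
        df = pd.DataFrame({"y": y, "a": a, "b": b})
        seq = sm.stats.anova_lm(smf.ols("y ~ C(a) * C(b)", df).fit(), typ=1)
        assert res.factor_a.F == pytest.approx(seq.loc["C(a)", "F"])
        assert res.factor_b.F == pytest.approx(seq.loc["C(b)", "F"])

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValidationError):
            two_way_anova([1, 2, 3, 4], ["a"] * 4, ["b1", "b1", "b2", "b2"])

    def test_empty_cell_with_interaction_rejected(self):
        y = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        a = ["a1", "a1", "a1", "a2", "a2", "a2"]
        b = ["b1", "b2", "b1", "b1", "b1", "b1"]  # (a2, b2) empty
        with pytest.raises(ValidationError):
            two_way_anova(y, a, b)
        res = two_way_anova(y, a, b, interaction=False)
        assert res.interaction is None


class TestTukeyHsd:
    def test_equal_means_p_near_one(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=30)
        g = np.repeat(["a", "b"], 15)
        res = tukey_hsd(y, g)
        assert res["pvalue"].iloc[0] > 0.5

    def test_two_groups_equals_pooled_t_test(self):
        """For k = 2 the Tukey adjusted p equals the pooled-variance t-test
        p (q = sqrt(2) |t|)."""
        rng = np.random.default_rng(7)
        y = np.concatenate([rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)])
        g = np.array(["a"] * 12 + ["b"] * 15)
        res = tukey_hsd(y, g)
        t = ss.ttest_ind(y[g == "a"], y[g == "b"], equal_var=True)
        assert res["pvalue"].iloc[0] == pytest.approx(t.pvalue, rel=1e-6)

    def test_three_groups_match_integration_oracle(self):
        """Adjusted p equals independent numeric integration of the
        studentized-range distribution."""
        rng = np.random.default_rng(8)
        groups = [rng.normal(m, 1, 8) for m in (0.0, 0.5, 1.2)]
        y = np.concatenate(groups)
        g = np.repeat(["a", "b", "c"], 8)
        res = tukey_hsd(y, g)
        ms_err = np.mean([gr.var(ddof=1) for gr in groups])
        df = len(y) - 3
        row = res[(res["level_1"] == "a") & (res["level_2"] == "c")].iloc[0]
        se = np.sqrt(ms_err / 8)
        q = abs(groups[0].mean() - groups[2].mean()) / se
        assert row["pvalue"] == pytest.approx(
            studentized_range_sf_oracle(q, 3, df), abs=1e-6
        )

    def test_adjusted_p_not_below_unadjusted_t(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(m, 1, 10) for m in (0, 0.3, 0.9, 1.1)]
        y = np.concatenate(groups)
        g = np.repeat(list("abcd"), 10)
        res = tukey_hsd(y, g)
        for _, row in res.iterrows():
            ga = y[g == row["level_1"]]
            gb = y[g == row["level_2"]]
            t = ss.ttest_ind(ga, gb, equal_var=True)
            assert row["pvalue"] >= t.pvalue - 1e-12

    def test_level_with_too_few_observations(self):
        with pytest.raises(ValidationError):
            tukey_hsd([1.0, 2.0, 3.0], ["a", "a", "b"])


# ---------------------------------------------------- preprocess + corr

class TestPreprocess:
    def test_mean_imputation(self):
        m = pd.DataFrame({"f": [1.0, np.nan, 3.0, 2.0, 2.0]})
        out = impute_missing(m)  # mean of observed = 2; 20% missing is allowed
        assert out["f"].tolist() == [1.0, 2.0, 3.0, 2.0, 2.0]

    def test_no_missing_is_identity(self):
        m = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        pd.testing.assert_frame_equal(impute_missing(m), m)

    def test_excess_missingness_rejected(self):
        m = pd.DataFrame({"f": [np.nan] * 21 + [1.0] * 79, "g": range(100)},
                         dtype=float)
        with pytest.raises(ValidationError):
            impute_missing(m)

    def test_autoscale_mean_zero_unit_sd(self):
        m = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        out = autoscale(m)
        assert out["f"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["f"].std(ddof=1) == pytest.approx(1.0)

    def test_autoscale_idempotent(self):
        rng = np.random.default_rng(10)
        m = pd.DataFrame(rng.normal(2, 5, size=(30, 4)))
        once = autoscale(m)
        twice = autoscale(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            autoscale(pd.DataFrame({"f": [2.0, 2.0, 2.0]}))

    def test_sklearn_pipeline_composition(self):
        from sklearn.pipeline import Pipeline

        from metabodrift.preprocess import MeanImputer

        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 3))
        X[2, 1] = np.nan
        pipe = Pipeline([("impute", MeanImputer()), ("scale", Autoscaler())])
        out = pipe.fit_transform(X)
        assert np.isfinite(out).all()
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)


class TestCorrelationCluster:
    def test_diagonal_and_anticorrelation(self):
        x = np.arange(10.0)
        m = pd.DataFrame({"x": x, "neg": -x, "noise": np.cos(x)})
        res = correlation_cluster(m)
        assert res.corr.loc["x", "x"] == pytest.approx(1.0)
        assert res.corr.loc["x", "neg"] == pytest.approx(-1.0)

    def test_block_structure_keeps_blocks_contiguous(self):
        """Two independent correlated blocks: the dendrogram leaf order
        keeps each block's members adjacent."""
        rng = np.random.default_rng(12)
        n = 200
        z1, z2 = rng.normal(size=n), rng.normal(size=n)
        cols = {}
        for j in range(4):
            cols[f"blk1_{j}"] = z1 + 0.3 * rng.normal(size=n)
        for j in range(4):
            cols[f"blk2_{j}"] = z2 + 0.3 * rng.normal(size=n)
        res = correlation_cluster(pd.DataFrame(cols))
        order = res.row_order
        first_block = ["blk1" in c for c in order]
        # block membership must be contiguous along the leaf order
        switches = sum(
            first_block[i] != first_block[i + 1] for i in range(len(order) - 1)
        )
        assert switches == 1

    def test_rectangular_clinical_correlation(self):
        rng = np.random.default_rng(13)
        n = 100
        chol = rng.normal(5, 1, n)
        feats = pd.DataFrame({
            "lipid1": chol * 2 + rng.normal(0, 0.5, n),
            "unrelated": rng.normal(size=n),
        })
        clin = pd.DataFrame({"CHOL": chol, "GLUC": rng.normal(5, 1, n)})
        res = correlation_cluster(feats, clin)
        assert res.corr.loc["lipid1", "CHOL"] > 0.9
        assert abs(res.corr.loc["unrelated", "GLUC"]) < 0.3
        assert set(res.row_order) == {"lipid1", "unrelated"}

    def test_top_k_selection(self):
        rng = np.random.default_rng(14)
        n = 150
        z = rng.normal(size=n)
        m = pd.DataFrame({
            "a": z, "b": z + 0.1 * rng.normal(size=n),
            "c": rng.normal(size=n), "d": rng.normal(size=n),
        })
        res = correlation_cluster(m, top_k=2)
        assert set(res.corr.columns) == {"a", "b"}

    def test_zero_variance_dropped(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0],
                          "b": [2.0, 2.0, 2.0, 2.0],
                          "c": [4.0, 3.0, 2.0, 1.0]})
        res = correlation_cluster(m)
        assert "b" not in res.corr.columns
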