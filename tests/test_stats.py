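"""Statistical routines against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from lungadc import (
    anova_oneway,
    cohort_dataframe,
    cohort_report,
    holm_bonferroni,
    mann_whitney,
    ols_fit,
    pearson_with_p,
)
from lungadc.errors import StatsError


def brute_force_mw_p(a, b):
    """Oracle: enumerate every labelling of the pooled sample."""
    pooled = np.concatenate([a, b])
    na = len(a)
    mu = na * len(b) / 2

    def u_stat(idx):
        s = set(idx)
        av = [pooled[i] for i in idx]
        bv = [pooled[i] for i in range(len(pooled)) if i not in s]
        return sum(1.0 for x in av for y in bv if x > y) \
            + 0.5 * sum(1.0 for x in av for y in bv if x == y)

    obs = abs(u_stat(range(na)) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        total += 1
        if abs(u_stat(idx) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_complete_separation_hand_case(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.100, abs=1e-12)

    def test_identical_groups_give_p_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 6), rng.integers(2, 7)
        # integer draws force ties so the mid-rank path is exercised
        a = rng.integers(0, 6, na).astype(float)
        b = rng.integers(0, 6, nb).astype(float)
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(brute_force_mw_p(a, b), abs=1e-12)

    def test_tie_free_exact_agrees_with_scipy(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=6)
        b = rng.normal(1.0, size=7)
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(
            sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=15)
        b = rng.normal(0.8, size=15)
        _, p = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic").pvalue
        assert p == pytest.approx(ref, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            mann_whitney([], [1.0])


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10.0)
        r, p, n = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_hand_computed_r(self):
        r, _, _ = pearson_with_p([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(0.9820, abs=5e-5)

    def test_listwise_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.1, 6.0, np.nan, 9.9]
        r, p, n = pearson_with_p(x, y)
        assert n == 3
        r_ref, _ = sps.pearsonr([1, 2, 5], [2, 4.1, 9.9])
        assert r == pytest.approx(r_ref)

    def test_constant_input_rejected(self):
        with pytest.raises(StatsError, match="constant"):
            pearson_with_p([1, 1, 1], [1, 2, 3])


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_down(self):
        out = holm_bonferroni([0.01, 0.02, 0.04])
        np.testing.assert_allclose(out, [0.03, 0.04, 0.04])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    def test_dominates_raw_and_matches_statsmodels(self, ps):
        out = holm_bonferroni(ps)
        assert (out >= np.asarray(ps) - 1e-15).all()
        assert (out <= 1.0).all()
        ref = multipletests(ps, method="holm")[1]
        np.testing.assert_allclose(out, ref, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=15), st.integers(0, 10_000))
    def test_order_invariance(self, ps, seed):
        perm = np.random.default_rng(seed).permutation(len(ps))
        out = holm_bonferroni(ps)
        out_perm = holm_bonferroni(np.asarray(ps)[perm])
        np.testing.assert_allclose(out_perm, out[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            holm_bonferroni([0.5, 1.2])


class TestOls:
    def test_exact_line_single_predictor(self):
        res = ols_fit([1.0, 3.0, 5.0], {"x": [0.0, 1.0, 2.0]})
        assert res.row("x").coef == pytest.approx(2.0)
        assert res.row("intercept").coef == pytest.approx(1.0)
        assert res.row("x").se == pytest.approx(0.0, abs=1e-12)

    def test_recovers_noiseless_coefficients(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        beta = np.array([1.5, -2.0, 0.25])
        y = X.to_numpy() @ beta + 0.7
        res = ols_fit(y, X)
        for name, b in zip("abc", beta):
            assert res.row(name).coef == pytest.approx(b, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 2))
        y = X @ [1.0, -1.0] + rng.normal(0, 0.5, 20)
        res = ols_fit(y, {"x1": X[:, 0], "x2": X[:, 1]})
        Xd = np.column_stack([np.ones(20), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        resid = y - Xd @ beta
        s2 = resid @ resid / (20 - 3)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(Xd.T @ Xd)))
        for i, name in enumerate(["intercept", "x1", "x2"]):
            assert res.row(name).coef == pytest.approx(beta[i], rel=1e-10)
            assert res.row(name).se == pytest.approx(se[i], rel=1e-10)
            assert res.row(name).t == pytest.approx(beta[i] / se[i], rel=1e-10)

    def test_rank_deficiency_names_collinear_columns(self):
        x = np.arange(8.0)
        with pytest.raises(StatsError, match="x2"):
            ols_fit(np.arange(8.0), {"x1": x, "x2": 2 * x})


class TestAnova:
    def test_identical_groups(self):
        f, p = anova_oneway([1.0, 1.0], [1.0, 1.0])
        assert f == 0.0 and p == 1.0

    def test_two_groups_equals_squared_t(self):
        a = [1.0, 2.0, 4.0, 5.0]
        b = [3.0, 6.0, 7.0, 9.0]
        f, p_f = anova_oneway(a, b)
        t, p_t = sps.ttest_ind(a, b)
        assert f == pytest.approx(t ** 2)
        assert p_f == pytest.approx(p_t)

    def test_hand_sums_of_squares(self):
        # SSB = 3*((2-3)^2 + 0 + (4-3)^2) = 6 on 2 df; SSW = 2+2+2 = 6 on
        # 6 df; F = 3/1 = 3
        f, _ = anova_oneway([1, 2, 3], [2, 3, 4], [3, 4, 5])
        assert f == pytest.approx(3.0)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(StatsError):
            anova_oneway([1.0], [2.0, 3.0])


@pytest.fixture(scope="module")
def report():
    return cohort_report(cohort_dataframe())


class TestCohortReport:

    def test_group_means(self, report):
        gs = report.group_summary
        he = gs[(gs["group"] == "COPD") & (gs["metric"] == "adc_he3_b1p6")].iloc[0]
        assert he["mean"] == pytest.approx(0.476, abs=5e-4)
        assert he["n"] == 10

    def test_correlation_cells(self, report):
        assert report.correlation("ra950_pct", "adc_he3_b1p6")["r"] == \
            pytest.approx(0.90, abs=0.01)
        assert report.correlation("hu15_hu", "adc_xe129_b12")["r"] == \
            pytest.approx(-0.90, abs=0.01)

    def test_holm_dominates_raw(self, report):
        c = report.correlations
        assert (c["p_holm"] >= c["p_raw"] - 1e-15).all()
        assert report.holm_family_size == 20

    def test_listwise_deletion_for_sparse_b30(self, report):
        assert report.correlation("ra950_pct", "adc_xe129_b30")["n"] == 3

    def test_schema_mismatch_rejected(self):
        with pytest.raises(StatsError, match="lacks columns"):
            cohort_report(pd.DataFrame({"group": ["COPD"]}))
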