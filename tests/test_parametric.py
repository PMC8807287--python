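"""Parametric endpoints: pooled t, one-sample t, JZS Bayes factors,
chi-square, Spearman / partial Spearman, PCA composites, Bonferroni."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vigimem.parametric import (
    bonferroni,
    chi_square_2x2,
    jzs_bayes_factor,
    one_sample_t,
    partial_spearman,
    pca_composite,
    pooled_t_from_summary,
    round_printed,
    spearman,
    two_sample_t,
)
from vigimem.resampling import InferenceError


class TestPooledT:
    def test_identical_summaries_give_zero(self):
        res = pooled_t_from_summary(5.0, 2.0, 30, 5.0, 2.0, 40)
        assert res.t == 0.0
        assert res.df == 68
        assert res.p == pytest.approx(1.0)

    def test_summary_equals_raw_data_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(1.0, 2.0, rng.integers(3, 40))
            b = rng.normal(0.0, 3.0, rng.integers(3, 40))
            raw = two_sample_t(a, b)
            summ = pooled_t_from_summary(
                a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
            )
            assert raw.t == pytest.approx(summ.t, rel=1e-12)
            assert raw.df == summ.df
            # cross-check against scipy's pooled t on the raw samples
            t_sp, p_sp = stats.ttest_ind(a, b, equal_var=True)
            assert raw.t == pytest.approx(t_sp, rel=1e-10)
            assert raw.p == pytest.approx(p_sp, rel=1e-10)

    def test_zero_pooled_variance(self):
        assert pooled_t_from_summary(3.0, 0.0, 5, 3.0, 0.0, 5).t == 0.0
        res = pooled_t_from_summary(4.0, 0.0, 5, 3.0, 0.0, 5)
        assert math.isinf(res.t) and res.t > 0
        assert res.p == 0.0

    def test_welch_flag(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 20), rng.normal(0, 5, 35)
        res = two_sample_t(a, b, welch=True)
        t_sp, p_sp = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(t_sp, rel=1e-10)
        assert res.p == pytest.approx(p_sp, rel=1e-6)


class TestOneSampleT:
    def test_all_equal_to_mu0(self):
        assert one_sample_t([2.0, 2.0, 2.0], mu0=2.0).t == 0.0

    def test_symmetric_sample(self):
        assert one_sample_t([1.0, 2.0, 3.0], mu0=2.0).t == 0.0

    def test_direct_formula(self):
        res = one_sample_t([1.0, 2.0, 3.0], mu0=0.0)
        assert res.t == pytest.approx(2.0 * math.sqrt(3.0))
        assert res.df == 2


class TestJZSBayesFactor:
    def test_null_favoured_at_t_zero(self):
        bf10, bf01 = jzs_bayes_factor(0.0, 30, 40)
        assert bf10 < 1.0
        assert bf01 == pytest.approx(1.0 / bf10, rel=1e-9)

    def test_identity_on_grid(self):
        for t in (0.0, 1.0, 2.5, 4.0):
            bf10, bf01 = jzs_bayes_factor(t, 25, 30)
            assert bf10 * bf01 == pytest.approx(1.0, rel=1e-9)

    def test_monotone_in_t(self):
        bfs = [jzs_bayes_factor(t, 53, 83)[0] for t in np.arange(0.0, 5.5, 0.5)]
        assert all(x < y for x, y in zip(bfs, bfs[1:]))

    def test_matches_trapezoid_oracle(self):
        """Independent high-resolution trapezoid quadrature over g."""

        def oracle(t, na, nb, r=math.sqrt(2) / 2):
            eff_n = na * nb / (na + nb)
            df = na + nb - 2
            # integrate over u = log(g) on a wide grid
            u = np.linspace(-14, 14, 200_001)
            g = np.exp(u)
            prior = (r**2 / 2) ** 0.5 / math.gamma(0.5) * g**-1.5 * np.exp(
                -(r**2) / (2 * g)
            )
            like = (1 + eff_n * g) ** -0.5 * (
                1 + t**2 / ((1 + eff_n * g) * df)
            ) ** (-(df + 1) / 2)
            alt = np.trapezoid(like * prior * g, u)  # dg = g du
            null = (1 + t**2 / df) ** (-(df + 1) / 2)
            return alt / null

        for t, na, nb in [(2.72, 53, 83), (0.5, 10, 12), (3.3, 36, 44), (1.0, 40, 40)]:
            bf10, _ = jzs_bayes_factor(t, na, nb)
            assert bf10 == pytest.approx(oracle(t, na, nb), rel=1e-6)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        for t, na, nb in [(2.72, 53, 83), (3.0, 36, 44), (0.9, 44, None)]:
            bf10, _ = jzs_bayes_factor(t, na, nb)
            ref = float(pg.bayesfactor_ttest(t, na, nb, paired=nb is None))
            # pingouin's own quadrature tolerance is looser than ours
            assert bf10 == pytest.approx(ref, rel=2e-3)

    def test_scale_invariance_of_raw_data(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(1, 2, 18), rng.normal(0, 2, 22)
        r1 = two_sample_t(a, b)
        r2 = two_sample_t(a * 37.5, b * 37.5)
        assert r1.t == pytest.approx(r2.t, rel=1e-12)
        assert r1.bf10 == pytest.approx(r2.bf10, rel=1e-9)

    def test_df_below_one_rejected(self):
        with pytest.raises(InferenceError):
            jzs_bayes_factor(1.0, 1)


class TestChiSquare:
    def test_uniform_table_is_zero(self):
        chi2, df, p = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            table = rng.integers(1, 60, size=(2, 2)).astype(float)
            chi2, _, p = chi_square_2x2(table)
            n = table.sum()
            expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
            ref = ((table - expected) ** 2 / expected).sum()
            assert chi2 == pytest.approx(ref, rel=1e-10)
            assert p == pytest.approx(stats.chi2.sf(ref, 1), rel=1e-10)

    def test_zero_marginal_undefined(self):
        chi2, _, p = chi_square_2x2([[0, 0], [5, 7]])
        assert math.isnan(chi2) and math.isnan(p)

    def test_bad_shapes_and_values(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            chi_square_2x2([[1.5, 2], [3, 4]])


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.linspace(-3, 3, 50)
        assert spearman(x, x**3)[0] == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(3)
        rhos = [
            spearman(rng.normal(size=200), rng.normal(size=200))[0] for _ in range(200)
        ]
        se = np.std(rhos, ddof=1) / np.sqrt(len(rhos))
        assert abs(np.mean(rhos)) < 3 * se


class TestPartialSpearman:
    def test_no_covariates_is_plain_spearman(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=40), rng.normal(size=40)
        assert partial_spearman(x, y) == pytest.approx(spearman(x, y))

    def test_identity_with_irrelevant_covariate(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        rho, _ = partial_spearman(x, x.copy(), z)
        assert rho == pytest.approx(1.0)

    def test_shared_covariate_removed(self):
        rng = np.random.default_rng(6)
        rhos = []
        for _ in range(150):
            c = rng.normal(size=120)
            x = c + 0.3 * rng.normal(size=120)
            y = c + 0.3 * rng.normal(size=120)
            rhos.append(partial_spearman(x, y, c)[0])
        se = np.std(rhos, ddof=1) / np.sqrt(len(rhos))
        assert abs(np.mean(rhos)) < 3 * se

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "x": rng.normal(size=60),
                "y": rng.normal(size=60),
                "c1": rng.normal(size=60),
                "c2": rng.normal(size=60),
            }
        )
        df["y"] += 0.5 * df["x"] + 0.4 * df["c1"]
        rho, p = partial_spearman(df["x"], df["y"], df[["c1", "c2"]].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"], method="spearman")
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-8)

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=30), rng.normal(size=30)
        z = rng.normal(size=30)
        with pytest.raises(InferenceError):
            partial_spearman(x, y, np.column_stack([z, z]))


class TestPCAComposite:
    def test_single_column_gives_z_scores(self):
        rng = np.random.default_rng(9)
        col = pd.DataFrame({"a": rng.normal(5, 2, 30)})
        cs = pca_composite(col)
        z = (col["a"] - col["a"].mean()) / col["a"].std(ddof=1)
        assert np.allclose(np.abs(cs.scores), np.abs(z))
        assert cs.variance_explained == pytest.approx(1.0)

    def test_identical_columns_fully_explained(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=25)
        cs = pca_composite(pd.DataFrame({"a": a, "b": a.copy()}))
        assert cs.variance_explained == pytest.approx(1.0)

    def test_matches_sklearn_oracle_up_to_sign(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(11)
        for _ in range(50):
            X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
            X["b"] += 0.7 * X["a"]
            cs = pca_composite(X)
            Z = (X - X.mean()) / X.std(ddof=1)
            ref = sklearn_pca.PCA(n_components=1).fit(Z)
            load_ref = ref.components_[0]
            sign = np.sign(np.dot(load_ref, cs.loadings.to_numpy()))
            assert np.allclose(cs.loadings.to_numpy(), sign * load_ref, atol=1e-8)
            assert cs.variance_explained == pytest.approx(
                float(ref.explained_variance_ratio_[0]), rel=1e-8
            )

    def test_scores_zero_mean_and_positive_orientation(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        X["b"] += X["a"]
        cs = pca_composite(X)
        assert abs(cs.scores.mean()) < 1e-10
        Z = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
        assert np.corrcoef(cs.scores, Z.mean(axis=1))[0, 1] > 0

    def test_zero_variance_column_dropped(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame({"a": rng.normal(size=20), "flat": 3.0})
        with pytest.warns(UserWarning, match="zero-variance"):
            cs = pca_composite(X)
        assert cs.dropped_columns == ("flat",)


class TestBonferroni:
    def test_battery_family_adjustment(self):
        assert bonferroni([0.001], 29)[0] == pytest.approx(0.029)

    def test_capped_at_one(self):
        assert bonferroni([0.5], 29)[0] == 1.0

    def test_zero_stays_zero(self):
        assert bonferroni([0.0], 1000)[0] == 0.0

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2, 0.3], 2)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_never_decreases_p(self, ps):
        adj = bonferroni(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)


@pytest.mark.parametrize(
    "value,expected",
    [(2.65, 2.7), (-2.65, -2.7), (-2.649, -2.6), (0.04, 0.0), (-7.16, -7.2)],
)
def test_round_half_away_from_zero(value, expected):
    assert round_printed(value) == pytest.approx(expected)
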