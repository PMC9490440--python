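"""The statistical battery against independent oracles: covariance-formula
Pearson r, closed-form Fisher discriminants, brute-force determinant-ratio
Wilks' lambda (cross-checked against statsmodels MANOVA), and Holm's
guarantee that adjusted p >= raw p."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioapatite import stats as bs
from bioapatite.errors import (
    DegenerateDesignError,
    InsufficientClassError,
    InsufficientDataError,
)


class TestScaling:
    def test_hand_computed_column(self):
        out = bs.zscore_scale(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        X = rng.normal(size=(20, 4))
        once = bs.zscore_scale(X)
        twice = bs.zscore_scale(once)
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_constant_column_zeroed_with_warning(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = bs.zscore_scale(X)
        assert np.all(out[:, 1] == 0.0)

    def test_single_row_rejected(self):
        with pytest.raises(InsufficientDataError):
            bs.zscore_scale(np.ones((1, 3)))


class TestRegression:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = bs.linregress_vs_pmi(x, 2.0 * x)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_r_matches_covariance_formula(self, seed):
        r = np.random.default_rng(seed)
        x = r.uniform(0, 365, 10)
        y = r.normal(size=10)
        res = bs.linregress_vs_pmi(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_oracle = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert res.r == pytest.approx(r_oracle, abs=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateDesignError):
            bs.linregress_vs_pmi([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_group_mean_mode(self):
        x = np.array([0, 0, 14, 14, 91, 91], dtype=float)
        y = np.array([1.0, 3.0, 4.0, 6.0, 9.0, 11.0])
        res = bs.linregress_vs_pmi(x, y, unit="group_mean")
        assert res.n == 3
        res_oracle = bs.linregress_vs_pmi([0, 14, 91], [2.0, 5.0, 10.0])
        assert res.slope == pytest.approx(res_oracle.slope)

    def test_one_sided_halves_p_for_positive_slope(self, rng):
        x = np.arange(20.0)
        y = x + rng.normal(0, 3, 20)
        two = bs.linregress_vs_pmi(x, y)
        one = bs.linregress_vs_pmi(x, y, alternative="greater")
        if two.r > 0:
            assert one.p == pytest.approx(two.p / 2)


class TestPca:
    def test_rank_one_data(self, rng):
        direction = np.array([1.0, 2.0, -1.0])
        X = rng.normal(size=(30, 1)) * direction
        res = bs.pca(X)
        assert res.explained_pct[0] == pytest.approx(100.0)

    def test_known_diagonal_covariance(self, rng):
        X = rng.normal(0, 1, size=(20000, 2)) * np.sqrt([4.0, 1.0])
        res = bs.pca(X)
        assert res.explained_pct[0] == pytest.approx(80.0, abs=1.5)
        assert res.explained_pct[1] == pytest.approx(20.0, abs=1.5)

    def test_explained_sums_to_100_loadings_orthonormal(self, rng):
        X = bs.zscore_scale(rng.normal(size=(40, 6)))
        res = bs.pca(X)
        assert res.explained_pct.sum() == pytest.approx(100.0, abs=1e-8)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_sign_convention(self, rng):
        X = rng.normal(size=(30, 4))
        res = bs.pca(X)
        for col in res.loadings.columns:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0


class TestLda:
    def test_separable_two_class(self, rng):
        a = rng.normal(0, 1, size=(25, 3))
        b = rng.normal(0, 1, size=(25, 3))
        b[:, 0] += 20.0  # >= 10 pooled SDs apart on one feature
        X = np.vstack([a, b])
        y = np.array(["u"] * 25 + ["b"] * 25)
        res = bs.lda(X, y)
        assert res.accuracy == 1.0

    def test_posteriors_sum_to_one_and_argmax(self, rng):
        X = rng.normal(size=(40, 4))
        y = np.repeat(["a", "b", "c", "d"], 10)
        res = bs.lda(X, y)
        np.testing.assert_allclose(res.posteriors.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_array_equal(
            res.predictions, res.classes[np.argmax(res.posteriors, axis=1)])
        assert res.scores.shape[1] <= len(res.classes) - 1

    def test_direction_matches_closed_form_fisher(self, rng):
        """Two-class LDA direction is proportional to pooled_Sigma^-1 (mu1-mu2)."""
        a = rng.normal(0, 1, size=(12, 3)) @ np.array([[1, .3, 0], [0, 1, .2], [0, 0, 1.0]])
        b = a[:10] * 0.9 + np.array([1.0, -0.5, 0.4])
        X = np.vstack([a, b])
        y = np.array(["a"] * len(a) + ["b"] * len(b))
        res = bs.lda(X, y)
        Sa = np.cov(a, rowvar=False, ddof=1) * (len(a) - 1)
        Sb = np.cov(b, rowvar=False, ddof=1) * (len(b) - 1)
        pooled = (Sa + Sb) / (len(a) + len(b) - 2)
        w_oracle = np.linalg.solve(pooled, a.mean(0) - b.mean(0))
        w = res.coefficients["LD1"].to_numpy()
        cos = abs(w @ w_oracle) / (np.linalg.norm(w) * np.linalg.norm(w_oracle))
        assert cos > 0.9999

    def test_small_class_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(InsufficientClassError):
            bs.lda(X, np.array(["a", "a", "a", "a", "b"]))


def brute_force_wilks(X, y):
    """Independent oracle: explicit det(W)/det(W+B) from per-group loops."""
    X = np.asarray(X, dtype=float)
    grand = X.mean(axis=0)
    W = np.zeros((X.shape[1],) * 2)
    T = np.zeros_like(W)
    for row, g in zip(X, y):
        mu = X[np.asarray(y) == g].mean(axis=0)
        W += np.outer(row - mu, row - mu)
        T += np.outer(row - grand, row - grand)
    return np.linalg.det(W) / np.linalg.det(T)


class TestManova:
    def test_lambda_matches_brute_force(self, rng):
        X = rng.normal(size=(15, 2))
        y = np.repeat(["a", "b", "c"], 5)
        res = bs.manova_with_mct(X, y)
        assert res.wilks_lambda == pytest.approx(brute_force_wilks(X, y), abs=1e-10)

    def test_matches_statsmodels(self, rng):
        """Cross-check Wilks' lambda and its F p-value against the
        independent statsmodels MANOVA implementation."""
        from statsmodels.multivariate.manova import MANOVA

        X = rng.normal(size=(30, 3))
        y = np.repeat(["g1", "g2", "g3"], 10)
        X[y == "g2"] += 0.8
        res = bs.manova_with_mct(X, y)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["grp"] = y
        sm = MANOVA.from_formula("a + b + c ~ grp", data=df).mv_test()
        tbl = sm.results["grp"]["stat"]
        assert res.wilks_lambda == pytest.approx(tbl.loc["Wilks' lambda", "Value"], abs=1e-8)
        assert res.p == pytest.approx(tbl.loc["Wilks' lambda", "Pr > F"], abs=1e-8)

    def test_identical_groups_lambda_near_one(self, rng):
        a = rng.normal(size=(10, 2))
        X = np.vstack([a, a + rng.normal(0, 1e-9, a.shape)])
        y = np.array(["a"] * 10 + ["b"] * 10)
        res = bs.manova_with_mct(X, y)
        assert res.wilks_lambda > 0.999
        assert res.p > 0.99

    def test_holm_adjusted_geq_raw_and_bounded(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.repeat(["a", "b", "c", "d"], 10)
        res = bs.manova_with_mct(X, y)
        pw = res.pairwise
        assert np.all(pw["p_adj"] >= pw["p_raw"] - 1e-15)
        assert np.all(pw["p_adj"] <= 1.0)
        assert 0.0 < res.wilks_lambda <= 1.0

    def test_bonferroni_mode(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.repeat(["a", "b", "c"], 10)
        res = bs.manova_with_mct(X, y, method="bonferroni")
        np.testing.assert_allclose(
            res.pairwise["p_adj"],
            np.minimum(1.0, res.pairwise["p_raw"] * 3), atol=1e-12)

    def test_hotelling_reduces_to_t_test_in_1d(self, rng):
        from scipy import stats as sps
        a = rng.normal(0, 1, size=(12, 1))
        b = rng.normal(0.5, 1, size=(15, 1))
        t2, p = bs.hotelling_t2(a, b)
        t_res = sps.ttest_ind(a[:, 0], b[:, 0], equal_var=True)
        assert t2 == pytest.approx(t_res.statistic**2, rel=1e-10)
        assert p == pytest.approx(t_res.pvalue, rel=1e-10)


class TestParameterRecovery:
    def test_slope_signs_recovered_on_synthetic_trends(self):
        """Configured monotone trends (unburnt K down, burnt Cl up) are
        recovered with the right sign in >= 95% of seeded replicates."""
        from bioapatite import empa, synthetic as syn

        trends = syn.make_default_trends()
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            design = syn.StudyDesign(
                groups=tuple(("burnt", p, 3) for p in syn.PMI_ANCHORS),
                points_per_zone=4, seed=seed, low_total_fraction=0.0)
            el = empa.oxide_to_element(syn.simulate_empa_table(design, trends))
            res_k = bs.linregress_vs_pmi(el["pmi_days"], el["K"])
            res_cl = bs.linregress_vs_pmi(el["pmi_days"], el["Cl"])
            hits += (res_k.slope < 0) and (res_cl.slope > 0)
        assert hits >= 0.95 * n_rep
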