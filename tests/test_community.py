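"""Composition-change statistics: dissimilarity, ordination contract,
axis regressions, family chi-square, rank correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from extirpa.community import (axis_trend_regression, bray_curtis_matrix,
                               family_composition_test, filter_year_samples,
                               ordinate, period_rank_correlation)


def frame(cols: dict) -> pd.DataFrame:
    return pd.DataFrame(cols)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis_matrix(frame({"a": [1, 2, 3], "b": [1, 2, 3]}))
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_disjoint_samples_one(self):
        d = bray_curtis_matrix(frame({"a": [5, 0, 0], "b": [0, 3, 2]}))
        assert d.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_worked_value(self):
        # (10,0,5) vs (2,8,5): 1 - 2*(2+0+5)/(15+15) = 0.5333...
        d = bray_curtis_matrix(frame({"a": [10, 0, 5], "b": [2, 8, 5]}))
        assert d.loc["a", "b"] == pytest.approx(1 - 14 / 30)

    def test_symmetry_range_zero_diagonal(self, rng):
        m = frame({f"s{i}": rng.integers(0, 20, 12) + (1 if i == 0 else 0)
                   for i in range(5)})
        m.iloc[0] += 1  # no all-zero columns
        d = bray_curtis_matrix(m)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d.to_numpy() >= 0).all() and (d.to_numpy() <= 1).all()

    def test_zero_total_sample_error_names_sample(self):
        with pytest.raises(ValueError, match="bad_year"):
            bray_curtis_matrix(frame({"ok": [1, 2], "bad_year": [0, 0]}))


class TestOrdination:
    def test_equidistant_triangle_near_zero_stress(self):
        d = pd.DataFrame(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]),
                         index=list("abc"), columns=list("abc"))
        res = ordinate(d, dims=2, seed=0)
        emb = res.coordinates.to_numpy()
        dd = np.linalg.norm(emb[:, None] - emb[None, :], axis=-1)
        off = dd[np.triu_indices(3, 1)]
        assert off.std() / off.mean() < 0.05  # near-equilateral embedding

    def test_duplicated_pair_nearly_coincident(self):
        d = pd.DataFrame(np.array([
            [0, 0.0, 0.8, 0.7],
            [0.0, 0, 0.8, 0.7],
            [0.8, 0.8, 0, 0.6],
            [0.7, 0.7, 0.6, 0.0]]), index=list("abcd"), columns=list("abcd"))
        res = ordinate(d, dims=2, seed=0)
        emb = res.coordinates.to_numpy()
        pair = np.linalg.norm(emb[0] - emb[1])
        others = np.linalg.norm(emb[2] - emb[3])
        assert pair < 0.2 * others

    def test_rank_preservation_on_random_matrix(self, rng):
        pts = rng.random((10, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d += rng.random(d.shape) * 0.01
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dd = pd.DataFrame(d)
        res = ordinate(dd, dims=2, seed=1)
        emb = res.coordinates.to_numpy()
        de = np.linalg.norm(emb[:, None] - emb[None, :], axis=-1)
        iu = np.triu_indices(10, 1)
        rho, _ = stats.spearmanr(d[iu], de[iu])
        assert rho > 0.5

    def test_too_many_dims_error(self):
        d = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            ordinate(d, dims=3)

    def test_reproducible_under_seed(self, rng):
        d = np.abs(rng.random((6, 6)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dd = pd.DataFrame(d)
        a = ordinate(dd, dims=2, seed=5).coordinates
        b = ordinate(dd, dims=2, seed=5).coordinates
        pd.testing.assert_frame_equal(a, b)


class TestAxisRegression:
    def test_exact_linear_scores_r2_one(self):
        year = np.arange(2000, 2010)
        effort = np.array([300, 500, 420, 310, 800, 650, 700, 450, 380, 900])
        scores = 0.03 * year - 1.0
        res = axis_trend_regression(scores, year, effort)
        assert res.r2 == pytest.approx(1.0)
        assert res.coef_p["year"] < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        year = np.arange(1990, 2002).astype(float)
        effort = rng.integers(300, 1000, year.size).astype(float)
        scores = 0.1 * year - 0.001 * effort + rng.normal(0, 0.5, year.size)
        res = axis_trend_regression(scores, year, effort)
        X = np.column_stack([np.ones(year.size), year, effort])
        beta = np.linalg.solve(X.T @ X, X.T @ scores)
        assert res.coefficients["year"] == pytest.approx(beta[1], rel=1e-8)
        assert res.coefficients["effort"] == pytest.approx(beta[2], rel=1e-8)
        rss = np.sum((scores - X @ beta) ** 2)
        tss = np.sum((scores - scores.mean()) ** 2)
        assert res.r2 == pytest.approx(1 - rss / tss, rel=1e-8)

    def test_collinear_predictors_error(self):
        year = np.arange(2000, 2008).astype(float)
        with pytest.raises(ValueError, match="collinear"):
            axis_trend_regression(np.ones(8), year, 2 * year)

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError):
            axis_trend_regression([1, 2, 3], [1, 2, 3], [4, 5, 6])


class TestFamilyComposition:
    def test_identical_proportions_chi2_zero(self):
        tab = pd.DataFrame({"old": [10, 20, 30], "recent": [20, 40, 60]},
                           index=["f1", "f2", "f3"])
        res = family_composition_test(tab)
        assert res.chi2 == pytest.approx(0.0)
        assert res.df == 2

    def test_hand_worked_two_by_two(self):
        tab = pd.DataFrame({"old": [10, 0], "recent": [0, 10]},
                           index=["f1", "f2"])
        res = family_composition_test(tab)
        assert res.chi2 == pytest.approx(20.0)
        assert res.df == 1

    def test_zero_row_dropped_with_warning(self):
        tab = pd.DataFrame({"old": [10, 0, 5], "recent": [8, 0, 9]},
                           index=["f1", "gone", "f3"])
        with pytest.warns(UserWarning, match="gone"):
            res = family_composition_test(tab)
        assert list(res.table.index) == ["f1", "f3"]

    def test_shares_sum_to_100_per_period(self, rng):
        tab = pd.DataFrame({"old": rng.integers(1, 500, 6),
                            "recent": rng.integers(1, 500, 6)})
        res = family_composition_test(tab)
        assert res.shares.sum(axis=0).to_numpy() == pytest.approx([100.0, 100.0])


class TestRankCorrelation:
    def test_concordant_and_reversed(self):
        a = pd.Series([1, 5, 9, 20], index=list("wxyz"))
        assert period_rank_correlation(a, a * 3)[0] == pytest.approx(1.0)
        b = pd.Series([20, 9, 5, 1], index=list("wxyz"))
        assert period_rank_correlation(a, b)[0] == pytest.approx(-1.0)

    def test_tied_example_matches_rank_formula_oracle(self):
        a = pd.Series([3, 3, 1, 7, 2], index=list("abcde"))
        b = pd.Series([1, 4, 4, 9, 2], index=list("abcde"))
        rho, n, _ = period_rank_correlation(a, b)
        ra = stats.rankdata(a)  # average ranks
        rb = stats.rankdata(b)
        expected = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(expected, rel=1e-12)
        assert n == 5

    def test_default_inclusion_rule_drops_double_zeros(self):
        a = pd.Series([0, 1, 2, 0], index=list("abcd"))
        b = pd.Series([0, 2, 1, 3], index=list("abcd"))
        _, n, _ = period_rank_correlation(a, b)
        assert n == 3

    def test_constant_vector_error(self):
        a = pd.Series([1, 1, 1], index=list("abc"))
        b = pd.Series([1, 2, 3], index=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            period_rank_correlation(a, b)


def test_filter_year_samples_threshold():
    m = pd.DataFrame({"y1": [200, 50], "y2": [250, 100], "y3": [10, 5]})
    kept = filter_year_samples(m, min_individuals=300)
    assert list(kept.columns) == ["y2"]
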