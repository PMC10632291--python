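"""OLS/WLS fits against explicit normal-equations oracles, totals, tests."""

import numpy as np
import pytest
from scipy import stats

import triqtl as tq
from triqtl.design import ModelDesign


def _design(G, kinds=None):
    n, k = G.shape
    terms = [("intercept",)]
    for j in range(1, k):
        terms.append(("add", f"m{j}") if kinds is None else kinds[j])
    return ModelDesign(G, terms)


def _random_instance(seed, n=None, k=None):
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(20, 201))
    k = k or int(rng.integers(2, 11))
    G = np.column_stack([np.ones(n), rng.choice([-1.0, 1.0], size=(n, k - 1))])
    y = rng.normal(size=n)
    w = rng.uniform(0.1, 10.0, size=n)
    return _design(G), y, w


def normal_equations(G, y, w=None):
    """Independent oracle: solve G'W^{-1}G a = G'W^{-1}y by matrix inverse."""
    Winv = np.eye(len(y)) if w is None else np.diag(1.0 / w)
    return np.linalg.inv(G.T @ Winv @ G) @ G.T @ Winv @ y


class TestFits:
    def test_intercept_only(self):
        d = _design(np.ones((3, 1)))
        fit = tq.fit_unweighted([3.0, 3.0, 3.0], d)
        assert fit.coef[0] == pytest.approx(3.0, abs=1e-12)

    def test_balanced_column_exact(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        d = _design(np.column_stack([np.ones(4), x]))
        fit = tq.fit_unweighted(2 * x, d)
        np.testing.assert_allclose(fit.coef, [0.0, 2.0], atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equations_oracle(self, seed):
        d, y, w = _random_instance(seed, n=30, k=6)
        np.testing.assert_allclose(
            tq.fit_unweighted(y, d).coef, normal_equations(d.G, y), atol=1e-8)
        np.testing.assert_allclose(
            tq.fit_weighted(y, d, w).coef, normal_equations(d.G, y, w), atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_equal_weights_reduce_to_unweighted(self, seed):
        d, y, _ = _random_instance(seed)
        u = tq.fit_unweighted(y, d)
        w = tq.fit_weighted(y, d, np.full(y.size, 3.7))
        np.testing.assert_allclose(u.coef, w.coef, atol=1e-10)
        assert w.r2 == pytest.approx(u.r2, abs=1e-10)

    def test_huge_variance_approaches_leave_one_out(self):
        d, y, _ = _random_instance(12, n=40, k=4)
        w = np.ones(40)
        w[0] = 1e9
        full = tq.fit_weighted(y, d, w)
        loo = tq.fit_unweighted(y[1:], ModelDesign(d.G[1:], d.terms))
        np.testing.assert_allclose(full.coef, loo.coef, atol=1e-4)

    def test_residuals_orthogonal_to_design(self):
        d, y, w = _random_instance(13)
        fit = tq.fit_weighted(y, d, w)
        np.testing.assert_allclose(d.G.T @ (fit.weights * fit.resid),
                                   0.0, atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        G = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(np.linalg.LinAlgError, match="check_full_rank"):
            tq.fit_unweighted(np.arange(10.0), _design(G))

    def test_nonpositive_weights_rejected(self):
        d, y, w = _random_instance(14)
        w[0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            tq.fit_weighted(y, d, w)

    def test_r2_in_unit_interval(self):
        for seed in range(5):
            d, y, w = _random_instance(seed + 100)
            assert 0.0 <= tq.fit_weighted(y, d, w).r2 <= 1.0


def _triple_fit(effects, seed=0, n=64):
    """A fit whose triple coefficients are (nearly) the given effects."""
    rng = np.random.default_rng(seed)
    k = len(effects)
    X = rng.choice([-1.0, 1.0], size=(n, k))
    G = np.column_stack([np.ones(n), X])
    kinds = {j + 1: ("triple", f"a{j}", f"b{j}", f"c{j}") for j in range(k)}
    d = _design(G, {0: ("intercept",), **kinds})
    y = G @ np.concatenate([[1.0], effects]) + 1e-9 * rng.normal(size=n)
    return tq.fit_unweighted(y, d)


class TestTotals:
    def test_zero_triples(self):
        d = _design(np.column_stack([np.ones(8), np.arange(8.0)]))
        fit = tq.fit_unweighted(np.arange(8.0) * 2, d)
        total, lo, hi, count = tq.total_aaa(fit)
        assert total == 0.0 and count == 0

    def test_single_triple_total_equals_effect(self):
        # one significant triple of effect 15.61: count 1, min=max=total
        fit = _triple_fit([15.61])
        total, lo, hi, count = tq.total_aaa(fit)
        assert count == 1
        assert total == pytest.approx(15.61, abs=1e-6)
        assert lo == pytest.approx(hi) == pytest.approx(total)

    def test_total_is_sum_min_max(self):
        fit = _triple_fit([2.0, -5.0, 7.0])
        total, lo, hi, count = tq.total_aaa(fit, which="all_retained")
        assert total == pytest.approx(4.0, abs=1e-6)
        assert (lo, hi, count) == (pytest.approx(-5.0, abs=1e-6),
                                   pytest.approx(7.0, abs=1e-6), 3)
        # totals are literal sums of the reported parts
        idx = fit.design.columns_of("triple")
        assert total == pytest.approx(float(fit.coef[idx].sum()), abs=1e-10)

    def test_significant_only_drops_null_triples(self):
        rng = np.random.default_rng(5)
        X = rng.choice([-1.0, 1.0], size=(100, 2))
        d = _design(np.column_stack([np.ones(100), X]),
                    {0: ("intercept",), 1: ("triple", "a", "b", "c"),
                     2: ("triple", "d", "e", "f")})
        y = 5.0 * X[:, 0] + rng.normal(size=100)  # second triple is pure noise
        fit = tq.fit_unweighted(y, d)
        _, _, _, count = tq.total_aaa(fit, which="significant_only")
        assert count == 1


class TestVarianceExplained:
    def test_zero_coefficient_explains_nothing(self):
        rng = np.random.default_rng(6)
        x1 = rng.choice([-1.0, 1.0], 50)
        x2 = np.where(rng.random(50) < 0.5, x1, -x1)  # partial overlap
        y = 3.0 * x1 + rng.normal(size=50)
        d = _design(np.column_stack([np.ones(50), x1, x2]),
                    {0: ("intercept",), 1: ("add", "m1"),
                     2: ("triple", "a", "b", "c")})
        fit = tq.fit_unweighted(y, d)
        pct = tq.triple_variance_explained(y, d, fit, ("triple", "a", "b", "c"))
        assert 0.0 <= pct <= fit.r2 * 100 + 1e-9

    def test_saturated_triple_explains_everything(self):
        rng = np.random.default_rng(7)
        t = rng.choice([-1.0, 1.0], 40)
        d = _design(np.column_stack([np.ones(40), t]),
                    {0: ("intercept",), 1: ("triple", "a", "b", "c")})
        y = 2.0 + 4.0 * t
        fit = tq.fit_unweighted(y, d)
        pct = tq.triple_variance_explained(y, d, fit, ("triple", "a", "b", "c"))
        assert pct == pytest.approx(100.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_two_refit_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        X = rng.choice([-1.0, 1.0], size=(n, 4))
        kinds = {0: ("intercept",), 1: ("add", "m1"), 2: ("add", "m2"),
                 3: ("pair", "m1", "m2"), 4: ("triple", "m1", "m2", "m3")}
        d = _design(np.column_stack([np.ones(n), X]), kinds)
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + rng.normal(size=n)
        w = rng.uniform(0.5, 2.0, n)
        fit = tq.fit_weighted(y, d, w)
        pct = tq.triple_variance_explained(y, d, fit, kinds[4])
        # oracle: two independent weighted refits via normal equations
        Winv = np.diag(1.0 / w)

        def rss(G):
            a = np.linalg.inv(G.T @ Winv @ G) @ G.T @ Winv @ y
            r = y - G @ a
            return r @ Winv @ r

        wmean = (y / w).sum() / (1.0 / w).sum()
        tss = ((y - wmean) ** 2 / w).sum()
        expected = 100.0 * (rss(d.G[:, :4]) - rss(d.G)) / tss
        assert pct == pytest.approx(expected, rel=1e-8)


class TestCoefficientTests:
    def test_zero_estimate(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        d = _design(np.column_stack([np.ones(6), x]))
        fit = tq.fit_unweighted(np.array([1.0, 1.0, -2.0, -2.0, 1.0, 1.0]), d)
        tests = fit.coefficient_tests().set_index("term")
        row = tests.loc[[("add", "m1")]]
        assert row["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert row["p"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_null_pvalues_uniform(self):
        """Coefficient p-values of a null triple are U(0,1) (KS test)."""
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(400):
            X = rng.choice([-1.0, 1.0], size=(25, 2))
            d = _design(np.column_stack([np.ones(25), X]),
                        {0: ("intercept",), 1: ("add", "m"),
                         2: ("triple", "a", "b", "c")})
            y = 1.0 + 0.5 * X[:, 0] + rng.normal(size=25)
            fit = tq.fit_unweighted(y, d)
            tests = fit.coefficient_tests().set_index("term")
            pvals.append(float(tests.loc[[("triple", "a", "b", "c")], "p"].iloc[0]))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_se_scales_with_replication(self):
        # duplicating every row halves the SE (up to the df correction)
        d, y, _ = _random_instance(21, n=50, k=3)
        fit1 = tq.fit_unweighted(y, d)
        d2 = ModelDesign(np.vstack([d.G, d.G]), d.terms)
        fit2 = tq.fit_unweighted(np.concatenate([y, y]), d2)
        s1 = fit1.sigma2
        s2 = fit2.sigma2
        # analytic oracle: SE2/SE1 = sqrt(s2 / (2 s1))
        np.testing.assert_allclose(fit2.se / fit1.se,
                                   np.sqrt(s2 / (2 * s1)), rtol=1e-8)
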