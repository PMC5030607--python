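"""Permutation inference: OLS oracle agreement, QAP mechanics, Geary's C."""
import itertools
import math

import numpy as np
import pytest

import gestnet as g
from gestnet.errors import DegenerateInputError, InputError, SizeError
from gestnet.inference import (
    geary_c,
    mrqap_dsp,
    mrqap_exhaustive,
    node_regression,
    ols_standardized,
    qap_node_permutation,
    vectorize_offdiag,
)

from conftest import random_matrix


def _zscore(v):
    return (v - v.mean(0)) / v.std(0)


class TestOlsStandardized:
    def test_identity_fit(self):
        x = np.arange(10.0)
        beta, r2 = ols_standardized(x, x)
        assert beta[0] == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_matches_hand_normal_equations(self, rng):
        y = rng.normal(size=40)
        X = rng.normal(size=(40, 2))
        beta, r2 = ols_standardized(y, X, names=["a", "b"])
        yz, Xz = _zscore(y), _zscore(X)
        expected = np.linalg.solve(Xz.T @ Xz, Xz.T @ yz)  # independent oracle
        np.testing.assert_allclose(beta, expected, atol=1e-10)
        resid = yz - Xz @ expected
        np.testing.assert_allclose(r2, 1 - resid @ resid / (yz @ yz), atol=1e-10)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        y = rng.normal(size=30)
        X = rng.normal(size=(30, 3))
        beta, r2 = ols_standardized(y, X)
        fit = sm.OLS(_zscore(y), _zscore(X)).fit()
        np.testing.assert_allclose(beta, fit.params, atol=1e-10)

    def test_constant_column_named_in_error(self):
        with pytest.raises(DegenerateInputError, match="flat"):
            ols_standardized(np.arange(5.0), np.ones((5, 1)), names=["flat"])


class TestQapNodePermutation:
    def test_identity_noop(self):
        m = random_matrix(4, 0)
        out = qap_node_permutation(m, {l: l for l in m.labels})
        np.testing.assert_array_equal(
            np.nan_to_num(out.values), np.nan_to_num(m.values)
        )

    def test_inverse_roundtrip(self):
        m = random_matrix(5, 1)
        perm = dict(zip(m.labels, m.labels[1:] + m.labels[:1]))
        inv = {v: k for k, v in perm.items()}
        back = qap_node_permutation(qap_node_permutation(m, perm), inv)
        np.testing.assert_array_equal(
            np.nan_to_num(back.values), np.nan_to_num(m.values)
        )

    def test_index_chase_3x3(self):
        # output cell (i, j) = input cell (p[i], p[j]) for index-array form
        m = random_matrix(3, 2)
        p = [2, 0, 1]
        out = qap_node_permutation(m, p)
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert out.values[i, j] == m.values[p[i], p[j]]

    def test_non_bijection_rejected(self):
        m = random_matrix(3, 0)
        with pytest.raises(InputError):
            qap_node_permutation(m, [0, 0, 1])
        with pytest.raises(InputError):
            qap_node_permutation(m, {l: m.labels[0] for l in m.labels})


class TestMrqapDsp:
    def test_perfect_predictor(self):
        y = random_matrix(6, 3)
        res = mrqap_dsp(y, [y], n_perm=200, seed=0)
        assert res.beta[0] == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p[0] == pytest.approx(1 / 201)

    def test_observed_beta_equals_normal_equations(self, rng):
        Y = random_matrix(7, 10)
        Xs = [random_matrix(7, 11 + k) for k in range(3)]
        res = mrqap_dsp(Y, Xs, n_perm=10, seed=0)
        cols = _zscore(vectorize_offdiag([Y, *Xs]))
        expected = np.linalg.solve(
            cols[:, 1:].T @ cols[:, 1:], cols[:, 1:].T @ cols[:, 0]
        )
        np.testing.assert_allclose(res.beta, expected, atol=1e-8)

    def test_p_value_bounds(self):
        Y = random_matrix(6, 21)
        Xs = [random_matrix(6, 22)]
        res = mrqap_dsp(Y, Xs, n_perm=99, seed=1)
        assert 1 / 100 <= res.p[0] <= 1.0

    def test_collinear_predictors_rejected(self):
        Y = random_matrix(5, 0)
        X = random_matrix(5, 1)
        with pytest.raises(DegenerateInputError):
            mrqap_dsp(Y, [X, X], n_perm=10, seed=0)

    def test_too_small(self):
        with pytest.raises(SizeError):
            mrqap_dsp(random_matrix(3, 0), [random_matrix(3, 1)], n_perm=10, seed=0)

    def test_seed_determinism(self):
        Y, X = random_matrix(6, 5), random_matrix(6, 6)
        r1 = mrqap_dsp(Y, [X], n_perm=100, seed=9)
        r2 = mrqap_dsp(Y, [X], n_perm=100, seed=9)
        assert r1 == r2

    def test_relabeling_invariance(self):
        # one simultaneous node permutation of Y and all Xs leaves the
        # observed statistics and the exhaustive p unchanged exactly
        Y = random_matrix(5, 30)
        Xs = [random_matrix(5, 31), random_matrix(5, 32)]
        p = [3, 1, 4, 0, 2]
        Yp = qap_node_permutation(Y, p)
        Xsp = [qap_node_permutation(x, p) for x in Xs]
        a = mrqap_exhaustive(Y, Xs)
        b = mrqap_exhaustive(Yp, Xsp)
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-10)
        assert a.r_squared == pytest.approx(b.r_squared, abs=1e-10)
        assert a.p == b.p

    def test_tstat_option_runs(self):
        Y, X = random_matrix(6, 5), random_matrix(6, 6)
        res = mrqap_dsp(Y, [X], n_perm=99, seed=0, permute_stat="tstat")
        assert 0 < res.p[0] <= 1


class TestMrqapExhaustive:
    def test_enumerates_full_group(self):
        res = mrqap_exhaustive(random_matrix(4, 1), [random_matrix(4, 2)])
        assert res.n_perm == math.factorial(4) == 24
        assert res.engine == "exhaustive"

    def test_identity_guarantees_minimum_p(self):
        res = mrqap_exhaustive(random_matrix(5, 3), [random_matrix(5, 4)])
        assert all(p >= 1 / math.factorial(5) for p in res.p)

    def test_refuses_large_n(self):
        with pytest.raises(SizeError):
            mrqap_exhaustive(random_matrix(8, 0), [random_matrix(8, 1)])

    def test_sampled_converges_to_exhaustive(self):
        # Monte-Carlo agreement on a fixed n=5 instance within 3 binomial SE
        Y, X = random_matrix(5, 40), random_matrix(5, 41)
        exact = mrqap_exhaustive(Y, [X]).p[0]
        n_perm = 4000
        sampled = mrqap_dsp(Y, [X], n_perm=n_perm, seed=5).p[0]
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(sampled - exact) <= 3 * se + 1 / (n_perm + 1)


class TestGearyC:
    def _net(self, vals, labels=None):
        labels = labels or tuple(f"i{k}" for k in range(len(vals)))
        return g.DyadicMatrix(labels=labels, values=np.asarray(vals, float))

    def test_two_node_hand_computation(self):
        net = self._net([[np.nan, 1.0], [1.0, np.nan]])
        res = geary_c([0.0, 1.0], net, n_perm=50, seed=0)
        assert res.c == pytest.approx(1.0)

    def test_perfectly_assortative_is_zero(self):
        # ties only within groups of equal attribute value
        vals = np.zeros((4, 4))
        vals[0, 1] = vals[1, 0] = vals[2, 3] = vals[3, 2] = 1.0
        res = geary_c([5.0, 5.0, 9.0, 9.0], self._net(vals), n_perm=200, seed=0)
        assert res.c == 0.0  # all within-tie attribute differences vanish

    def test_exhaustive_permutation_mean_is_one(self):
        # null expectation over the full permutation group equals 1 exactly
        rng = np.random.default_rng(3)
        n = 5
        vals = rng.random((n, n))
        x = rng.normal(size=n)
        rows, cols = g.offdiag_indices(n)
        w = vals[rows, cols]
        ss = ((x - x.mean()) ** 2).sum()
        cs = []
        for p in itertools.permutations(range(n)):
            xp = x[list(p)]
            cs.append((n - 1) * (w * (xp[rows] - xp[cols]) ** 2).sum() / (2 * w.sum() * ss))
        assert np.mean(cs) == pytest.approx(1.0, abs=1e-12)

    def test_monte_carlo_null_mean_matches(self):
        net = g.dichotomize(random_matrix(10, 8))
        res = geary_c(np.random.default_rng(4).normal(size=10), net,
                      n_perm=3000, seed=2)
        assert res.c_perm_mean == pytest.approx(1.0, abs=0.05)

    def test_affine_invariance(self):
        net = g.dichotomize(random_matrix(8, 9))
        x = np.random.default_rng(5).normal(size=8)
        a = geary_c(x, net, n_perm=10, seed=0)
        b = geary_c(3.5 * x - 7.0, net, n_perm=10, seed=0)
        assert a.c == pytest.approx(b.c, rel=1e-12)

    def test_weighted_vs_binary_modes(self):
        net = random_matrix(6, 10)
        x = np.random.default_rng(6).normal(size=6)
        cb = geary_c(x, net, n_perm=10, seed=0, weights="binary").c
        cw = geary_c(x, net, n_perm=10, seed=0, weights="weighted").c
        assert cb != cw  # weights matter for a non-binary network

    def test_degenerate_inputs(self):
        net = self._net([[np.nan, 1.0], [1.0, np.nan]])
        with pytest.raises(DegenerateInputError):
            geary_c([2.0, 2.0], net, n_perm=10, seed=0)
        empty = self._net([[np.nan, 0.0], [0.0, np.nan]])
        with pytest.raises(InputError):
            geary_c([0.0, 1.0], empty, n_perm=10, seed=0)


class TestNodeRegression:
    def test_perfect_fit(self):
        x = np.arange(8.0)
        res = node_regression(x, x, n_perm=499, seed=0)
        assert res.beta[0] == pytest.approx(1.0)
        assert res.p[0] == pytest.approx(1 / 500)

    def test_planted_node_effect_sign(self, rng):
        x = rng.normal(size=30)
        y = 0.9 * x + rng.normal(scale=0.5, size=30)
        res = node_regression(y, np.column_stack([x, rng.normal(size=30)]),
                              n_perm=999, seed=1, predictor_names=["planted", "noise"])
        assert res.beta[0] > 0
        assert res.p[0] < 0.05
        assert res.p[1] > 0.05

    def test_saturated_design_allowed(self, rng):
        # as many predictors as nodes: exact fit, permutation p still informative
        y = rng.normal(size=8)
        X = rng.normal(size=(8, 8))
        res = node_regression(y, X, n_perm=99, seed=0)
        assert res.r_squared == pytest.approx(1.0)
        assert all(0 < p <= 1 for p in res.p)

    def test_rank_deficiency_rejected_when_strict(self, rng):
        y = rng.normal(size=6)
        x = rng.normal(size=6)
        with pytest.raises(DegenerateInputError):
            node_regression(y, np.column_stack([x, x]), n_perm=10, seed=0,
                            allow_rank_deficient=False)

    def test_too_small(self):
        with pytest.raises(SizeError):
            node_regression(np.arange(3.0), np.arange(3.0), n_perm=10, seed=0)
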