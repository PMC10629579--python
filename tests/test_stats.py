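"""Connectivity statistics: permutation tests, FDR, the M ~ (W'W)^1/2
relation, subspace alignment and orderings."""

import numpy as np
import pytest

from ornln.data import ActivityEnsemble, InputError
from ornln.stats import (
    bh_fdr,
    hierarchical_order,
    mean_rectified_correlation,
    mw_relation_test,
    perm_test_correlations,
    sqrt_psd,
    subspace_alignment,
    tuning_curve,
    type_average,
)
from ornln.synthetic import make_connectome_like


class TestTypeAverage:
    def test_hand_example(self):
        W = np.array([[1.0, 3.0, 10.0], [2.0, 4.0, 20.0]])
        A, types = type_average(W, ["a", "a", "b"])
        assert types == ["a", "b"]
        assert np.allclose(A, [[2.0, 10.0], [3.0, 20.0]])

    def test_label_count_mismatch(self):
        with pytest.raises(InputError):
            type_average(np.eye(2), ["a"])


class TestTuningCurve:
    def test_sorted_descending_with_labels(self, rng):
        X = rng.standard_normal((5, 4))
        ens = ActivityEnsemble(X, sample_labels=list("abcd"))
        w = X[:, 2] + 0.01 * rng.standard_normal(5)
        curve = tuning_curve(w, ens)
        rs = [r for _, r in curve]
        assert rs == sorted(rs, reverse=True)
        assert curve[0][0] == "c"  # most-correlated pattern is its template

    def test_constant_w_rejected(self, rng):
        ens = ActivityEnsemble(rng.standard_normal((4, 3)))
        with pytest.raises(InputError):
            tuning_curve(np.ones(4), ens)


class TestPermTest:
    def test_exact_enumeration_self_correlation(self):
        # w identical to the target: only the identity permutation of 3! = 6
        # reaches r = 1, so the exact one-sided p-value is 1/6
        w = np.array([1.0, 2.0, 3.0])
        res = perm_test_correlations(w, w[:, None], n_perm=1000)
        assert res.exact
        assert res.n_perm == 6
        assert res.pvalues[0] == pytest.approx(1 / 6)
        assert res.observed[0] == pytest.approx(1.0)

    def test_unrelated_target_large_p(self, rng):
        w = rng.standard_normal(12)
        tgt = rng.standard_normal((12, 1))
        res = perm_test_correlations(w, tgt, n_perm=999, seed=0)
        assert not res.exact
        assert res.pvalues[0] > 0.001  # add-one estimator can never hit 0

    def test_constant_target_nan(self, rng):
        w = rng.standard_normal(10)
        tgt = np.column_stack([np.ones(10), rng.standard_normal(10)])
        res = perm_test_correlations(w, tgt, n_perm=99)
        assert np.isnan(res.pvalues[0]) and np.isfinite(res.pvalues[1])
        assert not res.fdr_flags[0]

    def test_two_sided_detects_anticorrelation(self, rng):
        w = np.arange(12.0)
        res_one = perm_test_correlations(w, -w[:, None], n_perm=999, seed=1)
        res_two = perm_test_correlations(w, -w[:, None], n_perm=999, sidedness="two_sided", seed=1)
        assert res_one.pvalues[0] > 0.5
        assert res_two.pvalues[0] < 0.01

    def test_determinism(self, rng):
        w = rng.standard_normal(10)
        tgt = rng.standard_normal((10, 3))
        r1 = perm_test_correlations(w, tgt, n_perm=200, seed=7)
        r2 = perm_test_correlations(w, tgt, n_perm=200, seed=7)
        assert np.array_equal(r1.pvalues, r2.pvalues)


class TestBHFDR:
    def test_matches_step_up_definition(self, rng):
        p = rng.uniform(size=40)
        q = 0.1
        flags = bh_fdr(p, q)
        # brute-force step-up: largest k with p_(k) <= k q / m
        order = np.argsort(p)
        m = p.size
        k_star = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k * q / m:
                k_star = k
        expected = np.zeros(m, bool)
        expected[order[:k_star]] = True
        assert np.array_equal(flags, expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_fdr([0.5, 1.5])


class TestSqrtPSD:
    def test_square_recovers_input(self, rng):
        A = rng.standard_normal((4, 4))
        S = A @ A.T
        R = sqrt_psd(S)
        assert np.allclose(R @ R, S, rtol=1e-8, atol=1e-10)
        assert np.allclose(R, R.T)

    def test_indefinite_rejected(self):
        with pytest.raises(InputError):
            sqrt_psd(np.diag([1.0, -0.5]))

    def test_asymmetric_rejected(self, rng):
        with pytest.raises(InputError):
            sqrt_psd(rng.standard_normal((3, 3)))


class TestMWRelation:
    def test_exact_relation_detected(self):
        W, M, _, _ = make_connectome_like(seed=0, noise_sd=0.0)
        r, p, res = mw_relation_test(W, M, n_perm=500, seed=0)
        assert r == pytest.approx(1.0, abs=1e-10)
        assert p < 0.01

    def test_shuffled_m_not_detected(self, rng):
        W, M, _, _ = make_connectome_like(seed=0, noise_sd=0.0)
        K = M.shape[0]
        perm = rng.permutation(K)
        M_shuf = M[np.ix_(perm, perm)]
        # keep symmetric but scramble the off-diagonal structure vs W
        iu = np.triu_indices(K, 1)
        vals = rng.permutation(M[iu])
        M_shuf = np.diag(np.diag(M)).astype(float)
        M_shuf[iu] = vals
        M_shuf = M_shuf + np.triu(M_shuf, 1).T
        r_s, p_s, _ = mw_relation_test(W, M_shuf, n_perm=500, seed=0)
        assert r_s < 0.9

    def test_k1_rejected(self):
        with pytest.raises(InputError):
            mw_relation_test(np.ones((3, 1)), np.ones((1, 1)))


class TestMeanRectifiedCorrelation:
    def test_hand_example(self):
        R = np.array([[1.0, 0.5, -0.2], [0.5, 1.0, 0.0], [-0.2, 0.0, 1.0]])
        # off-diagonal entries: 0.5, -0.2, 0.5, 0.0, -0.2, 0.0 -> rectified mean 1/6
        assert mean_rectified_correlation(R) == pytest.approx(1.0 / 6.0)

    def test_non_correlation_rejected(self):
        with pytest.raises(InputError):
            mean_rectified_correlation(np.array([[2.0, 0.0], [0.0, 2.0]]))


class TestSubspaceAlignment:
    def test_identical_spans_fully_aligned(self, rng):
        A = rng.standard_normal((20, 3))
        B = A @ rng.standard_normal((3, 3))  # same span
        angles, n_sig, pvals = subspace_alignment(A, B, n_perm=200, seed=0)
        assert np.allclose(angles, 0.0, atol=1e-8)
        assert n_sig == 3

    def test_random_spans_not_aligned(self, rng):
        A = rng.standard_normal((20, 3))
        B = rng.standard_normal((20, 3))
        _, n_sig, pvals = subspace_alignment(A, B, n_perm=200, seed=0)
        assert n_sig <= 1  # chance-level alignment

    def test_rank_deficient_rejected(self):
        A = np.ones((5, 2))
        with pytest.raises(InputError):
            subspace_alignment(A, np.eye(5)[:, :2])


class TestHierarchicalOrder:
    def test_groups_similar_columns_adjacently(self, rng):
        base1 = rng.standard_normal(30)
        base2 = rng.standard_normal(30)
        V = np.column_stack(
            [base1, base2, base1 + 0.01 * rng.standard_normal(30), base2 + 0.01 * rng.standard_normal(30)]
        )
        order = hierarchical_order(V).tolist()
        pos = {c: order.index(c) for c in range(4)}
        assert abs(pos[0] - pos[2]) == 1
        assert abs(pos[1] - pos[3]) == 1

    def test_deterministic(self, rng):
        V = rng.standard_normal((10, 5))
        assert np.array_equal(hierarchical_order(V), hierarchical_order(V))

    def test_constant_column_rejected(self):
        with pytest.raises(InputError):
            hierarchical_order(np.column_stack([np.ones(5), np.arange(5.0)]))
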