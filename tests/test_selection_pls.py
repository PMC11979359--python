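"""Feature selection, PLS-SVD, permutation inference and correspondence."""

import numpy as np
import pytest
from scipy import stats

from gswave.selection_pls import (
    PLSPermutation,
    correspondence,
    pca_correspondence,
    pls_fit,
    pls_permutation,
    replication_thresholds,
    select_features,
)


def planted_cross_cohort(rng, n, p=30, q=29, n_factors=2, strength=1.0):
    """X and Y sharing latent factors with fixed loading patterns."""
    lx = np.zeros((p, n_factors))
    ly = np.zeros((q, n_factors))
    lx[: p // 2, 0], lx[p // 2:, 1] = 1.0, 0.7
    ly[: q // 2, 0], ly[q // 2:, 1] = 0.9, 0.8
    F = rng.standard_normal((n, n_factors)) * np.array([1.5, 1.0])
    X = strength * F @ lx.T + rng.standard_normal((n, p))
    Y = strength * F @ ly.T + rng.standard_normal((n, q))
    return X, Y, lx, ly


class TestSelection:
    def test_skew_filter_applied_first(self, rng):
        X = rng.standard_normal((200, 10))
        X[:, 3] = np.exp(2 * rng.standard_normal(200))  # heavy right skew
        B = rng.standard_normal((200, 5))
        B[:, 0] = X[:, 3] + 0.01 * rng.standard_normal(200)
        sel = select_features(X, B, method="correlation", k=5)
        assert 3 in sel.skew_excluded
        assert 3 not in sel.indices

    def test_perfectly_correlated_feature_ranks_first(self, rng):
        X = rng.standard_normal((100, 20))
        B = rng.standard_normal((100, 3))
        X[:, 7] = B[:, 1]
        sel = select_features(X, B, method="correlation", k=1)
        assert sel.indices.tolist() == [7]

    def test_matches_exhaustive_oracle(self, rng):
        """Selection equals brute-force 'all 200 x 26 correlations, top 30'."""
        X = rng.standard_normal((150, 200))
        B = rng.standard_normal((150, 26))
        sel = select_features(X, B, method="correlation", k=30)
        skews = stats.skew(X, axis=0, bias=False)
        scores = np.full(200, -np.inf)
        for j in range(200):
            if abs(skews[j]) <= 1:
                scores[j] = max(abs(np.corrcoef(X[:, j], B[:, m])[0, 1]) for m in range(26))
        oracle = np.sort(np.argsort(-scores, kind="stable")[:30])
        assert np.array_equal(sel.indices, oracle)

    def test_icc_and_combined_methods(self, rng):
        X = rng.standard_normal((80, 50))
        B = rng.standard_normal((80, 5))
        iccs = rng.uniform(0, 1, 50)
        sel_icc = select_features(X, B, method="icc", k=10, iccs=iccs)
        eligible = np.abs(stats.skew(X, axis=0, bias=False)) <= 1
        top = np.sort(np.argsort(-np.where(eligible, iccs, -np.inf), kind="stable")[:10])
        assert np.array_equal(sel_icc.indices, top)
        sel_comb = select_features(X, B, method="combined", k=10, iccs=iccs)
        assert sel_comb.indices.size == 10

    def test_dynamic_method_returns_change_scores(self, rng):
        n, n_seq, p = 90, 6, 40
        P = rng.standard_normal((n, n_seq, p))
        B = rng.standard_normal((n, 4))
        # feature 11 couples to behavior 2 only in the last sequence
        P[:, 5, 11] = B[:, 2] + 0.3 * rng.standard_normal(n)
        sel = select_features(P.mean(axis=1), B, method="dynamic", k=5, per_sequence=P)
        assert 11 in sel.indices
        vals = sel.values(P.mean(axis=1), P)
        assert vals.shape == (n, 5)

    def test_small_pool_keeps_all_with_warning(self, rng):
        X = rng.standard_normal((50, 8))
        B = rng.standard_normal((50, 3))
        with pytest.warns(UserWarning, match="eligible"):
            sel = select_features(X, B, method="correlation", k=30)
        assert sel.indices.size <= 8


class TestPLS:
    def test_identity_coupling_perfect_first_component(self, rng):
        X = rng.standard_normal((60, 30))
        res = pls_fit(X, X.copy(), n_comp=5)
        assert res.score_correlations[0] == pytest.approx(1.0, abs=1e-10)

    def test_null_first_component_overfits_positive(self, rng):
        """Independent matrices still show a positive first score correlation
        (the overfitting that motivates permutation inference)."""
        rs = [
            pls_fit(rng.standard_normal((100, 30)), rng.standard_normal((100, 29))).score_correlations[0]
            for _ in range(20)
        ]
        assert np.mean(rs) > 0.3

    def test_planted_two_factor_recovery(self, rng):
        X, Y, lx, ly = planted_cross_cohort(rng, n=2000)
        res = pls_fit(X, Y, n_comp=4)
        for k in range(2):
            rx = abs(np.corrcoef(res.x_saliences[:, k], lx[:, k])[0, 1])
            ry = abs(np.corrcoef(res.y_saliences[:, k], ly[:, k])[0, 1])
            assert rx > 0.95 and ry > 0.95

    def test_constant_column_error_names_column(self, rng):
        X = rng.standard_normal((50, 5))
        X[:, 2] = 1.0
        with pytest.raises(ValueError, match=r"\[2\]"):
            pls_fit(X, rng.standard_normal((50, 4)))

    def test_estimator_interface(self, rng):
        X, Y, *_ = planted_cross_cohort(rng, n=80)
        est = PLSPermutation(n_components=3, n_perm=200, seed=0).fit(X, Y)
        assert est.perm_p_.shape == (3,)
        assert est.get_params()["n_perm"] == 200
        # determinism under the same seed
        est2 = PLSPermutation(n_components=3, n_perm=200, seed=0).fit(X, Y)
        assert np.array_equal(est.perm_p_, est2.perm_p_)


class TestPermutation:
    def test_strong_association_attains_minimum_p(self, rng):
        X, Y, *_ = planted_cross_cohort(rng, n=300, strength=3.0)
        res = pls_permutation(X, Y, n_perm=300, seed=1)
        assert res.perm_p[0] == pytest.approx(1.0 / 301.0)

    def test_default_n_perm_is_5000(self):
        assert PLSPermutation().n_perm == 5000

    def test_low_n_perm_warns(self, rng):
        with pytest.warns(UserWarning, match="very low"):
            pls_permutation(rng.standard_normal((40, 6)), rng.standard_normal((40, 5)), n_perm=50)

    def test_null_type_i_error_calibrated(self, rng):
        """First-component permutation p is ~uniform under independence."""
        n_rep = 120
        pvals = []
        for rep in range(n_rep):
            X = rng.standard_normal((60, 15))
            Y = rng.standard_normal((60, 12))
            res = pls_permutation(X, Y, n_perm=200, seed=rep, n_comp=3)
            pvals.append(res.perm_p[0])
        pvals = np.array(pvals)
        assert abs(np.mean(pvals < 0.05) - 0.05) < 0.06
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCorrespondence:
    def test_identity_diagonal_one(self, rng):
        X, Y, *_ = planted_cross_cohort(rng, n=100)
        res = pls_fit(X, Y, n_comp=4)
        rep = correspondence(res, res)
        assert np.allclose(rep.x_diagonal, 1.0)
        assert np.allclose(rep.y_diagonal, 1.0)

    def test_sign_flip_invariance(self, rng):
        X, Y, *_ = planted_cross_cohort(rng, n=100)
        res = pls_fit(X, Y, n_comp=4)
        import copy

        flipped = copy.deepcopy(res)
        flipped.x_saliences = -flipped.x_saliences
        flipped.y_saliences = -flipped.y_saliences
        rep = correspondence(res, flipped)
        assert np.allclose(rep.x_diagonal, 1.0)
        assert np.all(rep.sign_flips == -1)

    def test_shared_factors_reproduce_leading_components(self, rng):
        Xa, Ya, *_ = planted_cross_cohort(rng, n=400, strength=1.5)
        Xb, Yb, *_ = planted_cross_cohort(rng, n=400, strength=1.5)
        rep = correspondence(pls_fit(Xa, Ya), pls_fit(Xb, Yb))
        assert np.all(rep.x_diagonal[:2] > 0.7)
        assert rep.x_diagonal[:2].min() > np.median(rep.x_diagonal[4:])

    def test_differing_feature_sets_raise(self, rng):
        a = pls_fit(rng.standard_normal((50, 10)), rng.standard_normal((50, 5)))
        b = pls_fit(rng.standard_normal((50, 12)), rng.standard_normal((50, 5)))
        with pytest.raises(ValueError, match="feature"):
            correspondence(a, b)


class TestPCACorrespondence:
    def test_identical_matrices_diagonal_one(self, rng):
        X = rng.standard_normal((80, 12))
        res = pca_correspondence(X, X.copy(), n_comp=5)
        assert np.allclose(res["diagonal"], 1.0)

    def test_shared_three_factor_structure(self, rng):
        def cohort():
            # unequal block sizes keep the correlation-matrix eigenvalues
            # well separated after column standardization
            F = rng.standard_normal((500, 3))
            L = np.zeros((15, 3))
            L[:7, 0], L[7:12, 1], L[12:, 2] = 1.2, 1.0, 0.8
            return F @ L.T + 0.4 * rng.standard_normal((500, 15))

        res = pca_correspondence(cohort(), cohort(), n_comp=6)
        assert np.all(res["diagonal"][:3] > 0.8)

    def test_independent_noise_low_correspondence(self, rng):
        res = pca_correspondence(
            rng.standard_normal((200, 20)), rng.standard_normal((200, 20)), n_comp=6
        )
        assert np.mean(res["diagonal"]) < 0.5


class TestReplicationThresholds:
    @pytest.mark.parametrize("count,expected", [(15, 0.0033), (4, 0.0125), (1, 0.05)])
    def test_paper_thresholds(self, count, expected):
        assert replication_thresholds(count) == expected

    def test_zero_count_sentinel(self):
        assert replication_thresholds(0) is None


class TestSelectionLeakage:
    def test_training_anticonservative_frozen_test_calibrated(self, rng):
        """Correlation-based selection inflates training-sample significance;
        frozen indices evaluated on an independent cohort stay calibrated."""
        n_rep = 150
        train_sig = 0
        test_p = []
        for rep in range(n_rep):
            Xtr = rng.standard_normal((60, 150))
            Btr = rng.standard_normal((60, 10))
            sel = select_features(Xtr, Btr, method="correlation", k=20)
            res_tr = pls_permutation(Xtr[:, sel.indices], Btr, n_perm=150, seed=rep, n_comp=3)
            train_sig += res_tr.perm_p[0] < 0.05
            Xte = rng.standard_normal((60, 150))
            Bte = rng.standard_normal((60, 10))
            res_te = pls_permutation(Xte[:, sel.indices], Bte, n_perm=150, seed=rep + 1, n_comp=3)
            test_p.append(res_te.perm_p[0])
        assert train_sig / n_rep > 0.15  # inflated well beyond alpha
        assert abs(np.mean(np.array(test_p) < 0.05) - 0.05) < 0.05
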