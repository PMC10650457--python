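"""NCA objective/gradient against brute-force and finite-difference oracles."""

import numpy as np
import pytest

from pyrafex import (
    FeatureTable,
    NcaConfig,
    TableFixtureSpec,
    make_feature_table,
    nca_fit,
    nca_gradient,
    nca_objective,
    select_top_k,
    standardize,
)
from pyrafex.nca import NcaWeights


def brute_force_objective(X, labels, w, sigma, lam):
    """Direct triple-loop transcription of the objective definition."""
    n, d = X.shape
    total = 0.0
    for i in range(n):
        kappa = np.zeros(n)
        for j in range(n):
            if j == i:
                continue
            dist = sum(w[l] ** 2 * abs(X[i, l] - X[j, l]) for l in range(d))
            kappa[j] = np.exp(-dist / sigma)
        denom = kappa.sum()
        for j in range(n):
            if j != i and labels[j] == labels[i]:
                total += kappa[j] / denom
    return total / n - lam * sum(wl**2 for wl in w)


def toy_table(X, labels):
    n, d = X.shape
    return FeatureTable(
        X, np.asarray(labels), [f"s{i}" for i in range(n)],
        [f"f{i}" for i in range(d)],
    )


RAW = NcaConfig(standardize=False)


class TestStandardize:
    def test_hand_arithmetic_column(self):
        t = toy_table(np.array([[1.0], [2.0], [3.0]]), ["a", "a", "b"])
        out, means, sds = standardize(t)
        np.testing.assert_allclose(
            out.matrix[:, 0], [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )
        assert means[0] == 2.0 and sds[0] == pytest.approx(np.sqrt(2 / 3))

    def test_constant_column_zeroed(self):
        t = toy_table(np.array([[5.0, 1.0], [5.0, 2.0]]), ["a", "b"])
        out, _, sds = standardize(t)
        assert sds[0] == 0.0
        np.testing.assert_array_equal(out.matrix[:, 0], [0.0, 0.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        t = toy_table(rng.standard_normal((6, 4)), list("aabbab"))
        once, _, _ = standardize(t)
        twice, _, _ = standardize(once)
        np.testing.assert_allclose(twice.matrix, once.matrix, atol=1e-12)


class TestObjective:
    def test_identical_same_class_pair_scores_one(self):
        t = toy_table(np.array([[1.0, 2.0], [1.0, 2.0]]), ["a", "a"])
        cfg = NcaConfig(lam=0.0, standardize=False)
        assert nca_objective(t, np.ones(2), cfg) == pytest.approx(1.0)

    def test_different_class_pair_scores_zero(self):
        t = toy_table(np.array([[1.0, 2.0], [3.0, 0.0]]), ["a", "b"])
        cfg = NcaConfig(lam=0.0, standardize=False)
        assert nca_objective(t, np.ones(2), cfg) == pytest.approx(0.0)

    @pytest.mark.parametrize("n,d,seed", [(4, 2, 0), (6, 3, 1), (8, 5, 2)])
    def test_matches_brute_force_oracle(self, n, d, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, d))
        labels = rng.choice(["a", "b"], size=n)
        labels[0], labels[1] = "a", "b"  # ensure both classes
        w = rng.random(d) + 0.1
        sigma, lam = 0.8, 0.05
        cfg = NcaConfig(sigma=sigma, lam=lam, standardize=False)
        ours = nca_objective(toy_table(X, labels), w, cfg)
        ref = brute_force_objective(X, labels, w, sigma, lam)
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((8, 4))
        labels = np.array(list("aabbccab"))
        w = rng.random(4)
        perm = rng.permutation(8)
        a = nca_objective(toy_table(X, labels), w, RAW)
        b = nca_objective(toy_table(X[perm], labels[perm]), w, RAW)
        assert a == pytest.approx(b, abs=1e-12)

    def test_data_term_bounded_by_one(self):
        rng = np.random.default_rng(8)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((6, 3))
            labels = rng.choice(["a", "b"], 6)
            labels[:2] = ["a", "b"]
            cfg = NcaConfig(lam=0.0, standardize=False)
            val = nca_objective(toy_table(X, labels), rng.random(3), cfg)
            assert 0.0 <= val <= 1.0


class TestGradient:
    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((5, 4))
        labels = np.array(["a", "b", "a", "b", "a"])
        t = toy_table(X, labels)
        w = rng.random(4) + 0.5
        cfg = NcaConfig(sigma=0.9, lam=0.03, standardize=False)
        grad = nca_gradient(t, w, cfg)
        eps = 1e-6
        for l in range(4):
            wp, wm = w.copy(), w.copy()
            wp[l] += eps
            wm[l] -= eps
            fd = (nca_objective(t, wp, cfg) - nca_objective(t, wm, cfg)) / (2 * eps)
            assert abs(grad[l] - fd) / max(abs(fd), 1e-12) < 1e-4

    def test_blocked_equals_unblocked(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((7, 11))
        labels = rng.choice(["a", "b"], 7)
        labels[:2] = ["a", "b"]
        t = toy_table(X, labels)
        w = rng.random(11)
        small = NcaConfig(standardize=False, block_size=3)
        big = NcaConfig(standardize=False, block_size=1 << 20)
        assert nca_objective(t, w, small) == pytest.approx(
            nca_objective(t, w, big), rel=1e-14
        )
        np.testing.assert_allclose(
            nca_gradient(t, w, small), nca_gradient(t, w, big), rtol=1e-13
        )


class TestFit:
    def test_best_so_far_trace_non_decreasing(self, planted_table):
        w = nca_fit(planted_table, NcaConfig(max_iter=30))
        best = np.maximum.accumulate(w.objective_trace)
        assert (np.diff(best) >= 0).all()
        assert len(w.objective_trace) <= 30

    def test_planted_columns_rank_top(self, planted_table):
        w = nca_fit(planted_table, NcaConfig(max_iter=60))
        top10 = set(select_top_k(w, 10).indices.tolist())
        assert set(range(5)) <= top10

    def test_recovery_across_seeds(self):
        """Mean recall of the 5 planted columns in the top 10 over 5 seeds."""
        recalls = []
        for seed in range(5):
            t = make_feature_table(TableFixtureSpec(seed=seed))
            w = nca_fit(t, NcaConfig(max_iter=60))
            top10 = set(select_top_k(w, 10).indices.tolist())
            recalls.append(len(top10 & set(range(5))) / 5)
        assert np.mean(recalls) >= 0.9

    def test_large_lambda_shrinks_weights(self):
        t = make_feature_table(TableFixtureSpec(n_samples=40, seed=1))
        w = nca_fit(t, NcaConfig(lam=1e3, max_iter=20, learning_rate=1e-4))
        assert np.abs(w.w).max() < 1.0

    def test_single_class_rejected(self):
        t = toy_table(np.random.default_rng(0).standard_normal((4, 3)),
                      ["a"] * 4)
        with pytest.raises(ValueError, match="2 classes"):
            nca_fit(t)

    def test_zero_variance_columns_reported(self):
        X = np.random.default_rng(1).standard_normal((10, 4))
        X[:, 2] = 7.0
        t = toy_table(X, list("ababababab"))
        w = nca_fit(t, NcaConfig(max_iter=5))
        assert list(w.zero_variance_columns) == [2]


class TestSelectTopK:
    def test_ranks_by_squared_weight(self):
        sel = select_top_k(NcaWeights(np.sqrt([0.1, 0.9, 0.5]), [0.0]), 2)
        assert sel.indices.tolist() == [1, 2]

    def test_ties_broken_by_ascending_index(self):
        sel = select_top_k(NcaWeights(np.ones(5), [0.0]), 3)
        assert sel.indices.tolist() == [0, 1, 2]

    def test_k_equals_d_returns_all_sorted(self):
        sel = select_top_k(NcaWeights(np.array([0.2, -0.8, 0.5]), [0.0]), 3)
        assert sel.indices.tolist() == [1, 2, 0]

    def test_k_out_of_range_errors(self):
        with pytest.raises(ValueError):
            select_top_k(NcaWeights(np.ones(3), [0.0]), 4)

    def test_negative_weights_rank_by_magnitude(self):
        sel = select_top_k(NcaWeights(np.array([-3.0, 1.0, 2.0]), [0.0]), 1)
        assert sel.indices.tolist() == [0]
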