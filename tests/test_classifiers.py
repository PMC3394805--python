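import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.svm import SVC

from progfuse.classifiers import (
    CosineSVM,
    GiniTree,
    NearestMeanClassifier,
    PriorWeightedKNN,
    SimpleBayesClassifier,
    cosine_distance,
    cosine_kernel,
)

from .conftest import random_two_class


# ---------------------------------------------------------------------------
# independent oracles

def oracle_nmc_predict(X, y, x):
    """Brute-force nearest-centroid with explicit cosine distances."""
    cp = X[y == 1].mean(axis=0)
    cg = X[y == 0].mean(axis=0)
    d_poor = cosine_distance(x, cp)
    d_good = cosine_distance(x, cg)
    return 1 if d_good - d_poor >= 0 else 0


def oracle_3nn_predict(X, y, x, priors):
    d = np.array([cosine_distance(x, z) for z in X])
    nn = np.argsort(d, kind="stable")[:3]
    w_poor = sum(1.0 / priors[1] for i in nn if y[i] == 1)
    w_good = sum(1.0 / priors[0] for i in nn if y[i] == 0)
    return 1 if w_poor >= w_good else 0


def oracle_stump(X, y):
    """Exhaustive best depth-1 split (feature, threshold, leaf labels)."""
    n = len(y)
    best = (np.inf, None)
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = (a + b) / 2
            left = X[:, j] <= thr
            imp = 0.0
            for part in (left, ~left):
                yp = y[part]
                p1 = np.mean(yp == 1)
                imp += len(yp) * (1 - p1**2 - (1 - p1) ** 2)
            imp /= n
            if imp < best[0] - 1e-15:
                best = (imp, (j, thr))
    j, thr = best[1]
    left = X[:, j] <= thr
    lab = {}
    for name, part in (("L", left), ("R", ~left)):
        yp = y[part]
        lab[name] = 1 if np.sum(yp == 1) >= np.sum(yp == 0) else 0
    return j, thr, lab


class TestCosine:
    def test_basic_values(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cosine_distance(x, x) == pytest.approx(0.0)
        assert cosine_distance(x, -x) == pytest.approx(2.0)
        assert cosine_distance(
            np.array([1.0, 0.0]), np.array([0.0, 5.0])
        ) == pytest.approx(1.0)

    def test_zero_norm_gives_one(self):
        assert cosine_distance(np.zeros(3), np.ones(3)) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cosine_distance(np.ones(3), np.ones(4))

    def test_kernel_equals_normalized_linear(self, rng):
        A = rng.standard_normal((7, 5))
        B = rng.standard_normal((4, 5))
        K = cosine_kernel(A, B)
        An = A / np.linalg.norm(A, axis=1, keepdims=True)
        Bn = B / np.linalg.norm(B, axis=1, keepdims=True)
        np.testing.assert_allclose(K, An @ Bn.T, atol=1e-12)
        Ksym = cosine_kernel(A, A)
        np.testing.assert_allclose(Ksym, Ksym.T, atol=1e-12)
        assert np.all(np.abs(K) <= 1 + 1e-12)
        np.testing.assert_allclose(np.diag(Ksym), 1.0, atol=1e-12)


class TestNMC:
    def test_matches_bruteforce_oracle(self, rng):
        for trial in range(30):
            X, y = random_two_class(rng, n=20, p=5)
            Xt = rng.standard_normal((10, 5))
            model = NearestMeanClassifier().fit(X, y)
            pred = model.predict(Xt)
            expected = [oracle_nmc_predict(X, y, x) for x in Xt]
            np.testing.assert_array_equal(pred, expected)

    def test_sample_at_poor_centroid(self):
        X = np.array([[1.0, 0.0], [1.0, 0.2], [0.0, 1.0], [0.2, 1.0]])
        y = np.array([1, 1, 0, 0])
        model = NearestMeanClassifier().fit(X, y)
        assert model.predict(model.centroid_poor_[None, :])[0] == 1

    def test_equidistant_tie_goes_poor(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([1, 0])
        model = NearestMeanClassifier().fit(X, y)
        assert model.predict(np.array([[1.0, 1.0]]))[0] == 1

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            NearestMeanClassifier().fit(np.ones((3, 2)), np.ones(3, dtype=int))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=100.0), st.integers(0, 2**31 - 1))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        X, y = random_two_class(rng, n=15, p=4)
        Xt = rng.standard_normal((6, 4))
        m = NearestMeanClassifier().fit(X, y)
        np.testing.assert_array_equal(m.predict(Xt), m.predict(Xt * scale))


class TestSBC:
    def test_uninformative_feature_posterior_equals_prior(self, rng):
        x = rng.standard_normal(200)
        X = np.concatenate([x, x])[:, None]
        y = np.repeat([0, 1], 200)
        model = SimpleBayesClassifier().fit(X, y)
        post = model.posterior_poor(X[:5])
        np.testing.assert_allclose(post, 0.5, atol=1e-10)

    def test_symmetric_gaussian_midpoint(self):
        X = np.concatenate(
            [np.random.default_rng(0).normal(-1, 1, 50),
             np.random.default_rng(1).normal(1, 1, 50)]
        )[:, None]
        # force exactly symmetric parameters via handcrafted training sets
        Xs = np.array([[-2.0], [0.0], [2.0], [0.0]])
        ys = np.array([0, 0, 1, 1])
        # shift so class means are -1 and +1 with equal sd
        Xs = np.array([[-2.0], [0.0], [0.0], [2.0]])
        model = SimpleBayesClassifier().fit(Xs, ys)
        assert model.posterior_poor(np.array([[0.0]]))[0] == pytest.approx(0.5)

    def test_log_domain_oracle_mixed_features(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        Xc = rng.standard_normal((30, 2))
        Xd = rng.integers(0, 3, 30).astype(float)[:, None]
        X = np.hstack([Xc, Xd])
        y = (rng.random(30) < 0.4).astype(int)
        y[:2] = [0, 1]
        mask = np.array([False, False, True])
        model = SimpleBayesClassifier(discrete_mask=mask).fit(X, y)
        x = X[7]
        # independent hand computation of the joint log-density
        logj = np.zeros(2)
        for c in (0, 1):
            Xc_class = X[y == c]
            logj[c] = np.log(np.mean(y == c))
            for j in (0, 1):
                mu = Xc_class[:, j].mean()
                sd = max(Xc_class[:, j].std(ddof=1), 1e-6)
                logj[c] += stats.norm.logpdf(x[j], mu, sd)
            levels = np.unique(X[:, 2])
            counts = np.array(
                [np.sum(Xc_class[:, 2] == lv) for lv in levels]
            )
            probs = (counts + 1) / (len(Xc_class) + len(levels))
            logj[c] += np.log(probs[levels == x[2]][0])
        expected = np.exp(logj[1]) / np.exp(logj).sum()
        assert model.posterior_poor(x[None, :])[0] == pytest.approx(
            expected, abs=1e-10
        )

    def test_posteriors_sum_to_one(self, rng):
        X, y = random_two_class(rng, n=25, p=4)
        model = SimpleBayesClassifier().fit(X, y)
        p1 = model.posterior_poor(X)
        assert np.all((p1 >= 0) & (p1 <= 1))


class TestKNN:
    def test_matches_bruteforce_oracle(self, rng):
        for trial in range(30):
            X, y = random_two_class(rng, n=20, p=4)
            Xt = rng.standard_normal((8, 4))
            model = PriorWeightedKNN().fit(X, y)
            pred = model.predict(Xt)
            expected = [oracle_3nn_predict(X, y, x, model.priors_) for x in Xt]
            np.testing.assert_array_equal(pred, expected)

    def test_prior_weighting_arithmetic(self):
        # neighbors (poor, good, good), priors (0.3, 0.7):
        # poor weight 1/0.3 = 3.33 > good weight 2/0.7 = 2.86 -> poor
        X = np.array(
            [[1.0, 0.0], [0.9, 0.1], [0.8, 0.2]] + [[0.0, 1.0]] * 4
            + [[1.0, 0.05]] * 3
        )
        y = np.array([1, 0, 0, 0, 0, 0, 0, 1, 1, 1])
        model = PriorWeightedKNN().fit(X[:7], y[:7])
        assert model.priors_[1] == pytest.approx(1 / 7)
        # craft explicit distances instead: use predict_from_distances
        D = np.array([[0.0, 0.01, 0.02, 5, 5, 5, 5]])
        model.priors_ = np.array([0.7, 0.3])
        label, share = model.predict_from_distances(D)
        assert label[0] == 1
        assert share[0] == pytest.approx(
            (1 / 0.3) / (1 / 0.3 + 2 / 0.7)
        )

    def test_equal_priors_reduce_to_majority(self, rng):
        X = rng.standard_normal((10, 3))
        y = np.repeat([0, 1], 5)
        model = PriorWeightedKNN().fit(X, y)
        D = np.array([[0.0, 0.01, 0.02] + [9.0] * 7])
        label, _ = model.predict_from_distances(D)
        votes = y[[0, 1, 2]]
        assert label[0] == (1 if votes.sum() * 2 >= 3 else 0)


class TestSVM:
    def test_separable_toy_zero_training_error(self):
        X = np.vstack([np.ones((5, 2)) + [2, 0], np.ones((5, 2)) + [0, 2]])
        y = np.repeat([1, 0], 5)
        model = CosineSVM().fit(X, y)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_equivalent_to_linear_on_normalized(self, rng):
        for trial in range(5):
            X, y = random_two_class(rng, n=24, p=6)
            Xt = rng.standard_normal((10, 6))
            cos_svm = CosineSVM().fit(X, y)
            Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
            Xtn = Xt / np.linalg.norm(Xt, axis=1, keepdims=True)
            lin = SVC(kernel="linear", C=1.0, class_weight="balanced", tol=1e-10)
            lin.fit(Xn, y)
            np.testing.assert_allclose(
                cos_svm.score(Xt), lin.decision_function(Xtn), atol=1e-8
            )

    def test_balanced_costs_track_class_sizes(self, rng):
        # class_weight='balanced' gives C_class = C * N / (2 * N_class)
        X, y = random_two_class(rng, n=30, p=5)
        n, n1 = len(y), y.sum()
        w = {0: n / (2 * (n - n1)), 1: n / (2 * n1)}
        ref = SVC(kernel="linear", C=1.0, class_weight=w)
        bal = SVC(kernel="linear", C=1.0, class_weight="balanced", tol=1e-10)
        Xn = X / np.linalg.norm(X, axis=1, keepdims=True)
        ref.fit(Xn, y)
        bal.fit(Xn, y)
        np.testing.assert_allclose(
            ref.decision_function(Xn), bal.decision_function(Xn), atol=1e-10
        )


class TestTree:
    def test_pure_training_single_leaf(self):
        X = np.arange(8, dtype=float)[:, None]
        y = np.ones(8, dtype=int)
        tree = GiniTree().fit(X, y)
        assert tree.depth == 0
        assert np.all(tree.predict(X) == 1)

    def test_xor_depth_two_zero_error(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([0, 1, 1, 0])
        tree = GiniTree().fit(X, y)
        assert tree.depth == 2
        np.testing.assert_array_equal(tree.predict(X), y)

    def test_depth_one_matches_exhaustive_oracle(self, rng):
        for trial in range(30):
            X, y = random_two_class(rng, n=20, p=4)
            tree = GiniTree(max_depth=1).fit(X, y)
            j, thr, lab = oracle_stump(X, y)
            pred = tree.predict(X)
            expected = np.where(X[:, j] <= thr, lab["L"], lab["R"])
            np.testing.assert_array_equal(pred, expected)

    def test_refit_deterministic(self, rng):
        X, y = random_two_class(rng, n=30, p=5)
        t1 = GiniTree().fit(X, y)
        t2 = GiniTree().fit(X, y)
        Xt = rng.standard_normal((20, 5))
        np.testing.assert_array_equal(t1.predict(Xt), t2.predict(Xt))
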