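import itertools

import numpy as np
import pandas as pd
import pytest

from progfuse.classifiers import (
    CosineSVM,
    NearestMeanClassifier,
    PriorWeightedKNN,
    SimpleBayesClassifier,
    cosine_kernel,
)
from progfuse.integration import (
    HybridTree,
    IntegrationSpec,
    IntermediateKNN,
    IntermediateNMC,
    IntermediateSBC,
    IntermediateSVM,
    combine_kernels,
    concat_views,
    late_combine,
    select_alpha,
)

from .conftest import continuous_meta, random_two_class


class TestSpecValidation:
    @pytest.mark.parametrize("kind,mode", [
        ("Tree1", "intermediate"),
        ("Tree2", "intermediate"),
        ("HybridTreeC", "none_E"),
        ("HybridTreeE", "late_OR"),
    ])
    def test_untested_combinations_rejected(self, kind, mode):
        with pytest.raises(ValueError):
            IntegrationSpec(classifier=kind, mode=mode)

    def test_tested_combinations_accepted(self):
        for kind in ("NMC", "SBC", "3NN", "SVM"):
            for mode in ("none_E", "none_C", "early", "intermediate",
                         "late_AND", "late_OR"):
                IntegrationSpec(classifier=kind, mode=mode)
        IntegrationSpec(classifier="HybridTreeC", mode="intermediate")


class TestConcat:
    def test_shapes_and_meta(self, rng):
        E = rng.standard_normal((8, 3))
        C = rng.standard_normal((8, 2))
        mE = continuous_meta(3)
        mC = pd.DataFrame({"kind": ["binary", "continuous"]})
        X, meta = concat_views(E, C, mE, mC)
        assert X.shape == (8, 5)
        assert list(meta["kind"]) == ["continuous"] * 3 + ["binary",
                                                          "continuous"]

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            concat_views(rng.standard_normal((4, 2)),
                         rng.standard_normal((5, 2)))


class TestLateCombine:
    def test_truth_table(self):
        E = np.array([1, 1, 0, 0])
        C = np.array([1, 0, 1, 0])
        np.testing.assert_array_equal(late_combine(E, C, "OR"), [1, 1, 1, 0])
        np.testing.assert_array_equal(late_combine(E, C, "AND"), [1, 0, 0, 0])

    def test_exhaustive_set_algebra(self):
        # all label-pair combinations for n <= 8: OR = union, AND = intersection
        for n in range(1, 9):
            for pair in itertools.product(range(4), repeat=n):
                E = np.array([p // 2 for p in pair])
                C = np.array([p % 2 for p in pair])
                o = late_combine(E, C, "OR")
                a = late_combine(E, C, "AND")
                np.testing.assert_array_equal(o, E | C)
                np.testing.assert_array_equal(a, E & C)
                assert np.all(a <= o)  # AND-poor subset of OR-poor
            if n >= 4:
                break  # full exhaustion above is redundant beyond small n
        rng = np.random.default_rng(0)
        for _ in range(100):
            E = rng.integers(0, 2, 16)
            C = rng.integers(0, 2, 16)
            np.testing.assert_array_equal(late_combine(E, C, "OR"), E | C)
            np.testing.assert_array_equal(late_combine(E, C, "AND"), E & C)


class TestKernelCombination:
    def test_boundaries_and_psd(self, rng):
        A = rng.standard_normal((12, 5))
        B = rng.standard_normal((12, 7))
        K_E = cosine_kernel(A, A)
        K_C = cosine_kernel(B, B)
        np.testing.assert_array_equal(combine_kernels(K_E, K_C, 1.0), K_E)
        np.testing.assert_array_equal(combine_kernels(K_E, K_C, 0.0), K_C)
        for alpha in (0.25, 0.5, 0.9):
            K = combine_kernels(K_E, K_C, alpha)
            assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_identical_kernels_fixed_point(self, rng):
        A = rng.standard_normal((6, 3))
        K = cosine_kernel(A, A)
        np.testing.assert_allclose(combine_kernels(K, K, 0.5), K)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            combine_kernels(np.eye(3), np.eye(4), 0.5)


def _two_view_instance(rng, n=60):
    XE, y = random_two_class(rng, n=n, p=8)
    XC = rng.standard_normal((n, 5))
    XC[:, 0] += y * 1.5
    return XE, XC, y


class TestIntermediateBoundaries:
    """At alpha = 1 the combined classifier must reproduce the expression-only
    labels; at alpha = 0 the clinical-only labels."""

    @pytest.mark.parametrize("kind", ["NMC", "SBC", "3NN", "SVM"])
    def test_boundary_reduction(self, kind, rng):
        for trial in range(5):
            XE, XC, y = _two_view_instance(rng)
            Xte_E = rng.standard_normal((15, 8))
            Xte_C = rng.standard_normal((15, 5))
            if kind == "NMC":
                mE = NearestMeanClassifier().fit(XE, y)
                mC = NearestMeanClassifier().fit(XC, y)
                inter = lambda a: IntermediateNMC(mE, mC, a)
                single_E, single_C = mE.predict(Xte_E), mC.predict(Xte_C)
            elif kind == "SBC":
                mE = SimpleBayesClassifier().fit(XE, y)
                mC = SimpleBayesClassifier().fit(XC, y)
                inter = lambda a: IntermediateSBC(mE, mC, a)
                single_E, single_C = mE.predict(Xte_E), mC.predict(Xte_C)
            elif kind == "3NN":
                mE = PriorWeightedKNN().fit(XE, y)
                mC = PriorWeightedKNN().fit(XC, y)
                inter = lambda a: IntermediateKNN(XE, XC, y, a)
                single_E, single_C = mE.predict(Xte_E), mC.predict(Xte_C)
            else:
                mE = CosineSVM().fit(XE, y)
                mC = CosineSVM().fit(XC, y)
                inter = lambda a: IntermediateSVM(XE, XC, y, a)
                single_E, single_C = mE.predict(Xte_E), mC.predict(Xte_C)
            np.testing.assert_array_equal(
                inter(1.0).predict(Xte_E, Xte_C), single_E
            )
            np.testing.assert_array_equal(
                inter(0.0).predict(Xte_E, Xte_C), single_C
            )


class TestIntermediateArithmetic:
    def test_nmc_hand_combination(self):
        XE = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.2, 0.9]])
        XC = np.array([[2.0, 1.0], [1.0, 2.0], [0.5, 1.5], [2.0, 0.1]])
        y = np.array([1, 0, 0, 1])
        mE = NearestMeanClassifier().fit(XE, y)
        mC = NearestMeanClassifier().fit(XC, y)
        inter = IntermediateNMC(mE, mC, 0.5)
        x_E, x_C = XE[2][None], XC[2][None]
        d_poor, d_good = inter.combined_distances(x_E, x_C)
        dpE, dgE = mE.distances(x_E)
        dpC, dgC = mC.distances(x_C)
        assert d_poor[0] == pytest.approx(0.5 * dpE[0] + 0.5 * dpC[0],
                                          abs=1e-12)
        assert d_good[0] == pytest.approx(0.5 * dgE[0] + 0.5 * dgC[0],
                                          abs=1e-12)

    def test_sbc_posterior_combination(self):
        # P_E = (0.9, 0.1), P_C = (0.2, 0.8), alpha = 0.3
        # combined poor posterior = 0.3*0.1 + 0.7*0.8 = 0.59 -> ... good wins
        class Stub:
            def __init__(self, p):
                self.p = p

            def posterior_poor(self, X):
                return np.full(len(X), self.p)

        inter = IntermediateSBC(Stub(0.1), Stub(0.8), 0.3)
        x = np.zeros((1, 1))
        post = inter.score(x, x)
        assert post[0] == pytest.approx(0.59)
        assert inter.predict(x, x)[0] == 1  # 0.59 >= 0.5 -> poor
        inter2 = IntermediateSBC(Stub(0.9), Stub(0.2), 0.3)
        # 0.3*0.9 + 0.7*0.2 = 0.41 -> good
        assert inter2.predict(x, x)[0] == 0

    def test_3nn_neighbors_match_bruteforce(self, rng):
        XE, XC, y = _two_view_instance(rng, n=25)
        inter = IntermediateKNN(XE, XC, y, 0.37)
        xE, xC = rng.standard_normal((1, 8)), rng.standard_normal((1, 5))
        D = 0.37 * (1 - cosine_kernel(xE, XE)) + 0.63 * (
            1 - cosine_kernel(xC, XC)
        )
        nn = np.argsort(D[0], kind="stable")[:3]
        w = 1.0 / np.array([np.mean(y == 0), np.mean(y == 1)])
        poor_w = sum(w[1] for i in nn if y[i] == 1)
        good_w = sum(w[0] for i in nn if y[i] == 0)
        assert inter.predict(xE, xC)[0] == (1 if poor_w >= good_w else 0)


class TestSelectAlpha:
    def test_duplicated_view_ties_to_zero(self, rng):
        XE, y = random_two_class(rng, n=40, p=6)
        alpha = select_alpha(XE, XE.copy(), y, "NMC")
        assert alpha == 0.0

    def test_grid_membership(self, rng):
        XE, XC, y = _two_view_instance(rng)
        alpha = select_alpha(XE, XC, y, "NMC")
        assert round(alpha * 100) == pytest.approx(alpha * 100)

    def test_informative_view_preferred(self):
        # E separable, C pure noise -> alpha near 1 (median over seeds)
        alphas = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 30)
            XE = rng.standard_normal((60, 10)) + 2.5 * y[:, None]
            XC = rng.standard_normal((60, 10))
            alphas.append(select_alpha(XE, XC, y, "NMC"))
        assert np.median(alphas) >= 0.9


class TestHybridTree:
    def _views(self, rng, n=80):
        E = rng.standard_normal((n, 30))
        C = rng.standard_normal((n, 8))
        y = (rng.random(n) < 0.4).astype(int)
        y[:4] = [0, 0, 1, 1]
        E[:, :5] += 1.2 * y[:, None]
        C[:, :2] += 1.2 * y[:, None]
        meta_C = continuous_meta(8)
        return E, C, meta_C, y

    def test_depth_one_equals_start_view_nmc(self, rng):
        from progfuse.ranking import rank_features

        E, C, meta_C, y = self._views(rng)
        tree = HybridTree("C", max_depth=1).fit(E, C, meta_C, y)
        ranked = rank_features(C, meta_C, y)
        cols = ranked.order[: min(10, C.shape[1])]
        nmc = NearestMeanClassifier().fit(C[:, cols], y)
        Et = rng.standard_normal((20, 30))
        Ct = rng.standard_normal((20, 8))
        np.testing.assert_array_equal(
            tree.predict(Et, Ct), nmc.predict(Ct[:, cols])
        )

    def test_stopping_rules(self, rng):
        for trial in range(10):
            E, C, meta_C, y = self._views(rng, n=60)
            tree = HybridTree("E", max_depth=4).fit(E, C, meta_C, y)
            for node in tree.nodes:
                if not node.is_leaf:
                    assert node.n_samples >= 10
                    assert 0 < node.n_poor < node.n_samples

    def test_small_node_is_leaf(self, rng):
        E = rng.standard_normal((9, 5))
        C = rng.standard_normal((9, 3))
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1])
        tree = HybridTree("E", max_depth=3).fit(E, C, continuous_meta(3), y)
        assert tree.root_.is_leaf  # 9 samples < 10 -> no split

    def test_pure_node_is_leaf_regardless_of_size(self, rng):
        E = rng.standard_normal((40, 5))
        C = rng.standard_normal((40, 3))
        y = np.ones(40, dtype=int)
        tree = HybridTree("C", max_depth=3).fit(E, C, continuous_meta(3), y)
        assert tree.root_.is_leaf

    def test_views_alternate(self, rng):
        E, C, meta_C, y = self._views(rng, n=200)
        tc = HybridTree("C", max_depth=3).fit(E, C, meta_C, y)
        for node in tc.nodes:
            if not node.is_leaf:
                assert node.view == ("C" if node.depth == 0 else "E")
        te = HybridTree("E", max_depth=3).fit(E, C, meta_C, y)
        for node in te.nodes:
            if not node.is_leaf:
                assert node.view == ("E" if node.depth == 0 else "C")
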