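"""The five base classifiers, each on a single feature view.

All classifiers share one contract: ``fit(X, y)`` with y in {0 good, 1 poor},
``score(X)`` returning a continuous poor-likeness score, and ``predict(X)``
returning binary labels.  Poor is the positive class throughout; every tie
(equal distances, equal posteriors, zero SVM margin, tied votes) resolves to
poor ("believe the positive").

Distance geometry is the cosine correlation distance 1 - cos(x, y) in [0, 2];
a zero-norm vector is treated as orthogonal to everything (distance 1).
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import stats
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

_SD_FLOOR = 1e-6


def cosine_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - cosine similarity; zero-norm vectors give distance 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vector length mismatch")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        logger.debug("zero-norm vector in cosine_distance; distance 1")
        return 1.0
    return float(1.0 - np.dot(x, y) / (nx * ny))


def _row_normalize(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    zero = norms[:, 0] == 0
    if zero.any():
        logger.debug("%d zero-norm rows in cosine kernel", int(zero.sum()))
    norms[zero] = 1.0
    return X / norms


def cosine_kernel(X_a: np.ndarray, X_b: np.ndarray) -> np.ndarray:
    """Cosine similarity kernel; equals the linear kernel of L2-row-normalized
    inputs.  Zero-norm rows have similarity 0 against everything."""
    X_a, X_b = np.atleast_2d(X_a), np.atleast_2d(X_b)
    if X_a.shape[1] != X_b.shape[1]:
        raise ValueError("feature count mismatch")
    return _row_normalize(X_a) @ _row_normalize(X_b).T


def _cosine_dist_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return 1.0 - cosine_kernel(A, B)


def _check_classes(y: np.ndarray) -> None:
    y = np.asarray(y)
    if not ((y == 0).any() and (y == 1).any()):
        raise ValueError("training data must contain both classes")


class NearestMeanClassifier:
    """Nearest mean classifier with cosine correlation distance.

    Score is d(x, centroid_good) - d(x, centroid_poor): positive means closer
    to the poor centroid.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NearestMeanClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        _check_classes(y)
        self.centroid_poor_ = X[y == 1].mean(axis=0)
        self.centroid_good_ = X[y == 0].mean(axis=0)
        return self

    def distances(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d_poor = _cosine_dist_matrix(X, self.centroid_poor_[None, :])[:, 0]
        d_good = _cosine_dist_matrix(X, self.centroid_good_[None, :])[:, 0]
        return d_poor, d_good

    def score(self, X: np.ndarray) -> np.ndarray:
        d_poor, d_good = self.distances(X)
        return d_good - d_poor

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.score(X) >= 0).astype(int)


class SimpleBayesClassifier:
    """Naive Bayes over mixed features: class-conditional Gaussians for
    continuous columns, Laplace-smoothed level frequencies for discrete ones.

    ``discrete_mask`` flags the discrete columns; default all-continuous.
    Gaussian sds are floored at 1e-6; discrete levels unseen in a class get
    pseudocount-1 probability mass.
    """

    def __init__(self, discrete_mask: np.ndarray | None = None) -> None:
        self.discrete_mask = discrete_mask

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SimpleBayesClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        _check_classes(y)
        p = X.shape[1]
        mask = (
            np.zeros(p, dtype=bool)
            if self.discrete_mask is None
            else np.asarray(self.discrete_mask, dtype=bool)
        )
        if mask.shape[0] != p:
            raise ValueError("discrete_mask length mismatch")
        self.mask_ = mask
        self.log_prior_ = np.log(
            np.array([np.mean(y == 0), np.mean(y == 1)])
        )
        self.mean_ = np.zeros((2, p))
        self.sd_ = np.ones((2, p))
        self.levels_: list[np.ndarray | None] = [None] * p
        self.log_prob_: list[np.ndarray | None] = [None] * p
        for j in range(p):
            if mask[j]:
                levels = np.unique(X[:, j])
                self.levels_[j] = levels
                lp = np.zeros((2, len(levels)))
                for c in (0, 1):
                    xc = X[y == c, j]
                    counts = np.array([np.sum(xc == lv) for lv in levels])
                    probs = (counts + 1.0) / (len(xc) + len(levels))
                    lp[c] = np.log(probs)
                self.log_prob_[j] = lp
            else:
                for c in (0, 1):
                    xc = X[y == c, j]
                    self.mean_[c, j] = xc.mean()
                    sd = xc.std(ddof=1) if len(xc) > 1 else 0.0
                    self.sd_[c, j] = max(sd, _SD_FLOOR)
        # fallback log-mass for levels never seen in training at all
        self._unseen_ = [
            None if self.levels_[j] is None
            else np.array([
                np.log(1.0 / (np.sum(y == c) + len(self.levels_[j])))
                for c in (0, 1)
            ])
            for j in range(p)
        ]
        return self

    def _log_joint(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        L = np.tile(self.log_prior_, (n, 1))
        for c in (0, 1):
            cont = ~self.mask_
            if cont.any():
                L[:, c] += stats.norm.logpdf(
                    X[:, cont], loc=self.mean_[c, cont], scale=self.sd_[c, cont]
                ).sum(axis=1)
        for j in np.flatnonzero(self.mask_):
            levels = self.levels_[j]
            idx = np.searchsorted(levels, X[:, j])
            idx_clip = np.clip(idx, 0, len(levels) - 1)
            known = levels[idx_clip] == X[:, j]
            for c in (0, 1):
                contrib = np.where(
                    known, self.log_prob_[j][c][idx_clip], self._unseen_[j][c]
                )
                L[:, c] += contrib
        return L

    def posterior_poor(self, X: np.ndarray) -> np.ndarray:
        L = self._log_joint(X)
        m = L.max(axis=1, keepdims=True)
        w = np.exp(L - m)
        return w[:, 1] / w.sum(axis=1)

    def score(self, X: np.ndarray) -> np.ndarray:
        return self.posterior_poor(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.posterior_poor(X) >= 0.5).astype(int)


class PriorWeightedKNN:
    """3-nearest-neighbor classifier (cosine distance) whose majority vote is
    adjusted for class imbalance: each neighbor's vote is weighted by the
    reciprocal of its class prior."""

    def __init__(self, k: int = 3) -> None:
        if k % 2 == 0:
            raise ValueError("k must be odd")
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PriorWeightedKNN":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        _check_classes(y)
        if len(y) < self.k:
            raise ValueError(f"need at least {self.k} training samples")
        self.X_ = X
        self.y_ = y
        self.priors_ = np.array([np.mean(y == 0), np.mean(y == 1)])
        return self

    def _vote(self, D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # ties in distance broken by training-sample index (stable sort)
        nn = np.argsort(D, axis=1, kind="stable")[:, : self.k]
        votes = self.y_[nn]
        w = 1.0 / self.priors_
        poor_w = (votes * w[1]).sum(axis=1)
        good_w = ((1 - votes) * w[0]).sum(axis=1)
        share = poor_w / (poor_w + good_w)
        return (poor_w >= good_w).astype(int), share

    def predict_from_distances(self, D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels and weighted poor-vote share from a precomputed
        test x train distance matrix (used by intermediate integration)."""
        return self._vote(np.asarray(D, dtype=float))

    def score(self, X: np.ndarray) -> np.ndarray:
        D = _cosine_dist_matrix(np.atleast_2d(X), self.X_)
        return self._vote(D)[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        D = _cosine_dist_matrix(np.atleast_2d(X), self.X_)
        return self._vote(D)[0]


class KernelSVM:
    """Soft-margin SVM on a precomputed kernel with C = 1 rescaled per class
    by N/(2*N_class) to counter class imbalance."""

    def __init__(self, C: float = 1.0, tol: float = 1e-10) -> None:
        self.C = C
        self.tol = tol  # tight solver tolerance: decision values reproducible

    def fit(self, K: np.ndarray, y: np.ndarray) -> "KernelSVM":
        y = np.asarray(y).astype(int)
        _check_classes(y)
        self.svc_ = SVC(kernel="precomputed", C=self.C,
                        class_weight="balanced", tol=self.tol)
        self.svc_.fit(np.asarray(K, dtype=float), y)
        return self

    def decision(self, K_test_train: np.ndarray) -> np.ndarray:
        return self.svc_.decision_function(np.asarray(K_test_train, dtype=float))

    def predict_from_kernel(self, K_test_train: np.ndarray) -> np.ndarray:
        return (self.decision(K_test_train) >= 0).astype(int)


class CosineSVM:
    """SVM with the cosine correlation kernel (linear kernel on L2-row-
    normalized inputs)."""

    def __init__(self, C: float = 1.0) -> None:
        self.C = C

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CosineSVM":
        X = np.asarray(X, dtype=float)
        self.X_ = X
        self.kernel_svm_ = KernelSVM(C=self.C).fit(cosine_kernel(X, X), y)
        return self

    def score(self, X: np.ndarray) -> np.ndarray:
        K = cosine_kernel(np.atleast_2d(X), self.X_)
        return self.kernel_svm_.decision(K)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.score(X) >= 0).astype(int)


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p**2).sum())


class _TreeNode:
    __slots__ = ("feature", "threshold", "left", "right", "label",
                 "poor_frac", "n_samples", "depth", "impurity")

    def __init__(self) -> None:
        self.feature = None
        self.threshold = None
        self.left = None
        self.right = None
        self.label = None
        self.poor_frac = 0.0
        self.n_samples = 0
        self.depth = 0
        self.impurity = 0.0


class GiniTree:
    """Greedy binary decision tree minimizing weighted Gini impurity.

    Deterministic: the best split is the (feature, threshold) pair with the
    smallest weighted impurity; ties resolve to the smallest feature index,
    then the smallest threshold.  Candidate thresholds are midpoints between
    consecutive distinct sorted values.  A node becomes a leaf when pure,
    smaller than ``min_node``, at ``max_depth``, or when every feature is
    constant.  Leaf labels are the majority class (ties -> poor).
    """

    def __init__(self, max_depth: int | None = None, min_node: int = 2) -> None:
        self.max_depth = max_depth
        self.min_node = min_node

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GiniTree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.shape[1] == 0:
            raise ValueError("empty feature set")
        self.root_ = self._build(X, y, depth=0)
        return self

    def _best_split(self, X: np.ndarray, y: np.ndarray):
        n = len(y)
        best = (math.inf, -1, 0.0)  # (impurity, feature, threshold)
        for j in range(X.shape[1]):
            order = np.argsort(X[:, j], kind="stable")
            xs = X[order, j]
            ys = y[order]
            cum_poor = np.cumsum(ys)
            total_poor = cum_poor[-1]
            # split after position i (left = first i+1 samples)
            distinct = xs[:-1] < xs[1:]
            for i in np.flatnonzero(distinct):
                nl = i + 1
                nr = n - nl
                pl = cum_poor[i]
                pr = total_poor - pl
                gl = 1.0 - ((pl / nl) ** 2 + ((nl - pl) / nl) ** 2)
                gr = 1.0 - ((pr / nr) ** 2 + ((nr - pr) / nr) ** 2)
                imp = (nl * gl + nr * gr) / n
                thr = 0.5 * (xs[i] + xs[i + 1])
                if imp < best[0] - 1e-15:
                    best = (imp, j, thr)
        return best

    def _build(self, X: np.ndarray, y: np.ndarray, depth: int) -> _TreeNode:
        node = _TreeNode()
        node.n_samples = len(y)
        node.depth = depth
        node.poor_frac = float(np.mean(y == 1)) if len(y) else 0.0
        counts = np.array([np.sum(y == 0), np.sum(y == 1)])
        node.impurity = _gini(counts)
        node.label = 1 if counts[1] >= counts[0] else 0
        if (
            node.impurity == 0.0
            or len(y) < self.min_node
            or (self.max_depth is not None and depth >= self.max_depth)
        ):
            return node
        # zero-gain splits are allowed (an XOR pattern needs one); recursion
        # terminates because both children are strictly smaller
        imp, j, thr = self._best_split(X, y)
        if j < 0:
            return node
        mask = X[:, j] <= thr
        node.feature = j
        node.threshold = thr
        node.left = self._build(X[mask], y[mask], depth + 1)
        node.right = self._build(X[~mask], y[~mask], depth + 1)
        return node

    def _leaf(self, x: np.ndarray) -> _TreeNode:
        node = self.root_
        while node.feature is not None:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([self._leaf(x).poor_frac for x in X])

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([self._leaf(x).label for x in X], dtype=int)

    @property
    def depth(self) -> int:
        def _d(node: _TreeNode) -> int:
            if node.feature is None:
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root_)


#: classifier kind names used throughout the package
NMC, SBC, KNN3, SVM, TREE1, TREE2 = "NMC", "SBC", "3NN", "SVM", "Tree1", "Tree2"
HYBRID_C, HYBRID_E = "HybridTreeC", "HybridTreeE"
BASE_KINDS = (NMC, SBC, KNN3, SVM, TREE1, TREE2)


def make_classifier(
    kind: str,
    discrete_mask: np.ndarray | None = None,
    max_depth: int | None = None,
):
    """Factory for the single-view classifiers."""
    if kind == NMC:
        return NearestMeanClassifier()
    if kind == SBC:
        return SimpleBayesClassifier(discrete_mask=discrete_mask)
    if kind == KNN3:
        return PriorWeightedKNN(k=3)
    if kind == SVM:
        return CosineSVM()
    if kind == TREE1:
        return GiniTree(max_depth=max_depth)
    if kind == TREE2:
        return GiniTree(max_depth=None)
    raise ValueError(f"unknown classifier kind {kind!r}")
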