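"""Integration strategies: none, early, intermediate, late, and the HybridTree.

Conventions fixed project-wide: the mixing parameter ``alpha`` weights the
expression view and ``1 - alpha`` the clinical view; poor is the positive
class; discordant late-fusion samples go to poor under OR ("believe the
positive") and to good under AND ("believe the negative").
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import classifiers as clf
from .classifiers import (
    KernelSVM,
    NearestMeanClassifier,
    PriorWeightedKNN,
    SimpleBayesClassifier,
    cosine_kernel,
)
from .metrics import confusion, efpfn
from .preprocess import DISCRETE_KINDS
from .ranking import rank_features

logger = logging.getLogger(__name__)

MODES = ("none_E", "none_C", "early", "intermediate", "late_AND", "late_OR")

#: the tested classifier x integration combinations ('+' cells)
ALLOWED_MODES: dict[str, tuple[str, ...]] = {
    clf.NMC: MODES,
    clf.SBC: MODES,
    clf.KNN3: MODES,
    clf.SVM: MODES,
    clf.TREE1: ("none_E", "none_C", "early", "late_AND", "late_OR"),
    clf.TREE2: ("none_E", "none_C", "early", "late_AND", "late_OR"),
    clf.HYBRID_C: ("intermediate",),
    clf.HYBRID_E: ("intermediate",),
}

DEFAULT_ALPHA_GRID = np.round(np.arange(0, 101) / 100.0, 2)


@dataclasses.dataclass(frozen=True)
class IntegrationSpec:
    """One experiment arm: classifier kind x integration mode (x fixed alpha
    or feature budgets, which otherwise come from the run config)."""

    classifier: str
    mode: str
    alpha: float | None = None
    n_features_E: int | None = None
    n_features_C: int | None = None
    clinical_subset: str = "O+S+N"

    def __post_init__(self) -> None:
        if self.classifier not in ALLOWED_MODES:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode not in ALLOWED_MODES[self.classifier]:
            raise ValueError(
                f"combination {self.classifier}/{self.mode} is not a tested "
                "combination"
            )
        if self.alpha is not None and not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def name(self) -> str:
        return f"{self.classifier};{self.mode}"


def concat_views(
    E: np.ndarray, C: np.ndarray,
    meta_E: pd.DataFrame | None = None, meta_C: pd.DataFrame | None = None,
) -> tuple[np.ndarray, pd.DataFrame | None]:
    """Column-wise concatenation EC, with merged per-column metadata so the
    ranking still routes t vs chi-squared correctly."""
    E, C = np.asarray(E), np.asarray(C)
    if E.shape[0] != C.shape[0]:
        raise ValueError("row count mismatch between views")
    X = np.hstack([E, C])
    meta = None
    if meta_E is not None and meta_C is not None:
        meta = pd.concat([meta_E, meta_C], ignore_index=True)
    return X, meta


def late_combine(label_E: np.ndarray, label_C: np.ndarray, op: str) -> np.ndarray:
    """Fuse two binary label vectors: OR = poor iff either says poor,
    AND = poor iff both say poor."""
    label_E = np.asarray(label_E).astype(int)
    label_C = np.asarray(label_C).astype(int)
    if label_E.shape != label_C.shape:
        raise ValueError("label vector length mismatch")
    if op == "OR":
        return label_E | label_C
    if op == "AND":
        return label_E & label_C
    raise ValueError(f"op must be 'AND' or 'OR', got {op!r}")


def combine_kernels(K_E: np.ndarray, K_C: np.ndarray, alpha: float) -> np.ndarray:
    """alpha*K_E + (1-alpha)*K_C; PSD because both weights are non-negative."""
    K_E, K_C = np.asarray(K_E, dtype=float), np.asarray(K_C, dtype=float)
    if K_E.shape != K_C.shape:
        raise ValueError("kernel shape mismatch")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * K_E + (1.0 - alpha) * K_C


# ---------------------------------------------------------------------------
# intermediate-integration predictors

class IntermediateNMC:
    """Combined-distance nearest mean: d_class = alpha*d_E + (1-alpha)*d_C,
    assign to the class with the smaller combined distance (ties -> poor)."""

    def __init__(self, model_E: NearestMeanClassifier,
                 model_C: NearestMeanClassifier, alpha: float) -> None:
        _check_alpha(alpha)
        self.model_E, self.model_C, self.alpha = model_E, model_C, alpha

    def combined_distances(self, X_E, X_C) -> tuple[np.ndarray, np.ndarray]:
        dpE, dgE = self.model_E.distances(X_E)
        dpC, dgC = self.model_C.distances(X_C)
        a = self.alpha
        return a * dpE + (1 - a) * dpC, a * dgE + (1 - a) * dgC

    def score(self, X_E, X_C) -> np.ndarray:
        d_poor, d_good = self.combined_distances(X_E, X_C)
        return d_good - d_poor

    def predict(self, X_E, X_C) -> np.ndarray:
        return (self.score(X_E, X_C) >= 0).astype(int)


class IntermediateSBC:
    """Linear combination of per-view posteriors; assign to the class with
    the maximal combined posterior (ties -> poor)."""

    def __init__(self, model_E: SimpleBayesClassifier,
                 model_C: SimpleBayesClassifier, alpha: float) -> None:
        _check_alpha(alpha)
        self.model_E, self.model_C, self.alpha = model_E, model_C, alpha

    def score(self, X_E, X_C) -> np.ndarray:
        a = self.alpha
        return (a * self.model_E.posterior_poor(X_E)
                + (1 - a) * self.model_C.posterior_poor(X_C))

    def predict(self, X_E, X_C) -> np.ndarray:
        return (self.score(X_E, X_C) >= 0.5).astype(int)


class IntermediateKNN:
    """Prior-adjusted 3NN on the linear combination of per-view cosine
    distances to the training samples."""

    def __init__(self, X_E_train, X_C_train, y_train, alpha: float,
                 k: int = 3) -> None:
        _check_alpha(alpha)
        self.alpha = alpha
        self.knn = PriorWeightedKNN(k=k).fit(
            np.asarray(X_E_train, dtype=float), y_train
        )
        self.X_E_train = np.asarray(X_E_train, dtype=float)
        self.X_C_train = np.asarray(X_C_train, dtype=float)

    def _combined_D(self, X_E, X_C) -> np.ndarray:
        D_E = 1.0 - cosine_kernel(np.atleast_2d(X_E), self.X_E_train)
        D_C = 1.0 - cosine_kernel(np.atleast_2d(X_C), self.X_C_train)
        return self.alpha * D_E + (1 - self.alpha) * D_C

    def score(self, X_E, X_C) -> np.ndarray:
        return self.knn.predict_from_distances(self._combined_D(X_E, X_C))[1]

    def predict(self, X_E, X_C) -> np.ndarray:
        return self.knn.predict_from_distances(self._combined_D(X_E, X_C))[0]


class IntermediateSVM:
    """SVM on the convex combination of the per-view cosine kernels."""

    def __init__(self, X_E_train, X_C_train, y_train, alpha: float,
                 C: float = 1.0) -> None:
        _check_alpha(alpha)
        self.alpha = alpha
        self.X_E_train = np.asarray(X_E_train, dtype=float)
        self.X_C_train = np.asarray(X_C_train, dtype=float)
        K = combine_kernels(
            cosine_kernel(self.X_E_train, self.X_E_train),
            cosine_kernel(self.X_C_train, self.X_C_train),
            alpha,
        )
        self.kernel_svm = KernelSVM(C=C).fit(K, y_train)

    def _K(self, X_E, X_C) -> np.ndarray:
        return combine_kernels(
            cosine_kernel(np.atleast_2d(X_E), self.X_E_train),
            cosine_kernel(np.atleast_2d(X_C), self.X_C_train),
            self.alpha,
        )

    def score(self, X_E, X_C) -> np.ndarray:
        return self.kernel_svm.decision(self._K(X_E, X_C))

    def predict(self, X_E, X_C) -> np.ndarray:
        return (self.score(X_E, X_C) >= 0).astype(int)


def _check_alpha(alpha: float) -> None:
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")


# thin functional forms of the intermediate rules

def intermediate_nmc(model_E, model_C, alpha, x_E, x_C):
    """Combined per-class distances and label for sample(s) x."""
    inter = IntermediateNMC(model_E, model_C, alpha)
    d_poor, d_good = inter.combined_distances(x_E, x_C)
    return d_poor, d_good, (d_good - d_poor >= 0).astype(int)


def intermediate_sbc(model_E, model_C, alpha, x_E, x_C):
    """Combined posterior of the poor class and label."""
    inter = IntermediateSBC(model_E, model_C, alpha)
    post = inter.score(x_E, x_C)
    return post, (post >= 0.5).astype(int)


def intermediate_3nn(X_E_train, X_C_train, y_train, alpha, x_E, x_C):
    """Label from 3NN on combined distances."""
    return IntermediateKNN(X_E_train, X_C_train, y_train, alpha).predict(x_E, x_C)


# ---------------------------------------------------------------------------
# alpha selection

def _train_metric(pred: np.ndarray, y: np.ndarray, metric: str) -> float:
    if metric == "efpfn":
        return efpfn(confusion(pred, y))
    if metric == "error":
        return float(np.mean(pred != y))
    raise ValueError(f"unknown training metric {metric!r}")


def _alpha_curve_predictions(
    E: np.ndarray, C: np.ndarray, y: np.ndarray, fit_idx: np.ndarray,
    eval_idx: np.ndarray, classifier_kind: str, grid: np.ndarray,
    discrete_mask_E, discrete_mask_C,
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and poor-likeness scores of the intermediate classifier on
    ``eval_idx`` for every alpha in the grid, with per-view models fitted on
    ``fit_idx``.  Both arrays have shape (len(grid), len(eval_idx))."""
    yf = y[fit_idx]
    labels = np.empty((len(grid), len(eval_idx)), dtype=int)
    scores = np.empty((len(grid), len(eval_idx)))
    if classifier_kind == clf.NMC:
        mE = NearestMeanClassifier().fit(E[fit_idx], yf)
        mC = NearestMeanClassifier().fit(C[fit_idx], yf)
        dpE, dgE = mE.distances(E[eval_idx])
        dpC, dgC = mC.distances(C[eval_idx])
        for i, a in enumerate(grid):
            s = (a * dgE + (1 - a) * dgC) - (a * dpE + (1 - a) * dpC)
            scores[i] = s
            labels[i] = (s >= 0).astype(int)
    elif classifier_kind == clf.SBC:
        mE = SimpleBayesClassifier(discrete_mask_E).fit(E[fit_idx], yf)
        mC = SimpleBayesClassifier(discrete_mask_C).fit(C[fit_idx], yf)
        pE = mE.posterior_poor(E[eval_idx])
        pC = mC.posterior_poor(C[eval_idx])
        for i, a in enumerate(grid):
            s = a * pE + (1 - a) * pC
            scores[i] = s
            labels[i] = (s >= 0.5).astype(int)
    elif classifier_kind == clf.KNN3:
        knn = PriorWeightedKNN(k=3).fit(E[fit_idx], yf)
        D_E = 1.0 - cosine_kernel(E[eval_idx], E[fit_idx])
        D_C = 1.0 - cosine_kernel(C[eval_idx], C[fit_idx])
        for i, a in enumerate(grid):
            lab, share = knn.predict_from_distances(
                a * D_E + (1 - a) * D_C
            )
            labels[i] = lab
            scores[i] = share
    elif classifier_kind == clf.SVM:
        K_E_ff = cosine_kernel(E[fit_idx], E[fit_idx])
        K_C_ff = cosine_kernel(C[fit_idx], C[fit_idx])
        K_E_ef = cosine_kernel(E[eval_idx], E[fit_idx])
        K_C_ef = cosine_kernel(C[eval_idx], C[fit_idx])
        for i, a in enumerate(grid):
            svm = KernelSVM().fit(combine_kernels(K_E_ff, K_C_ff, a), yf)
            s = svm.decision(combine_kernels(K_E_ef, K_C_ef, a))
            scores[i] = s
            labels[i] = (s >= 0).astype(int)
    else:
        raise ValueError(
            f"alpha selection undefined for classifier {classifier_kind!r}"
        )
    return labels, scores


def select_alpha(
    train_E: np.ndarray,
    train_C: np.ndarray,
    label: np.ndarray,
    classifier_kind: str,
    metric: str = "efpfn",
    alpha_grid: np.ndarray | None = None,
    discrete_mask_E: np.ndarray | None = None,
    discrete_mask_C: np.ndarray | None = None,
    evaluation: str = "cv",
    cv_folds: int = 10,
    seed: int = 0,
) -> float:
    """Pick the grid alpha minimizing the error of the intermediate
    classifier over the training partition (ties -> smallest alpha).

    The views passed in are the per-view optimal feature sets; the scan is
    0..1 in steps of 0.01.  Only training samples are involved, keeping the
    optimization unbiased with respect to the outer loop.  By default the
    alpha curve is scored on stratified cross-validated predictions within
    the training partition; ``evaluation='train'`` scores plain
    resubstitution error instead (which is biased toward the noisier view:
    a pure-noise view earns spurious resubstitution accuracy because each
    sample contributes to its own class model).
    """
    grid = DEFAULT_ALPHA_GRID if alpha_grid is None else np.asarray(alpha_grid)
    y = np.asarray(label).astype(int)
    E = np.asarray(train_E, dtype=float)
    C = np.asarray(train_C, dtype=float)
    n = len(y)
    all_idx = np.arange(n)
    if evaluation == "train":
        preds, scores = _alpha_curve_predictions(
            E, C, y, all_idx, all_idx, classifier_kind, grid,
            discrete_mask_E, discrete_mask_C,
        )
    elif evaluation == "cv":
        from .dlcv import stratified_kfold  # deferred: avoids import cycle

        k = min(cv_folds, int(np.bincount(y, minlength=2).min()))
        if k < 2:
            raise ValueError("training set not stratifiable for alpha CV")
        assign = stratified_kfold(y, k, seed)
        preds = np.empty((len(grid), n), dtype=int)
        scores = np.empty((len(grid), n))
        for f in range(k):
            ev = np.flatnonzero(assign == f)
            ft = np.flatnonzero(assign != f)
            preds[:, ev], scores[:, ev] = _alpha_curve_predictions(
                E, C, y, ft, ev, classifier_kind, grid,
                discrete_mask_E, discrete_mask_C,
            )
    else:
        raise ValueError("evaluation must be 'cv' or 'train'")
    values = np.array([
        _train_metric(preds[i], y, metric) for i in range(len(grid))
    ])
    # exact ties in the discrete error are resolved by the continuous class
    # separation of the combined score (larger is better), then by the
    # smallest alpha; identical views therefore still resolve to alpha = 0
    tied = np.flatnonzero(values == values.min())
    sep = np.array([
        scores[i, y == 1].mean() - scores[i, y == 0].mean() for i in tied
    ])
    near_max = sep >= sep.max() - 1e-9 * max(1.0, abs(sep.max()))
    best = tied[np.flatnonzero(near_max)[0]]
    return float(grid[best])


# ---------------------------------------------------------------------------
# HybridTree

@dataclasses.dataclass
class _HybridNode:
    depth: int
    n_samples: int
    n_poor: int
    is_leaf: bool
    label: int
    view: str | None = None
    nmc: NearestMeanClassifier | None = None
    columns: np.ndarray | None = None
    left: "_HybridNode | None" = None   # predicted poor branch
    right: "_HybridNode | None" = None  # predicted good branch


class HybridTree:
    """Decision tree whose nodes are nearest-mean classifiers.

    HybridTree(C) roots an NMC on the clinical view and branches with
    expression NMCs below; HybridTree(E) roots on expression and uses
    clinical NMCs in all subsequent nodes.  Per-node features are re-ranked
    on that node's samples only: top 100 on E, top 10 on C (capped at the
    view's width).  Branching stops at pure nodes, nodes with fewer than
    ``min_node`` (10) samples, or ``max_depth``; leaves take the majority
    class (ties -> poor).
    """

    def __init__(self, start_view: str, max_depth: int,
                 n_features_E: int = 100, n_features_C: int = 10,
                 min_node: int = 10) -> None:
        if start_view not in ("E", "C"):
            raise ValueError("start_view must be 'E' or 'C'")
        if max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        self.start_view = start_view
        self.max_depth = max_depth
        self.n_features_E = n_features_E
        self.n_features_C = n_features_C
        self.min_node = min_node

    def _view_at(self, depth: int) -> str:
        if depth == 0:
            return self.start_view
        return "E" if self.start_view == "C" else "C"

    def fit(self, E: np.ndarray, C: np.ndarray, meta_C: pd.DataFrame,
            y: np.ndarray) -> "HybridTree":
        self._E_meta_cols = None
        self.meta_C = meta_C
        self.nodes: list[_HybridNode] = []
        self.root_ = self._build(
            np.asarray(E, dtype=float), np.asarray(C, dtype=float),
            np.asarray(y).astype(int), depth=0,
        )
        return self

    def _build(self, E, C, y, depth) -> _HybridNode:
        n = len(y)
        n_poor = int(np.sum(y == 1))
        label = 1 if n_poor >= n - n_poor else 0
        node = _HybridNode(depth=depth, n_samples=n, n_poor=n_poor,
                           is_leaf=True, label=label)
        self.nodes.append(node)
        pure = n_poor in (0, n)
        if pure or n < self.min_node or depth >= self.max_depth:
            return node
        view = self._view_at(depth)
        X = E if view == "E" else C
        budget = self.n_features_E if view == "E" else self.n_features_C
        budget = min(budget, X.shape[1])
        if view == "E":
            meta = pd.DataFrame({"kind": ["continuous"] * X.shape[1]})
        else:
            meta = self.meta_C[["kind"]]
        ranked = rank_features(X, meta, y)
        cols = ranked.order[:budget]
        nmc = NearestMeanClassifier().fit(X[:, cols], y)
        pred = nmc.predict(X[:, cols])
        go_poor = pred == 1
        if go_poor.all() or (~go_poor).all():
            # the node NMC fails to split the samples; stay a leaf
            return node
        node.is_leaf = False
        node.view = view
        node.nmc = nmc
        node.columns = cols
        node.left = self._build(E[go_poor], C[go_poor], y[go_poor], depth + 1)
        node.right = self._build(E[~go_poor], C[~go_poor], y[~go_poor], depth + 1)
        return node

    def _route(self, e: np.ndarray, c: np.ndarray) -> _HybridNode:
        node = self.root_
        while not node.is_leaf:
            x = e if node.view == "E" else c
            go_poor = node.nmc.predict(x[None, node.columns])[0] == 1
            node = node.left if go_poor else node.right
        return node

    def predict(self, E: np.ndarray, C: np.ndarray) -> np.ndarray:
        E = np.atleast_2d(np.asarray(E, dtype=float))
        C = np.atleast_2d(np.asarray(C, dtype=float))
        return np.array(
            [self._route(e, c).label for e, c in zip(E, C)], dtype=int
        )

    def score(self, E: np.ndarray, C: np.ndarray) -> np.ndarray:
        E = np.atleast_2d(np.asarray(E, dtype=float))
        C = np.atleast_2d(np.asarray(C, dtype=float))
        out = np.empty(len(E))
        for i, (e, c) in enumerate(zip(E, C)):
            node = self._route(e, c)
            out[i] = node.n_poor / node.n_samples if node.n_samples else 0.0
        return out


def fit_hybrid_tree(E, C, meta_C, y, start_view: str, max_depth: int,
                    **kwargs) -> HybridTree:
    return HybridTree(start_view, max_depth, **kwargs).fit(E, C, meta_C, y)
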