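"""Double-loop cross-validation: stratified outer folds for unbiased
performance estimation, an inner 10-fold loop selecting the number of
features (tree depth, mixing parameter alpha), paired significance testing,
and pre-validation consensus labels for survival analysis.

Pairing is guaranteed by the seed schedule: repeat ``r`` uses
``seed + r`` for the outer split and ``seed + 10**6 + r`` for inner splits,
independent of the experiment arm, so every arm sees identical folds.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import classifiers as clf
from .classifiers import GiniTree, make_classifier
from .integration import (
    HybridTree,
    IntegrationSpec,
    IntermediateKNN,
    IntermediateNMC,
    IntermediateSBC,
    IntermediateSVM,
    concat_views,
    late_combine,
    select_alpha,
)
from .metrics import confusion, efpfn, late_roc, roc_auc
from .preprocess import CONTINUOUS, DISCRETE_KINDS, Normalizer
from .ranking import rank_features

logger = logging.getLogger(__name__)

_INNER_SEED_OFFSET = 10**6


@dataclasses.dataclass(frozen=True)
class DlcvConfig:
    """Protocol parameters.  Full-scale runs use 60 repeats; the default is
    the desk-scale 10."""

    n_repeats: int = 10
    outer_folds: int = 5
    inner_folds: int = 10
    max_features_E: int = 200
    max_features_C: int = 54
    max_depth: int = 5
    feature_stride: int = 1
    metric: str = "efpfn"        # 'efpfn' (minimize) or 'auc' (maximize)
    alpha_metric: str = "efpfn"  # criterion of the alpha scan
    alpha_evaluation: str = "cv"  # 'cv' (within-train CV) or 'train'
    normalize_in_cv: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.max_features_E < 1 or self.max_features_C < 1:
            raise ValueError("feature budgets must be >= 1")
        if self.metric not in ("efpfn", "auc"):
            raise ValueError("metric must be 'efpfn' or 'auc'")


@dataclasses.dataclass
class DlcvResult:
    spec: IntegrationSpec
    config: DlcvConfig
    records: pd.DataFrame
    oof_labels: np.ndarray   # (n_repeats, n_samples)
    oof_scores: np.ndarray   # (n_repeats, n_samples); NaN for late fusion
    metric: str

    @property
    def metric_values(self) -> np.ndarray:
        """Per-(repeat, fold) outer-loop metric, in (repeat, fold) order —
        identical ordering across arms run under the same config seed."""
        ordered = self.records.sort_values(["repeat", "fold"])
        return ordered["value"].to_numpy(dtype=float)

    @property
    def mean_metric(self) -> float:
        return float(self.records["value"].mean())

    def consensus_labels(self) -> np.ndarray:
        return prevalidation_consensus(self.oof_labels)


def stratified_kfold(label: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold assignment with per-class counts differing by at most one."""
    label = np.asarray(label).astype(int)
    counts = np.bincount(label, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"smallest class ({counts.min()}) smaller than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assign = np.empty(len(label), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(label)), label)):
        assign[test_idx] = f
    return assign


def paired_test(metric_A: np.ndarray, metric_B: np.ndarray) -> float:
    """One-sided paired t-test p-value for mean(A) < mean(B).

    All-zero differences give p = 1 by convention; a degenerate nonzero
    constant difference gives 0 or 1 by its sign.
    """
    a = np.asarray(metric_A, dtype=float)
    b = np.asarray(metric_B, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    if np.all(d == 0):
        return 1.0
    if d.std(ddof=1) == 0:
        return 0.0 if d.mean() < 0 else 1.0
    return float(stats.ttest_rel(a, b, alternative="less").pvalue)


def prevalidation_consensus(oof_labels: np.ndarray) -> np.ndarray:
    """Mean out-of-fold prediction per sample across repeats, encoded
    good = 1 / poor = 0; means of at most 0.5 go to poor (believe the
    positive on ties)."""
    oof = np.asarray(oof_labels)
    if oof.ndim != 2:
        raise ValueError("expect (n_repeats, n_samples) label matrix")
    valid = oof >= 0
    if not valid.any(axis=0).all():
        raise ValueError("every sample needs at least one prediction")
    good = np.where(valid, 1 - oof, 0).sum(axis=0) / valid.sum(axis=0)
    return np.where(good > 0.5, 0, 1)


def final_feature_count(result: DlcvResult) -> dict:
    """Arithmetic mean of the per-(repeat, fold) selected feature counts per
    view, rounded half away from zero."""

    def _round(m: float) -> int:
        return int(np.floor(m + 0.5))

    out = {}
    for key in ("n_features_E", "n_features_C"):
        vals = result.records[key].dropna()
        out[key] = _round(float(vals.mean())) if len(vals) else None
    return out


# ---------------------------------------------------------------------------
# inner-loop selection machinery

def _continuous_meta(p: int) -> pd.DataFrame:
    return pd.DataFrame({"kind": [CONTINUOUS] * p})


def _discrete_mask(meta: pd.DataFrame) -> np.ndarray:
    return meta["kind"].isin(DISCRETE_KINDS).to_numpy()


def _nmc_prefix_margin(Xtr: np.ndarray, ytr: np.ndarray,
                       Xval: np.ndarray) -> np.ndarray:
    """NMC decision margin (d_good - d_poor) for every feature-count prefix.

    Columns must already be in ranked order; returns (n_val, p), where
    column k-1 is the margin of the top-k classifier.  Exploits the fact
    that cosine distances to prefix centroids decompose into cumulative
    sums of dot products and squared norms.
    """
    c_poor = Xtr[ytr == 1].mean(axis=0)
    c_good = Xtr[ytr == 0].mean(axis=0)
    cum_x2 = np.cumsum(Xval**2, axis=1)
    out = np.empty((Xval.shape[0], Xval.shape[1]))
    sims = []
    for c in (c_poor, c_good):
        cum_c2 = np.cumsum(c**2)
        dot = np.cumsum(Xval * c, axis=1)
        denom = np.sqrt(cum_x2 * cum_c2)
        with np.errstate(divide="ignore", invalid="ignore"):
            sim = np.where(denom > 0, dot / np.where(denom > 0, denom, 1.0), 0.0)
        sims.append(sim)
    out = sims[0] - sims[1]  # sim_poor - sim_good = d_good - d_poor
    return out


def _sbc_prefix_margin(Xtr: np.ndarray, ytr: np.ndarray, Xval: np.ndarray,
                       discrete: np.ndarray) -> np.ndarray:
    """Naive-Bayes log-posterior margin log P(poor|x) - log P(good|x) for
    every feature-count prefix (columns in ranked order)."""
    n_val, p = Xval.shape
    contrib = np.empty((2, n_val, p))
    sd_floor = 1e-6
    for ci, c in enumerate((0, 1)):
        Xc = Xtr[ytr == c]
        cont = ~discrete
        if cont.any():
            mu = Xc[:, cont].mean(axis=0)
            sd = Xc[:, cont].std(axis=0, ddof=1) if Xc.shape[0] > 1 else \
                np.zeros(cont.sum())
            sd = np.maximum(sd, sd_floor)
            contrib[ci][:, cont] = stats.norm.logpdf(
                Xval[:, cont], loc=mu, scale=sd
            )
        for j in np.flatnonzero(discrete):
            levels, counts = np.unique(Xtr[:, j], return_counts=True)
            xc = Xc[:, j]
            cc = np.array([np.sum(xc == lv) for lv in levels])
            probs = (cc + 1.0) / (len(xc) + len(levels))
            idx = np.searchsorted(levels, Xval[:, j])
            idx_c = np.clip(idx, 0, len(levels) - 1)
            known = levels[idx_c] == Xval[:, j]
            unseen = np.log(1.0 / (len(xc) + len(levels)))
            contrib[ci][:, j] = np.where(known, np.log(probs)[idx_c], unseen)
    log_prior = np.log(
        np.array([np.mean(ytr == 0), np.mean(ytr == 1)])
    )
    L0 = log_prior[0] + np.cumsum(contrib[0], axis=1)
    L1 = log_prior[1] + np.cumsum(contrib[1], axis=1)
    return L1 - L0


def _labels_metric(labels: np.ndarray, margins: np.ndarray, yval: np.ndarray,
                   ks: np.ndarray, metric: str) -> np.ndarray:
    """Metric per candidate count k, from per-prefix labels/margins."""
    cols = ks - 1
    lab = labels[:, cols]
    if metric == "efpfn":
        pos = yval == 1
        fn = (lab[pos] == 0).sum(axis=0) / max(pos.sum(), 1)
        fp = (lab[~pos] == 1).sum(axis=0) / max((~pos).sum(), 1)
        return 0.5 * (fn + fp)
    vals = np.empty(len(cols))
    for i, c in enumerate(cols):
        s = margins[:, c]
        vals[i] = 0.5 if np.ptp(s) == 0 else roc_auc_score(yval, s)
    return vals


def _inner_assignments(y: np.ndarray, config: DlcvConfig,
                       seed: int) -> np.ndarray:
    k = min(config.inner_folds, int(np.bincount(y, minlength=2).min()))
    if k < 2:
        raise ValueError("training set not stratifiable into inner folds")
    if k < config.inner_folds:
        logger.debug("inner folds reduced to %d (small class)", k)
    return stratified_kfold(y, k, seed)


def _select_count(kind: str, Xo: np.ndarray, y: np.ndarray,
                  discrete_o: np.ndarray, budget: int, config: DlcvConfig,
                  seed: int) -> int:
    """Learning curve over feature counts 1..budget via inner CV; returns the
    count with the best mean metric (ties -> smallest count)."""
    budget = min(budget, Xo.shape[1])
    ks = np.arange(1, budget + 1, config.feature_stride)
    assign = _inner_assignments(y, config, seed)
    n_folds = assign.max() + 1
    curve = np.zeros((n_folds, len(ks)))
    for f in range(n_folds):
        tr, va = assign != f, assign == f
        Xtr, Xva, ytr, yva = Xo[tr], Xo[va], y[tr], y[va]
        if kind == clf.NMC:
            margins = _nmc_prefix_margin(Xtr[:, :budget], ytr, Xva[:, :budget])
            labels = (margins >= 0).astype(int)
            curve[f] = _labels_metric(labels, margins, yva, ks, config.metric)
        elif kind == clf.SBC:
            margins = _sbc_prefix_margin(
                Xtr[:, :budget], ytr, Xva[:, :budget], discrete_o[:budget]
            )
            labels = (margins >= 0).astype(int)
            curve[f] = _labels_metric(labels, margins, yva, ks, config.metric)
        else:
            for i, k in enumerate(ks):
                model = make_classifier(kind, discrete_mask=discrete_o[:k])
                model.fit(Xtr[:, :k], ytr)
                lab = model.predict(Xva[:, :k])
                if config.metric == "efpfn":
                    curve[f, i] = efpfn(confusion(lab, yva))
                else:
                    s = model.score(Xva[:, :k])
                    curve[f, i] = 0.5 if np.ptp(s) == 0 else \
                        roc_auc_score(yva, s)
    mean = curve.mean(axis=0)
    best = int(np.argmin(mean)) if config.metric == "efpfn" else \
        int(np.argmax(mean))
    return int(ks[best])


def _select_depth(kind: str, X: np.ndarray, y: np.ndarray,
                  config: DlcvConfig, seed: int) -> int:
    """Inner-CV learning curve over tree depths 1..max_depth."""
    depths = np.arange(1, config.max_depth + 1)
    assign = _inner_assignments(y, config, seed)
    n_folds = assign.max() + 1
    curve = np.zeros((n_folds, len(depths)))
    for f in range(n_folds):
        tr, va = assign != f, assign == f
        for i, d in enumerate(depths):
            model = GiniTree(max_depth=int(d)).fit(X[tr], y[tr])
            curve[f, i] = _depth_metric(model.predict(X[va]),
                                        model.score(X[va]), y[va], config)
    mean = curve.mean(axis=0)
    best = int(np.argmin(mean)) if config.metric == "efpfn" else \
        int(np.argmax(mean))
    return int(depths[best])


def _select_hybrid_depth(E, C, meta_C, y, start_view: str,
                         config: DlcvConfig, seed: int) -> int:
    depths = np.arange(1, config.max_depth + 1)
    assign = _inner_assignments(y, config, seed)
    n_folds = assign.max() + 1
    curve = np.zeros((n_folds, len(depths)))
    for f in range(n_folds):
        tr, va = assign != f, assign == f
        for i, d in enumerate(depths):
            model = HybridTree(start_view, int(d)).fit(
                E[tr], C[tr], meta_C, y[tr]
            )
            curve[f, i] = _depth_metric(
                model.predict(E[va], C[va]), model.score(E[va], C[va]),
                y[va], config,
            )
    mean = curve.mean(axis=0)
    best = int(np.argmin(mean)) if config.metric == "efpfn" else \
        int(np.argmax(mean))
    return int(depths[best])


def _depth_metric(labels, scores, yval, config: DlcvConfig) -> float:
    if config.metric == "efpfn":
        return efpfn(confusion(labels, yval))
    return 0.5 if np.ptp(scores) == 0 else float(roc_auc_score(yval, scores))


# ---------------------------------------------------------------------------
# fitting one experiment arm on one training partition

@dataclasses.dataclass
class FittedSpec:
    predict: callable   # (E_test, C_test) -> (labels, scores)
    info: dict


def _fit_view(kind: str, X: np.ndarray, meta: pd.DataFrame, y: np.ndarray,
              budget: int, config: DlcvConfig, seed: int,
              fixed_count: int | None = None) -> dict:
    """Rank + inner-select + refit a single-view classifier (or, for Tree1,
    depth-select on all features)."""
    if kind == clf.TREE1:
        depth = _select_depth(kind, X, y, config, seed)
        model = GiniTree(max_depth=depth).fit(X, y)
        return {"model": model, "cols": np.arange(X.shape[1]),
                "n_features": None, "depth": depth}
    ranked = rank_features(X, meta, y)
    budget = min(budget, X.shape[1])
    if kind == clf.TREE2:
        budget = min(budget, 200)
    Xo = X[:, ranked.order]
    discrete_o = _discrete_mask(meta)[ranked.order]
    if fixed_count is not None:
        k = min(fixed_count, budget)
    else:
        k = _select_count(kind, Xo, y, discrete_o, budget, config, seed)
    cols = ranked.order[:k]
    model = make_classifier(kind, discrete_mask=_discrete_mask(meta)[cols])
    model.fit(X[:, cols], y)
    return {"model": model, "cols": cols, "n_features": k, "depth": None}


def _fit_spec(spec: IntegrationSpec, Etr, Ctr, meta_C, ytr,
              config: DlcvConfig, seed: int) -> FittedSpec:
    kind = spec.classifier
    meta_E = _continuous_meta(Etr.shape[1])

    if spec.mode in ("none_E", "none_C"):
        use_E = spec.mode == "none_E"
        X = Etr if use_E else Ctr
        meta = meta_E if use_E else meta_C
        budget = config.max_features_E if use_E else config.max_features_C
        fixed = spec.n_features_E if use_E else spec.n_features_C
        fv = _fit_view(kind, X, meta, ytr, budget, config, seed, fixed)

        def predict(Ete, Cte, fv=fv, use_E=use_E):
            Xt = (Ete if use_E else Cte)[:, fv["cols"]]
            return fv["model"].predict(Xt), fv["model"].score(Xt)

        info = {
            "n_features_E": fv["n_features"] if use_E else None,
            "n_features_C": None if use_E else fv["n_features"],
            "alpha": None, "depth": fv["depth"],
        }
        return FittedSpec(predict, info)

    if spec.mode == "early":
        X, meta = concat_views(Etr, Ctr, meta_E, meta_C)
        fv = _fit_view(kind, X, meta, ytr, config.max_features_E, config,
                       seed, spec.n_features_E)
        p_E = Etr.shape[1]

        def predict(Ete, Cte, fv=fv, p_E=p_E):
            Xt = np.hstack([Ete, Cte])[:, fv["cols"]]
            return fv["model"].predict(Xt), fv["model"].score(Xt)

        n_from_E = int(np.sum(fv["cols"] < p_E)) if fv["n_features"] else None
        info = {
            "n_features_E": n_from_E,
            "n_features_C": (fv["n_features"] - n_from_E)
            if fv["n_features"] else None,
            "alpha": None, "depth": fv["depth"],
        }
        return FittedSpec(predict, info)

    if spec.mode == "intermediate":
        if kind in (clf.HYBRID_C, clf.HYBRID_E):
            start = "C" if kind == clf.HYBRID_C else "E"
            depth = _select_hybrid_depth(Etr, Ctr, meta_C, ytr, start,
                                         config, seed)
            model = HybridTree(start, depth).fit(Etr, Ctr, meta_C, ytr)

            def predict(Ete, Cte, model=model):
                return model.predict(Ete, Cte), model.score(Ete, Cte)

            return FittedSpec(predict, {
                "n_features_E": None, "n_features_C": None,
                "alpha": None, "depth": depth,
            })

        fvE = _fit_view(kind, Etr, meta_E, ytr, config.max_features_E,
                        config, seed, spec.n_features_E)
        fvC = _fit_view(kind, Ctr, meta_C, ytr, config.max_features_C,
                        config, seed, spec.n_features_C)
        E_sel, C_sel = Etr[:, fvE["cols"]], Ctr[:, fvC["cols"]]
        mask_C = _discrete_mask(meta_C)[fvC["cols"]]
        if spec.alpha is not None:
            alpha = spec.alpha
        else:
            alpha = select_alpha(
                E_sel, C_sel, ytr, kind, metric=config.alpha_metric,
                discrete_mask_E=np.zeros(E_sel.shape[1], dtype=bool),
                discrete_mask_C=mask_C,
                evaluation=config.alpha_evaluation,
                cv_folds=config.inner_folds, seed=seed,
            )
        if kind == clf.NMC:
            inter = IntermediateNMC(fvE["model"], fvC["model"], alpha)
        elif kind == clf.SBC:
            inter = IntermediateSBC(fvE["model"], fvC["model"], alpha)
        elif kind == clf.KNN3:
            inter = IntermediateKNN(E_sel, C_sel, ytr, alpha)
        elif kind == clf.SVM:
            inter = IntermediateSVM(E_sel, C_sel, ytr, alpha)
        else:  # pragma: no cover - excluded by spec validation
            raise ValueError(kind)

        def predict(Ete, Cte, inter=inter, fvE=fvE, fvC=fvC):
            Xe, Xc = Ete[:, fvE["cols"]], Cte[:, fvC["cols"]]
            return inter.predict(Xe, Xc), inter.score(Xe, Xc)

        return FittedSpec(predict, {
            "n_features_E": fvE["n_features"],
            "n_features_C": fvC["n_features"],
            "alpha": alpha, "depth": fvE["depth"],
        })

    if spec.mode in ("late_AND", "late_OR"):
        op = spec.mode.split("_")[1]
        fvE = _fit_view(kind, Etr, meta_E, ytr, config.max_features_E,
                        config, seed, spec.n_features_E)
        fvC = _fit_view(kind, Ctr, meta_C, ytr, config.max_features_C,
                        config, seed, spec.n_features_C)

        def predict(Ete, Cte, fvE=fvE, fvC=fvC, op=op):
            Xe, Xc = Ete[:, fvE["cols"]], Cte[:, fvC["cols"]]
            lab_E = fvE["model"].predict(Xe)
            lab_C = fvC["model"].predict(Xc)
            fused = late_combine(lab_E, lab_C, op)
            return fused, (fvE["model"].score(Xe), fvC["model"].score(Xc))

        return FittedSpec(predict, {
            "n_features_E": fvE["n_features"],
            "n_features_C": fvC["n_features"],
            "alpha": None, "depth": fvE["depth"],
        })

    raise ValueError(f"unknown mode {spec.mode!r}")  # pragma: no cover


def inner_select(E, C, meta_C, y, spec: IntegrationSpec,
                 config: DlcvConfig, seed: int | None = None) -> dict:
    """Run the inner-loop selection for one training partition and return the
    chosen feature counts / depth / alpha."""
    seed = config.seed if seed is None else seed
    return _fit_spec(spec, np.asarray(E, dtype=float),
                     np.asarray(C, dtype=float), meta_C,
                     np.asarray(y).astype(int), config, seed).info


def _rank_by_score(scores: np.ndarray) -> np.ndarray:
    """Sample ordering most-to-least poor-like, ties broken by index."""
    return np.lexsort((np.arange(len(scores)), -np.asarray(scores)))


def _outer_metric(labels, scores, yte, config: DlcvConfig, mode: str) -> float:
    if config.metric == "efpfn":
        return efpfn(confusion(labels, yte))
    if isinstance(scores, tuple):  # late fusion: joint-operating-point ROC
        op = mode.split("_")[1]
        return late_roc(_rank_by_score(scores[0]), _rank_by_score(scores[1]),
                        yte, op).auc
    if np.ptp(scores) == 0:
        return 0.5
    return roc_auc(scores, yte).auc


def dlcv_run(E, C, meta_C, y, spec: IntegrationSpec,
             config: DlcvConfig) -> DlcvResult:
    """Run the full double-loop protocol for one experiment arm.

    Feature ranking, inner selection, alpha and depth optimization all see
    only the outer-training partition; the held-out fold contributes one
    metric value and one out-of-fold prediction per sample per repeat.
    """
    E = np.asarray(E, dtype=float)
    C = np.asarray(C, dtype=float)
    y = np.asarray(y).astype(int)
    n = len(y)
    rows = []
    oof_labels = np.full((config.n_repeats, n), -1, dtype=int)
    oof_scores = np.full((config.n_repeats, n), np.nan)
    for r in range(config.n_repeats):
        assign = stratified_kfold(y, config.outer_folds, config.seed + r)
        inner_seed = config.seed + _INNER_SEED_OFFSET + r
        for f in range(config.outer_folds):
            te = assign == f
            tr = ~te
            if config.normalize_in_cv:
                nE = Normalizer().fit(E[tr])
                nC = Normalizer().fit(C[tr])
            else:
                nE = Normalizer().fit(E)
                nC = Normalizer().fit(C)
            Etr, Ete = nE.transform(E[tr]), nE.transform(E[te])
            Ctr, Cte = nC.transform(C[tr]), nC.transform(C[te])
            fitted = _fit_spec(spec, Etr, Ctr, meta_C, y[tr], config,
                               inner_seed)
            labels, scores = fitted.predict(Ete, Cte)
            value = _outer_metric(labels, scores, y[te], config, spec.mode)
            oof_labels[r, te] = labels
            if not isinstance(scores, tuple):
                oof_scores[r, te] = scores
            rows.append({
                "repeat": r, "fold": f, "value": value,
                **fitted.info,
            })
    records = pd.DataFrame(rows)
    return DlcvResult(spec=spec, config=config, records=records,
                      oof_labels=oof_labels, oof_scores=oof_scores,
                      metric=config.metric)
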