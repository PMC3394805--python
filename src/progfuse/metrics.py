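"""Evaluation metrics: eFPFN, trapezoidal ROC/AUC, the joint-operating-point
late-fusion ROC, and Kaplan-Meier / log-rank survival summaries.

The primary error metric is the average false-positive false-negative ratio

    eFPFN = (FP/(FP+TN) + FN/(FN+TP)) / 2 = 1 - (Sensitivity + Specificity)/2,

which is insensitive to class imbalance; poor outcome is the positive class.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with poor (1) as the positive class."""
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    if not (np.isin(pred, (0, 1)).all() and np.isin(truth, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (truth == 1))),
        tn=int(np.sum((pred == 0) & (truth == 0))),
        fp=int(np.sum((pred == 1) & (truth == 0))),
        fn=int(np.sum((pred == 0) & (truth == 1))),
    )


def efpfn(cc: ConfusionCounts) -> float:
    """Mean of the false-positive and false-negative rates."""
    if cc.tp + cc.fn == 0 or cc.tn + cc.fp == 0:
        raise ValueError("eFPFN undefined when a true class is empty")
    fpr = cc.fp / (cc.fp + cc.tn)
    fnr = cc.fn / (cc.fn + cc.tp)
    return 0.5 * (fpr + fnr)


@dataclasses.dataclass
class RocCurve:
    """Ordered (FPR, TPR) points from (0,0) to (1,1) and the trapezoidal AUC."""

    points: np.ndarray
    auc: float

    @property
    def fpr(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tpr(self) -> np.ndarray:
        return self.points[:, 1]


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> RocCurve:
    """ROC over all distinct score thresholds (tied scores move together),
    AUC by trapezoidal approximation; higher score = more poor-like."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    if not ((truth == 0).any() and (truth == 1).any()):
        raise ValueError("both classes must be present")
    if np.ptp(scores) == 0:
        logger.warning("constant scores; ROC degenerates to AUC 0.5")
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        return RocCurve(points=pts, auc=0.5)
    fpr, tpr, _ = _sk_roc_curve(truth, scores, drop_intermediate=False)
    pts = np.column_stack([fpr, tpr])
    return RocCurve(points=pts, auc=float(np.trapezoid(tpr, fpr)))


@dataclasses.dataclass
class LateRocCurve:
    """Joint-operating-point ROC for late integration.

    ``operating_points`` holds the N+1 (FPR, TPR) pairs in k order (k samples
    called poor by each view before fusing); ``points`` is the same set after
    lexicographic sorting and de-duplication, over which the trapezoidal AUC
    is computed.
    """

    operating_points: np.ndarray
    points: np.ndarray
    auc: float

    @property
    def fpr(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def tpr(self) -> np.ndarray:
        return self.points[:, 1]


def late_roc(rank_E: np.ndarray, rank_C: np.ndarray, truth: np.ndarray,
             op: str) -> LateRocCurve:
    """ROC restricted to operating points where both per-view classifiers
    call the same number k of samples poor (k = 0..N), fused by AND/OR."""
    rank_E = np.asarray(rank_E).astype(int)
    rank_C = np.asarray(rank_C).astype(int)
    truth = np.asarray(truth).astype(int)
    n = len(truth)
    if sorted(rank_E.tolist()) != list(range(n)) or \
            sorted(rank_C.tolist()) != list(range(n)):
        raise ValueError("rankings must be permutations of the same samples")
    if op not in ("AND", "OR"):
        raise ValueError("op must be 'AND' or 'OR'")
    n_pos = int(truth.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    in_E = np.zeros(n, dtype=bool)
    in_C = np.zeros(n, dtype=bool)
    ops = np.empty((n + 1, 2))
    ops[0] = (0.0, 0.0)
    for k in range(1, n + 1):
        in_E[rank_E[k - 1]] = True
        in_C[rank_C[k - 1]] = True
        poor = (in_E | in_C) if op == "OR" else (in_E & in_C)
        tp = int(np.sum(poor & (truth == 1)))
        fp = int(np.sum(poor & (truth == 0)))
        ops[k] = (fp / n_neg, tp / n_pos)
    pts = np.unique(ops, axis=0)  # sorts lexicographically by (FPR, TPR)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return LateRocCurve(operating_points=ops, points=pts, auc=auc)


@dataclasses.dataclass
class KmGroup:
    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    frac_at_horizon: float
    n: int


@dataclasses.dataclass
class KmCurve:
    groups: dict
    logrank_p: float | None
    horizon: float


def km_estimate(time: np.ndarray, event: np.ndarray, group: np.ndarray,
                horizon: float = 5.0) -> KmCurve:
    """Product-limit survival per group plus the two-group log-rank p and the
    survival fraction at the horizon (five years by default)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    group = np.asarray(group)
    names = [g for g in dict.fromkeys(group.tolist())]
    if any(np.sum(group == g) == 0 for g in names) or len(names) == 0:
        raise ValueError("every group must be non-empty")
    groups: dict = {}
    for g in names:
        sel = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event_observed=event[sel])
        timeline = kmf.survival_function_.index.to_numpy(dtype=float)
        survival = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
        groups[g] = KmGroup(
            timeline=timeline,
            survival=survival,
            at_risk=at_risk,
            frac_at_horizon=float(kmf.predict(horizon)),
            n=int(sel.sum()),
        )
    p = None
    if len(names) == 2:
        a = group == names[0]
        res = logrank_test(time[a], time[~a], event[a], event[~a])
        p = float(res.p_value)
    return KmCurve(groups=groups, logrank_p=p, horizon=horizon)
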