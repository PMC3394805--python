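"""Filter-based feature ranking: t-test for continuous features, chi-squared
for discrete ones, merged into a single ascending-p ordering."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CONTINUOUS, DISCRETE_KINDS

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RankedFeatures:
    order: np.ndarray       # permutation of column indices, best first
    p_values: np.ndarray    # per original column
    test_used: np.ndarray   # 't' or 'chi2' per original column


def pvalue_continuous(x: np.ndarray, label: np.ndarray) -> float:
    """Two-sided pooled-variance two-sample t-test p-value."""
    x = np.asarray(x, dtype=float)
    label = np.asarray(label)
    x1, x0 = x[label == 1], x[label == 0]
    if len(x1) < 2 or len(x0) < 2:
        logger.debug("t-test with a class of <2 samples; p=1")
        return 1.0
    p = stats.ttest_ind(x1, x0, equal_var=True).pvalue
    return 1.0 if np.isnan(p) else float(p)


def pvalue_discrete(x: np.ndarray, label: np.ndarray) -> float:
    """Pearson chi-squared p-value on the levels x class contingency table
    (no continuity correction)."""
    x = np.asarray(x)
    label = np.asarray(label)
    levels = np.unique(x)
    if len(levels) < 2:
        return 1.0
    table = np.array(
        [[np.sum((x == lv) & (label == c)) for c in (0, 1)] for lv in levels]
    )
    chi2 = stats.chi2_contingency(table, correction=False)
    return float(chi2.pvalue)


def rank_features(
    X: np.ndarray, meta: pd.DataFrame, label: np.ndarray
) -> RankedFeatures:
    """Rank all columns by ascending p-value; ties broken by column index."""
    X = np.asarray(X, dtype=float)
    label = np.asarray(label)
    kinds = meta["kind"].to_numpy()
    if len(kinds) != X.shape[1]:
        raise ValueError("meta does not cover all columns")
    p = np.ones(X.shape[1])
    test = np.empty(X.shape[1], dtype=object)
    cont = kinds == CONTINUOUS
    test[cont] = "t"
    disc = np.array([k in DISCRETE_KINDS for k in kinds])
    test[disc] = "chi2"
    if not (cont | disc).all():
        bad = set(kinds[~(cont | disc)])
        raise ValueError(f"unknown feature kinds: {bad}")
    if cont.any():
        x1 = X[label == 1][:, cont]
        x0 = X[label == 0][:, cont]
        if x1.shape[0] < 2 or x0.shape[0] < 2:
            logger.debug("t-test with a class of <2 samples; p=1 for all")
        else:
            pv = stats.ttest_ind(x1, x0, axis=0, equal_var=True).pvalue
            p[cont] = np.where(np.isnan(pv), 1.0, pv)
    for j in np.flatnonzero(disc):
        p[j] = pvalue_discrete(X[:, j], label)
    order = np.lexsort((np.arange(len(p)), p))
    return RankedFeatures(order=order, p_values=p, test_used=test)
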