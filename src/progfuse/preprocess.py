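"""Outcome dichotomization, nominal expansion, and per-feature normalization."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
ORDINAL = "ordinal"
BINARY = "binary"
NOMINAL = "nominal"
NOMINAL_DERIVED = "nominal-derived"
EXPRESSION_GROUP = "expression"

#: feature kinds routed to the chi-squared test / discrete likelihoods
DISCRETE_KINDS = frozenset({ORDINAL, BINARY, NOMINAL_DERIVED})


@dataclasses.dataclass(frozen=True)
class FeatureMeta:
    """Per-column metadata after nominal expansion."""

    name: str
    kind: str
    group: str
    source_variable: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {CONTINUOUS, ORDINAL, BINARY, NOMINAL_DERIVED}:
            raise ValueError(f"unknown feature kind {self.kind!r}")


def meta_frame(metas: list[FeatureMeta]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(m) for m in metas])


def expression_meta(gene_names: list[str]) -> pd.DataFrame:
    """Column metadata for an expression matrix (all continuous)."""
    return pd.DataFrame(
        {
            "name": gene_names,
            "kind": CONTINUOUS,
            "group": EXPRESSION_GROUP,
            "source_variable": None,
        }
    )


def dichotomize_outcome(
    survival_time: np.ndarray,
    event: np.ndarray,
    horizon: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign poor/good outcome labels from survival records.

    Poor: event before the horizon.  Good: follow-up (with or without a later
    event) reaching the horizon.  Samples censored before the horizon cannot
    be assigned and are excluded (mask False, label -1).
    """
    time = np.asarray(survival_time, dtype=float)
    event = np.asarray(event)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    label = np.full(time.shape, -1, dtype=int)
    poor = (event == 1) & (time < horizon)
    good = time >= horizon
    label[poor] = 1
    label[good] = 0
    included = poor | good
    return label, included


def expand_nominal(
    clinical: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One indicator column per level of each nominal variable.

    Non-nominal columns pass through unchanged.  Declared levels (from a
    ``levels`` column in ``meta``, comma-separated) that never occur in the
    data produce an all-zero indicator and a logged warning.
    """
    out_cols: dict[str, np.ndarray] = {}
    out_meta: list[dict[str, object]] = []
    for row in meta.itertuples(index=False):
        name, kind, group = row.name, row.kind, row.group
        values = clinical[name]
        if kind != NOMINAL:
            out_cols[name] = values.to_numpy(dtype=float)
            out_meta.append(
                {"name": name, "kind": kind, "group": group,
                 "source_variable": ""}
            )
            continue
        declared = getattr(row, "levels", "") or ""
        if str(declared).strip():
            levels = [float(x) for x in str(declared).split(",")]
        else:
            levels = sorted(values.unique().tolist())
        if len(values.unique()) < 2:
            raise ValueError(
                f"nominal variable {name!r} has fewer than 2 observed levels"
            )
        observed = set(values.unique().tolist())
        for lv in levels:
            col = f"{name}={lv:g}"
            out_cols[col] = (values.to_numpy(dtype=float) == lv).astype(float)
            if lv not in observed:
                logger.warning(
                    "declared level %s of nominal variable %s never observed; "
                    "indicator is all zeros", lv, name
                )
            out_meta.append(
                {"name": col, "kind": NOMINAL_DERIVED, "group": group,
                 "source_variable": name}
            )
    expanded = pd.DataFrame(out_cols, index=clinical.index)
    return expanded, pd.DataFrame(out_meta)


class Normalizer:
    """Per-feature mean/sd (n-1 estimator) fitted on one sample set and
    reapplied unchanged to held-out samples.  Zero-variance features map to
    zero (sd treated as 1)."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Normalizer":
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            raise ValueError("fitting set is empty")
        self.mean_ = X.mean(axis=0)
        if X.shape[0] > 1:
            sd = X.std(axis=0, ddof=1)
        else:
            sd = np.zeros(X.shape[1])
        degenerate = ~(sd > 0)
        if degenerate.any():
            logger.debug("%d zero-variance features mapped to zero",
                         int(degenerate.sum()))
        self.sd_ = np.where(degenerate, 1.0, sd)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Normalizer not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.sd_


def zscore_normalize(
    X: np.ndarray, fit_idx: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalize every row of ``X`` using statistics from rows ``fit_idx``
    (all rows when None).  Returns ``(X_normalized, mean, sd)``."""
    X = np.asarray(X, dtype=float)
    norm = Normalizer().fit(X if fit_idx is None else X[fit_idx])
    return norm.transform(X), norm.mean_, norm.sd_
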