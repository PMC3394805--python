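"""Synthetic breast-cancer-style cohorts with paired expression and clinical views.

The generator emulates the statistical structure that the integration
analysis assumes: a continuous expression block whose informative genes are
driven by a latent "proliferation-like" factor, a mixed-type clinical block
(continuous / ordinal / binary / nominal variables tagged with O/S/N groups)
whose informative variables share that factor with tunable correlation, an
optional clinical-only "matrix-formation-like" signal that is generatively
independent of every gene, ~30% poor-outcome prevalence, and survival records
supporting a five-year dichotomization with pre-horizon censoring.

Two outcome models are used:

* ``clinical_only_signal=False`` — a single Bernoulli poor/good label shifts
  both latent factors (the literal shared-signal model).
* ``clinical_only_signal=True`` — the poor label is the OR of two independent
  latent causes; genes and shared clinical features track cause 1, the
  matrix-like feature tracks cause 2.  Both views are informative about the
  outcome, yet the matrix-like feature has exactly zero generative
  correlation with every gene, which is the complementarity that late-OR
  fusion is meant to exploit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

POOR, GOOD = 1, 0

_GROUP_CYCLE = ("O", "S", "N")


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Effect sizes are standardized mean shifts (Cohen's d) of each informative
    feature with respect to its driving outcome cause; ``shared_signal_rho``
    is the correlation between the latent factor behind the informative genes
    and the one behind the grade-like informative clinical features.
    """

    n_samples: int = 300
    n_genes: int = 1000
    n_clinical_continuous: int = 10
    n_clinical_ordinal: int = 20
    n_clinical_binary: int = 13
    n_clinical_nominal: int = 2
    nominal_levels: tuple[int, ...] = (5, 6)
    prevalence_poor: float = 0.3
    effect_expression: float = 0.8
    effect_clinical: float = 0.8
    n_informative_genes: int = 120
    n_informative_clinical: int = 8
    shared_signal_rho: float = 0.5
    clinical_only_signal: bool = False
    clinical_only_prevalence: float = 0.12
    n_clinical_only_features: int = 4
    gene_factor_loading: float = 1.0
    clinical_factor_loading: float = 0.7071
    feature_skew: float = 1.4
    censor_rate_pre5y: float = 0.1
    horizon_years: float = 5.0
    informative_clinical_groups: tuple[str, ...] = ("O", "S")
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_genes": self.n_genes,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name in (
            "n_clinical_continuous",
            "n_clinical_ordinal",
            "n_clinical_binary",
            "n_clinical_nominal",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        levels = self.nominal_levels
        if isinstance(levels, int):
            levels = (levels,) * self.n_clinical_nominal
            object.__setattr__(self, "nominal_levels", levels)
        if len(levels) != self.n_clinical_nominal:
            raise ValueError(
                "nominal_levels must give one level count per nominal variable"
            )
        if any(lv < 2 for lv in levels):
            raise ValueError("each nominal variable needs >= 2 levels")
        if not 0.0 < self.prevalence_poor < 1.0:
            raise ValueError("prevalence_poor must lie in (0, 1)")
        if not 0.0 <= self.censor_rate_pre5y < 1.0:
            raise ValueError("censor_rate_pre5y must lie in [0, 1)")
        if self.effect_expression < 0 or self.effect_clinical < 0:
            raise ValueError("effect sizes must be >= 0")
        if not 0.0 <= self.shared_signal_rho <= 1.0:
            raise ValueError("shared_signal_rho must lie in [0, 1]")
        if self.clinical_only_signal and not (
            0.0 < self.clinical_only_prevalence < self.prevalence_poor
        ):
            raise ValueError(
                "clinical_only_prevalence must lie in (0, prevalence_poor)"
            )
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")
        if self.gene_factor_loading < 0 or self.clinical_factor_loading < 0:
            raise ValueError("factor loadings must be >= 0")
        if self.feature_skew < 0:
            raise ValueError("feature_skew must be >= 0")
        if self.clinical_only_signal and self.n_clinical_only_features < 1:
            raise ValueError("n_clinical_only_features must be >= 1")
        if self.n_informative_genes > self.n_genes:
            raise ValueError("n_informative_genes exceeds n_genes")
        slots = (
            self.n_clinical_continuous
            + self.n_clinical_ordinal
            + self.n_clinical_binary
        )
        if self.n_informative_clinical > slots:
            raise ValueError(
                "n_informative_clinical exceeds available continuous/ordinal/"
                "binary clinical slots"
            )


@dataclasses.dataclass
class Cohort:
    """A generated (or loaded) cohort: paired views plus ground truth."""

    expression: np.ndarray
    gene_names: list[str]
    clinical: pd.DataFrame
    clinical_meta: pd.DataFrame
    survival_time: np.ndarray
    event: np.ndarray
    truth_label: np.ndarray
    truth_informative_gene_idx: np.ndarray
    truth_informative_clinical_idx: np.ndarray
    config: CohortConfig | None = None

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    def validate(self) -> None:
        if self.expression.shape[0] != self.clinical.shape[0]:
            raise ValueError("expression and clinical row counts differ")
        if np.isnan(self.expression).any() or self.clinical.isna().any().any():
            raise ValueError("cohort contains missing values")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        if (self.survival_time <= 0).any():
            raise ValueError("survival times must be positive")


def _outcome_causes(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the poor label and its latent cause indicators.

    Returns ``(label, cause_shared, cause_clinical_only)`` as float arrays in
    {0, 1}.  Without the clinical-only signal, both causes coincide with the
    label itself.
    """
    n = config.n_samples
    if config.clinical_only_signal:
        # label = cause1 OR cause2 with P(poor) = prevalence_poor overall;
        # the proliferation-like cause dominates, the matrix-like cause adds
        # a smaller complementary poor group invisible to expression
        p2 = config.clinical_only_prevalence
        p1 = 1.0 - (1.0 - config.prevalence_poor) / (1.0 - p2)
        b1 = (rng.random(n) < p1).astype(float)
        b2 = (rng.random(n) < p2).astype(float)
        y = np.maximum(b1, b2)
    else:
        y = (rng.random(n) < config.prevalence_poor).astype(float)
        b1 = y
        b2 = np.zeros(n)
    return y, b1, b2


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a cohort deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    y, b1, b2 = _outcome_causes(config, rng)

    # Informative feature (latent scale) = class shift + factor loading +
    # unit idiosyncratic noise, with the raw shift scaled so the latent-scale
    # Cohen's d equals the config effect size.  Genes load the proliferation
    # factor fully (a tight co-expressed module); the grade-like clinical
    # scores load their factor partially (semi-redundant readouts).  The
    # monotone _skew transform then gives the continuous features the
    # heavy-right-tailed marginals of real expression intensities and
    # pathology scores; quantile-thresholded ordinal/binary variables are
    # unaffected by it.
    lam_g = config.gene_factor_loading
    lam_c = config.clinical_factor_loading
    shift_e = config.effect_expression * math.sqrt(1.0 + lam_g**2)
    shift_c = config.effect_clinical * math.sqrt(1.0 + lam_c**2)
    rho = config.shared_signal_rho
    e1 = rng.standard_normal(n)
    e2 = rho * e1 + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    z_prolif = lam_g * e1 + shift_e * (b1 - 0.5)
    z_clin = lam_c * e2 + shift_c * (b1 - 0.5)

    def _skew(v: np.ndarray) -> np.ndarray:
        k = config.feature_skew
        if k == 0:
            return v
        return np.expm1(k * v) / k

    expression = rng.standard_normal((n, config.n_genes))
    gene_perm = rng.permutation(config.n_genes)
    info_gene_idx = np.sort(gene_perm[: config.n_informative_genes])
    expression[:, info_gene_idx] = _skew(
        z_prolif[:, None] + expression[:, info_gene_idx]
    )
    gene_names = [f"g{j:05d}" for j in range(config.n_genes)]

    # clinical variables, in declared order: continuous, ordinal, binary, nominal
    kinds: list[tuple[str, str]] = []
    kinds += [(f"cont_{i:02d}", "continuous") for i in range(config.n_clinical_continuous)]
    kinds += [(f"ord_{i:02d}", "ordinal") for i in range(config.n_clinical_ordinal)]
    kinds += [(f"bin_{i:02d}", "binary") for i in range(config.n_clinical_binary)]
    kinds += [(f"nom_{i}", "nominal") for i in range(config.n_clinical_nominal)]

    # informative slots: continuous first, then ordinal, then binary
    slot_order = [i for i, (_, k) in enumerate(kinds) if k == "continuous"]
    slot_order += [i for i, (_, k) in enumerate(kinds) if k == "ordinal"]
    slot_order += [i for i, (_, k) in enumerate(kinds) if k == "binary"]
    informative = set(slot_order[: config.n_informative_clinical])

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict[str, object]] = []
    info_clin_idx: list[int] = []
    n_info_seen = 0
    n_noise_seen = 0
    nominal_i = 0
    for var_i, (name, kind) in enumerate(kinds):
        is_info = var_i in informative
        if is_info:
            group = config.informative_clinical_groups[
                n_info_seen % len(config.informative_clinical_groups)
            ]
            n_info_seen += 1
            info_clin_idx.append(var_i)
        else:
            group = _GROUP_CYCLE[n_noise_seen % len(_GROUP_CYCLE)]
            n_noise_seen += 1
        levels = ""
        if kind == "nominal":
            n_levels = config.nominal_levels[nominal_i]
            nominal_i += 1
            values = rng.integers(0, n_levels, size=n).astype(float)
            levels = ",".join(str(lv) for lv in range(n_levels))
        else:
            latent = rng.standard_normal(n)
            if is_info:
                latent = latent + z_clin
            if kind == "continuous":
                values = _skew(latent)
            elif kind == "ordinal":
                cuts = np.quantile(latent, [1 / 3, 2 / 3])
                values = np.digitize(latent, cuts).astype(float)
            else:  # binary
                values = (latent > np.median(latent)).astype(float)
        columns[name] = values
        meta_rows.append(
            {"name": name, "kind": kind, "group": group, "levels": levels}
        )

    if config.clinical_only_signal:
        # matrix-formation-like pathology block: redundant readouts of one
        # stromal process driven by the second outcome cause only, hence
        # generatively independent of every gene and every other clinical var
        shift_m = config.effect_clinical * math.sqrt(2.0)
        e3 = rng.standard_normal(n)
        z_matrix = e3 + shift_m * (b2 - 0.5)
        base_names = ["matrix_formation", "central_fibrosis", "fibrotic_focus"]
        for m in range(config.n_clinical_only_features):
            name = base_names[m] if m < len(base_names) else f"stromal_{m}"
            columns[name] = _skew(z_matrix + rng.standard_normal(n))
            meta_rows.append(
                {"name": name, "kind": "continuous", "group": "N",
                 "levels": ""}
            )
            info_clin_idx.append(len(meta_rows) - 1)

    sample_ids = [f"s{i:04d}" for i in range(n)]
    clinical = pd.DataFrame(columns, index=sample_ids)
    clinical_meta = pd.DataFrame(meta_rows)
    truth_label = y.astype(int)

    survival_time, event = generate_survival(truth_label, config, rng=rng)

    cohort = Cohort(
        expression=expression,
        gene_names=gene_names,
        clinical=clinical,
        clinical_meta=clinical_meta,
        survival_time=survival_time,
        event=event,
        truth_label=truth_label,
        truth_informative_gene_idx=info_gene_idx,
        truth_informative_clinical_idx=np.array(sorted(info_clin_idx)),
        config=config,
    )
    cohort.validate()
    return cohort


def generate_survival(
    truth_label: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Survival records consistent with the five-year dichotomization.

    Poor samples get an event strictly before the horizon; good samples get
    event-free follow-up beyond it.  Independently of the label, a fraction
    ``censor_rate_pre5y`` is converted to pre-horizon censored records, which
    the dichotomization rule must exclude.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 104729)
    truth_label = np.asarray(truth_label)
    n = truth_label.shape[0]
    h = config.horizon_years
    time = np.where(
        truth_label == POOR,
        rng.uniform(0.5, h, size=n),
        rng.uniform(h, h + 7.0, size=n),
    )
    event = np.where(truth_label == POOR, 1, 0)
    censored = rng.random(n) < config.censor_rate_pre5y
    time = np.where(censored, rng.uniform(0.5, h, size=n), time)
    event = np.where(censored, 0, event)
    return time, event.astype(int)


# ---------------------------------------------------------------------------
# TSV/JSON round trip (real-data mode reads the same layout)

def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Write expression.tsv, clinical.tsv, clinical_meta.tsv, survival.tsv
    and a truth.json ground-truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    expr = pd.DataFrame(
        cohort.expression, index=cohort.clinical.index, columns=cohort.gene_names
    )
    expr.to_csv(directory / "expression.tsv", sep="\t")
    cohort.clinical.to_csv(directory / "clinical.tsv", sep="\t")
    cohort.clinical_meta.to_csv(directory / "clinical_meta.tsv", sep="\t", index=False)
    surv = pd.DataFrame(
        {"time_years": cohort.survival_time, "event": cohort.event},
        index=cohort.clinical.index,
    )
    surv.to_csv(directory / "survival.tsv", sep="\t")
    truth = {
        "truth_label": cohort.truth_label.tolist(),
        "informative_gene_idx": cohort.truth_informative_gene_idx.tolist(),
        "informative_clinical_idx": cohort.truth_informative_clinical_idx.tolist(),
    }
    if cohort.config is not None:
        truth["config"] = dataclasses.asdict(cohort.config)
    (directory / "truth.json").write_text(json.dumps(truth, indent=1))


def read_cohort(directory: str | Path) -> Cohort:
    """Read the TSV trio (+ optional truth.json sidecar) back into a Cohort."""
    directory = Path(directory)
    expr = pd.read_csv(directory / "expression.tsv", sep="\t", index_col=0)
    clinical = pd.read_csv(directory / "clinical.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(
        directory / "clinical_meta.tsv", sep="\t", keep_default_na=False
    )
    surv = pd.read_csv(directory / "survival.tsv", sep="\t", index_col=0)
    truth_path = directory / "truth.json"
    config = None
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        label = np.asarray(truth["truth_label"], dtype=int)
        gene_idx = np.asarray(truth["informative_gene_idx"], dtype=int)
        clin_idx = np.asarray(truth["informative_clinical_idx"], dtype=int)
        if "config" in truth:
            raw = dict(truth["config"])
            raw["nominal_levels"] = tuple(raw["nominal_levels"])
            raw["informative_clinical_groups"] = tuple(
                raw["informative_clinical_groups"]
            )
            config = CohortConfig(**raw)
    else:
        logger.info("no truth.json in %s; real-data mode without ground truth",
                    directory)
        label = np.full(len(expr), -1, dtype=int)
        gene_idx = np.array([], dtype=int)
        clin_idx = np.array([], dtype=int)
    cohort = Cohort(
        expression=expr.to_numpy(dtype=float),
        gene_names=list(expr.columns),
        clinical=clinical,
        clinical_meta=meta,
        survival_time=surv["time_years"].to_numpy(dtype=float),
        event=surv["event"].to_numpy(dtype=int),
        truth_label=label,
        truth_informative_gene_idx=gene_idx,
        truth_informative_clinical_idx=clin_idx,
        config=config,
    )
    return cohort
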