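"""Cohort tables, preprocessing, and rule-set files.

A cohort is a plain CSV with a header, one subject per row: one binary
outcome column (0/1), optional subject-id column, and any number of numeric
predictor columns.  Missing values are empty cells or ``NA``/``NaN``.

Preprocessing mirrors the usual epidemiological workflow: drop predictors
that are mostly missing, then drop subjects that are mostly missing over the
remaining predictors (column pass first — the order matters and is fixed),
then impute what is left by nearest-neighbour averaging.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .rules import MinedRule, Rule, RuleMetrics

logger = logging.getLogger(__name__)

#: predictor kind labels
DICHOTOMOUS = "dichotomous"
ORDINAL = "ordinal"
CONTINUOUS = "continuous"

#: strings read as missing, besides empty cells
NA_TOKENS = ("NA", "NaN", "nan")

RULESET_SCHEMA_VERSION = 1


@dataclasses.dataclass
class Cohort:
    """Subjects-by-predictors table with a binary outcome.

    ``X`` is float with ``NaN`` marking missing entries (allowed only before
    imputation); ``y`` holds 0 ("negative") / 1 ("positive", e.g. the event
    occurred).
    """

    subject_ids: list[str]
    X: np.ndarray
    y: np.ndarray
    predictor_names: list[str]
    predictor_kinds: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, m = self.X.shape
        if n < 1 or m < 1:
            raise ValueError("cohort must have at least one subject and one predictor")
        if len(self.subject_ids) != n or len(self.y) != n:
            raise ValueError("subject_ids / y length does not match X")
        if len(self.predictor_names) != m or len(self.predictor_kinds) != m:
            raise ValueError("predictor metadata length does not match X")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("outcome must contain only 0/1")
        self.y = self.y.astype(np.int8)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def copy(self) -> "Cohort":
        return Cohort(
            list(self.subject_ids),
            self.X.copy(),
            self.y.copy(),
            list(self.predictor_names),
            list(self.predictor_kinds),
        )

    def select_predictors(self, indices: Sequence[int]) -> "Cohort":
        """New cohort keeping the given predictor columns, in the given order."""
        idx = list(indices)
        if not idx:
            raise ValueError("cannot select an empty predictor set")
        return Cohort(
            list(self.subject_ids),
            self.X[:, idx].copy(),
            self.y.copy(),
            [self.predictor_names[j] for j in idx],
            [self.predictor_kinds[j] for j in idx],
        )


def infer_kinds(X: np.ndarray) -> list[str]:
    """Infer predictor kinds from observed values.

    Exactly two distinct non-missing values → dichotomous; all-integer values
    → ordinal; anything else → continuous.  Downstream only the
    distinct-value count matters, so the ordinal/continuous split is
    informational.
    """
    kinds = []
    for j in range(X.shape[1]):
        col = X[:, j]
        obs = col[~np.isnan(col)]
        distinct = np.unique(obs)
        if distinct.size == 2:
            kinds.append(DICHOTOMOUS)
        elif distinct.size and np.all(distinct == np.round(distinct)):
            kinds.append(ORDINAL)
        else:
            kinds.append(CONTINUOUS)
    return kinds


def read_cohort(
    path: str | Path,
    outcome_column: str = "outcome",
    id_column: str | None = None,
) -> Cohort:
    """Read a cohort CSV.

    Raises ``ValueError`` on a missing/non-binary outcome column or an empty
    table.  Predictor kinds are inferred (see :func:`infer_kinds`).
    """
    frame = pd.read_csv(
        path, na_values=list(NA_TOKENS), keep_default_na=True, float_precision="round_trip"
    )
    if frame.empty:
        raise ValueError(f"{path}: empty cohort table")
    if outcome_column not in frame.columns:
        raise ValueError(f"{path}: outcome column {outcome_column!r} not found")

    y = pd.to_numeric(frame[outcome_column], errors="raise").to_numpy()
    if np.isnan(y).any() or not np.isin(y, (0, 1)).all():
        raise ValueError(f"{path}: outcome column must contain only 0/1")

    if id_column is not None:
        if id_column not in frame.columns:
            raise ValueError(f"{path}: id column {id_column!r} not found")
        subject_ids = frame[id_column].astype(str).tolist()
        predictors = frame.drop(columns=[outcome_column, id_column])
    else:
        subject_ids = [str(i) for i in range(len(frame))]
        predictors = frame.drop(columns=[outcome_column])
    if predictors.shape[1] == 0:
        raise ValueError(f"{path}: no predictor columns")

    X = predictors.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    return Cohort(subject_ids, X, y.astype(np.int8), list(predictors.columns), infer_kinds(X))


def write_cohort(
    cohort: Cohort,
    path: str | Path,
    outcome_column: str = "outcome",
    id_column: str = "subject_id",
) -> None:
    frame = pd.DataFrame(cohort.X, columns=cohort.predictor_names)
    frame.insert(0, outcome_column, cohort.y)
    frame.insert(0, id_column, cohort.subject_ids)
    frame.to_csv(path, index=False)


def filter_sparse(
    cohort: Cohort,
    max_missing_row: float = 0.3,
    max_missing_col: float = 0.3,
) -> Cohort:
    """Drop sparse predictors, then sparse subjects.

    Columns whose missing fraction exceeds ``max_missing_col`` are removed
    first; rows are then judged over the remaining columns against
    ``max_missing_row``.  Defaults (0.3/0.3) are configuration, not data
    facts.  Raises if nothing survives.
    """
    for frac in (max_missing_row, max_missing_col):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("missing-fraction thresholds must lie in [0, 1]")

    miss = np.isnan(cohort.X)
    col_frac = miss.mean(axis=0)
    keep_cols = np.flatnonzero(col_frac <= max_missing_col)
    if keep_cols.size == 0:
        raise ValueError("all predictors removed by sparsity filtering")

    X = cohort.X[:, keep_cols]
    row_frac = np.isnan(X).mean(axis=1)
    keep_rows = np.flatnonzero(row_frac <= max_missing_row)
    if keep_rows.size == 0:
        raise ValueError("all subjects removed by sparsity filtering")

    logger.info(
        "sparsity filter removed %d/%d predictors and %d/%d subjects",
        cohort.m - keep_cols.size, cohort.m, cohort.n - keep_rows.size, cohort.n,
    )
    return Cohort(
        [cohort.subject_ids[i] for i in keep_rows],
        X[keep_rows],
        cohort.y[keep_rows],
        [cohort.predictor_names[j] for j in keep_cols],
        [cohort.predictor_kinds[j] for j in keep_cols],
    )


def knn_impute(cohort: Cohort, k: int = 5) -> Cohort:
    """Fill missing cells by the mean of the k nearest subjects.

    Nearest neighbours are found by Euclidean distance over mutually observed
    predictors (the classic neighbour-mean imputation for expression-style
    tables); observed cells are left untouched.  ``k`` larger than n−1 is
    clamped with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    miss = np.isnan(cohort.X)
    if not miss.any():
        return cohort.copy()
    if miss.all(axis=0).any():
        bad = [cohort.predictor_names[j] for j in np.flatnonzero(miss.all(axis=0))]
        raise ValueError(f"predictors with zero observed values cannot be imputed: {bad}")
    if k > cohort.n - 1:
        logger.warning("k=%d exceeds n-1=%d; clamping", k, cohort.n - 1)
        k = cohort.n - 1

    from sklearn.impute import KNNImputer

    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    X = np.asarray(imputer.fit_transform(cohort.X), dtype=float)
    # imputer preserves observed cells; restore exact bit-identity regardless
    X[~miss] = cohort.X[~miss]
    out = cohort.copy()
    out.X = X
    return out


# ---------------------------------------------------------------------------
# Rule-set files
# ---------------------------------------------------------------------------

def write_rules(
    path: str | Path,
    rules: Sequence[MinedRule],
    scheme,
    metadata: dict | None = None,
) -> None:
    """Serialize mined rules (predicates + metrics + provenance) to JSON.

    ``scheme`` is the discretization scheme the rules were mined against; it
    supplies predictor names and human-readable level descriptions so the
    file is self-describing.
    """
    payload = {
        "schema_version": RULESET_SCHEMA_VERSION,
        "metadata": metadata or {},
        "rules": [
            {
                "predicates": [
                    {
                        "predictor": scheme.predictors[j].name,
                        "level": int(level),
                        "description": scheme.describe_level(j, level),
                    }
                    for j, level in mr.rule.predicates
                ],
                "metrics": {
                    "n_subjects": int(mr.metrics.n_subjects),
                    "n_pos": int(mr.metrics.n_pos),
                    "n_neg": int(mr.metrics.n_neg),
                    "tpr": None if np.isnan(mr.metrics.tpr) else float(mr.metrics.tpr),
                    "tnr": None if np.isnan(mr.metrics.tnr) else float(mr.metrics.tnr),
                    "accuracy": None if np.isnan(mr.metrics.accuracy) else float(mr.metrics.accuracy),
                },
                "problem": mr.problem,
                "run": int(mr.run),
            }
            for mr in rules
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_rules(path: str | Path, scheme) -> tuple[list[MinedRule], dict]:
    """Read a rule-set JSON written by :func:`write_rules`.

    Every predicate must reference an existing predictor of ``scheme`` and a
    valid level index.
    """
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != RULESET_SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported rule-set schema version")
    name_to_idx = {p.name: j for j, p in enumerate(scheme.predictors)}
    out: list[MinedRule] = []
    for entry in payload["rules"]:
        predicates = []
        for pred in entry["predicates"]:
            name = pred["predictor"]
            if name not in name_to_idx:
                raise ValueError(f"{path}: unknown predictor {name!r} in rule file")
            j = name_to_idx[name]
            level = int(pred["level"])
            if not 0 <= level < scheme.n_levels[j]:
                raise ValueError(f"{path}: invalid level {level} for predictor {name!r}")
            predicates.append((j, level))
        met = entry["metrics"]
        metrics = RuleMetrics(
            n_subjects=int(met["n_subjects"]),
            n_pos=int(met["n_pos"]),
            n_neg=int(met["n_neg"]),
            tpr=np.nan if met["tpr"] is None else float(met["tpr"]),
            tnr=np.nan if met["tnr"] is None else float(met["tnr"]),
            accuracy=np.nan if met["accuracy"] is None else float(met["accuracy"]),
        )
        out.append(MinedRule(Rule.from_pairs(predicates), metrics, entry["problem"], int(entry["run"])))
    return out, payload.get("metadata", {})
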