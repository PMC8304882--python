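"""Final-rule selection, subject categorization, and predictor importance.

From the pooled rule inventory the final set keeps rules that (1) cover at
least ``Supp`` subjects, (2) are balanced — |TPR − TNR| within a fraction γ of
max(TPR, TNR) — so they describe both outcome classes, and (3) have a covered
accuracy at or above α_easy (easy-case rules) or at or below α_diff
(difficult-case rules).  The final rules split the cohort into four
categories: *easy* (covered only by easy rules), *difficult* (only by
difficult rules), *ambiguous* (by both), and *non-covered* (by none).
Predictor importance counts, for every (predictor, level) predicate appearing
in a final rule, the unique easy/difficult/ambiguous subjects covered by
final rules containing that predicate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cv_engine import PerformanceProfile
from .discretize import DiscretizationScheme
from .rules import MinedRule, RuleEvaluator, describe

logger = logging.getLogger(__name__)

EASY = "easy"
DIFFICULT = "difficult"
AMBIGUOUS = "ambiguous"
NON_COVERED = "non_covered"
CATEGORIES = (EASY, DIFFICULT, AMBIGUOUS, NON_COVERED)


@dataclasses.dataclass
class SelectionCriteria:
    """Thresholds of the three final-rule criteria."""

    min_support: int = 30
    balance_gamma: float = 0.1
    acc_easy: float = 0.95
    acc_diff: float = 0.50

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.balance_gamma < 0:
            raise ValueError("balance_gamma must be >= 0")
        if not 0.0 < self.acc_diff < self.acc_easy < 1.0:
            raise ValueError("need 0 < acc_diff < acc_easy < 1")


def select_final_rules(
    pooled: Sequence[MinedRule], criteria: SelectionCriteria
) -> tuple[list[MinedRule], list[MinedRule]]:
    """Apply the three selection criteria; returns (easy_rules, difficult_rules).

    Rules with an undefined TPR or TNR cannot be balanced across classes and
    are excluded up front.  Rules in neither accuracy band are dropped.
    """
    easy: list[MinedRule] = []
    difficult: list[MinedRule] = []
    for mr in pooled:
        met = mr.metrics
        if met is None or np.isnan(met.tpr) or np.isnan(met.tnr):
            continue
        if met.n_subjects < criteria.min_support:
            continue
        if abs(met.tpr - met.tnr) > criteria.balance_gamma * max(met.tpr, met.tnr):
            continue
        if met.accuracy >= criteria.acc_easy:
            easy.append(mr)
        elif met.accuracy <= criteria.acc_diff:
            difficult.append(mr)
    if not easy:
        logger.warning("no rule met the easy-case criteria")
    if not difficult:
        logger.warning("no rule met the difficult-case criteria")
    logger.info("final rule set: %d easy, %d difficult", len(easy), len(difficult))
    return easy, difficult


@dataclasses.dataclass
class CategoryAssignment:
    """Per-subject category labels plus per-category profile aggregates."""

    subject_ids: list[str]
    labels: np.ndarray  # strings from CATEGORIES
    y: np.ndarray
    summary: pd.DataFrame  # per category: counts by outcome, accuracy, tpr, tnr
    coverage_easy: np.ndarray  # (n, n_easy_rules) bool
    coverage_difficult: np.ndarray  # (n, n_difficult_rules) bool

    def counts(self) -> dict[str, int]:
        return {c: int((self.labels == c).sum()) for c in CATEGORIES}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids, "y": self.y, "category": self.labels})


def _aggregate(mask: np.ndarray, profile: PerformanceProfile) -> dict[str, float]:
    pos = mask & (profile.y == 1)
    neg = mask & (profile.y == 0)
    tp, fn = profile.tp[pos].sum(), profile.fn[pos].sum()
    tn, fp = profile.tn[neg].sum(), profile.fp[neg].sum()
    total = profile.n_predictions[mask].sum()
    return {
        "n": int(mask.sum()),
        "n_pos": int(pos.sum()),
        "n_neg": int(neg.sum()),
        "accuracy": float((tp + tn) / total) if total else float("nan"),
        "tpr": float(tp / (tp + fn)) if (tp + fn) else float("nan"),
        "tnr": float(tn / (tn + fp)) if (tn + fp) else float("nan"),
        "accuracy_pos": float(tp / (tp + fn)) if (tp + fn) else float("nan"),
        "accuracy_neg": float(tn / (tn + fp)) if (tn + fp) else float("nan"),
    }


def categorize(
    level_matrix: np.ndarray,
    easy_rules: Sequence[MinedRule],
    difficult_rules: Sequence[MinedRule],
    profile: PerformanceProfile,
) -> CategoryAssignment:
    """Assign every subject to easy / difficult / ambiguous / non-covered."""
    n = level_matrix.shape[0]
    evaluator = RuleEvaluator(level_matrix, profile.y, profile)
    cov_easy = np.zeros((n, len(easy_rules)), dtype=bool)
    for k, mr in enumerate(easy_rules):
        cov_easy[:, k] = evaluator.coverage(mr.rule)
    cov_diff = np.zeros((n, len(difficult_rules)), dtype=bool)
    for k, mr in enumerate(difficult_rules):
        cov_diff[:, k] = evaluator.coverage(mr.rule)

    any_easy = cov_easy.any(axis=1)
    any_diff = cov_diff.any(axis=1)
    labels = np.full(n, NON_COVERED, dtype=object)
    labels[any_easy & ~any_diff] = EASY
    labels[any_diff & ~any_easy] = DIFFICULT
    labels[any_easy & any_diff] = AMBIGUOUS

    rows = {c: _aggregate(labels == c, profile) for c in CATEGORIES}
    rows["whole_sample"] = _aggregate(np.ones(n, dtype=bool), profile)
    summary = pd.DataFrame(rows).T

    return CategoryAssignment(
        subject_ids=list(profile.subject_ids),
        labels=labels,
        y=profile.y.copy(),
        summary=summary,
        coverage_easy=cov_easy,
        coverage_difficult=cov_diff,
    )


def predictor_importance(
    easy_rules: Sequence[MinedRule],
    difficult_rules: Sequence[MinedRule],
    assignment: CategoryAssignment,
    scheme: DiscretizationScheme,
) -> pd.DataFrame:
    """Unique covered subjects per (predictor, level) predicate, by category.

    For each predicate appearing in any final rule: the union of subjects
    covered by final rules containing that predicate, intersected with the
    easy / difficult / ambiguous categories (no double counting across
    rules).  Sorted by total; percentages are of the whole cohort.
    """
    n = len(assignment.labels)
    coverage = {}
    tagged = [(mr, assignment.coverage_easy[:, k]) for k, mr in enumerate(easy_rules)]
    tagged += [(mr, assignment.coverage_difficult[:, k]) for k, mr in enumerate(difficult_rules)]
    for mr, cov in tagged:
        for pred in mr.rule.predicates:
            if pred in coverage:
                coverage[pred] = coverage[pred] | cov
            else:
                coverage[pred] = cov.copy()

    records = []
    for (j, level), cov in coverage.items():
        row = {
            "predictor": scheme.predictors[j].name,
            "level": level,
            "description": scheme.describe_level(j, level),
        }
        total = 0
        for cat in (EASY, DIFFICULT, AMBIGUOUS):
            count = int((cov & (assignment.labels == cat)).sum())
            row[f"n_{cat}"] = count
            row[f"pct_{cat}"] = 100.0 * count / n
            total += count
        row["n_total"] = total
        records.append(row)
    frame = pd.DataFrame.from_records(records)
    if len(frame):
        frame = frame.sort_values("n_total", ascending=False, kind="mergesort").reset_index(drop=True)
    return frame


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def rule_space_coordinates(
    assignment: CategoryAssignment, seed: int = 0, perplexity: float = 30.0
) -> pd.DataFrame:
    """Optional 2-D t-SNE embedding of subjects in rule-coverage space.

    Each covered subject is a binary vector over the final rules; the
    embedding itself is delegated to scikit-learn and is presentation only.
    """
    from sklearn.manifold import TSNE

    covered = assignment.labels != NON_COVERED
    vectors = np.hstack([assignment.coverage_easy, assignment.coverage_difficult])[covered]
    perplexity = min(perplexity, max(2.0, (covered.sum() - 1) / 3.0))
    coords = TSNE(n_components=2, random_state=seed, perplexity=perplexity).fit_transform(
        vectors.astype(float)
    )
    return pd.DataFrame(
        {
            "subject_id": np.array(assignment.subject_ids, dtype=object)[covered],
            "category": assignment.labels[covered],
            "x": coords[:, 0],
            "y": coords[:, 1],
        }
    )


def write_report(
    outdir: str | Path,
    easy_rules: Sequence[MinedRule],
    difficult_rules: Sequence[MinedRule],
    assignment: CategoryAssignment,
    importance: pd.DataFrame,
    scheme: DiscretizationScheme,
) -> None:
    """Write the JSON + Markdown report bundle into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    summary = assignment.summary.reset_index(names="category")
    payload = {
        "n_easy_rules": len(easy_rules),
        "n_difficult_rules": len(difficult_rules),
        "category_counts": assignment.counts(),
        "category_summary": json.loads(summary.to_json(orient="records")),
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=1))
    assignment.to_frame().to_csv(outdir / "categories.csv", index=False)
    importance.to_csv(outdir / "importance.csv", index=False)

    lines = ["# Post-analysis report", "", "## Subject categories", ""]
    lines += ["```", summary.to_string(index=False, float_format=lambda v: f"{v:.4f}"), "```"]
    lines += ["", f"## Easy-case rules ({len(easy_rules)})", ""]
    for mr in easy_rules:
        met = mr.metrics
        lines.append(
            f"- {describe(mr.rule, scheme)}  —  n={met.n_subjects}, "
            f"TPR={met.tpr:.3f}, TNR={met.tnr:.3f}, accuracy={met.accuracy:.3f}"
        )
    lines += ["", f"## Difficult-case rules ({len(difficult_rules)})", ""]
    for mr in difficult_rules:
        met = mr.metrics
        lines.append(
            f"- {describe(mr.rule, scheme)}  —  n={met.n_subjects}, "
            f"TPR={met.tpr:.3f}, TNR={met.tnr:.3f}, accuracy={met.accuracy:.3f}"
        )
    lines += ["", "## Predictor importance (unique covered subjects per predicate)", ""]
    if len(importance):
        lines += ["```", importance.head(50).to_string(index=False), "```"]
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
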