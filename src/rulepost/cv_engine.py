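"""Lasso logistic regression under repeated stratified k-fold CV.

The reference model is an L1-penalized logistic regression minimizing

    ||w||_1 + C * sum_i log(1 + exp(-y_i * (w . x_i + w0)))        (y_i in {-1,+1})

with C = 0.15 by default — note C multiplies the loss, so the penalty grows
as C shrinks.  This is exactly scikit-learn's C-parameterization of
``LogisticRegression(penalty="l1")``, to which the convex solve is delegated
(solver ``saga``, which leaves the intercept unpenalized as the objective
requires).  Predictors are min-max scaled to (0, 1) with the scaler fitted on
the training folds only; test values are clipped to [0, 1].

A subject is classified positive when the predicted probability reaches the
cutoff α, defined as the positive-class proportion of the training sample
(0.5 for a balanced sample); the boundary P = α classifies positive.

Repeated stratified k-fold CV (default 50 runs × 5 folds) accumulates, per
subject, how often its test-fold predictions were correct or wrong: TP/FN
tallies for positives, TN/FP for negatives.  This per-subject performance
profile — not the model — is what the rule-mining stages consume, so any
external model's tallies can be substituted (the tool is model-independent).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler

from .data_io import Cohort

logger = logging.getLogger(__name__)

#: coefficients with absolute value above this count as "selected"
NONZERO_TOL = 1e-10


@dataclasses.dataclass
class ModelConfig:
    """Settings of the reference model and the repeated-CV protocol."""

    shrinkage_c: float = 0.15
    n_runs: int = 50
    n_folds: int = 5
    base_seed: int = 0
    max_iter: int = 20_000
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.shrinkage_c <= 0:
            raise ValueError("shrinkage_c must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclasses.dataclass
class PerformanceProfile:
    """Per-subject prediction tallies accumulated over repeated CV.

    For positives (y=1): ``tp + fn = n_predictions`` and ``tn = fp = 0``;
    symmetric for negatives.  ``selected_predictors`` collects the indices of
    predictors with a nonzero coefficient in at least one fitted model.
    """

    subject_ids: list[str]
    y: np.ndarray
    tp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    n_predictions: np.ndarray
    selected_predictors: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        for name in ("tp", "fn", "tn", "fp", "n_predictions"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        pos = self.y == 1
        if not np.array_equal(self.tp[pos] + self.fn[pos], self.n_predictions[pos]):
            raise ValueError("tp + fn must equal n_predictions for positives")
        if not np.array_equal(self.tn[~pos] + self.fp[~pos], self.n_predictions[~pos]):
            raise ValueError("tn + fp must equal n_predictions for negatives")
        if self.tn[pos].any() or self.fp[pos].any() or self.tp[~pos].any() or self.fn[~pos].any():
            raise ValueError("tallies of the wrong class must be zero")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_correct(self) -> np.ndarray:
        return self.tp + self.tn

    @property
    def accuracy(self) -> float:
        return float(self.n_correct.sum() / self.n_predictions.sum())

    @property
    def tpr(self) -> float:
        pos = self.y == 1
        return float(self.tp[pos].sum() / self.n_predictions[pos].sum())

    @property
    def tnr(self) -> float:
        neg = self.y == 0
        return float(self.tn[neg].sum() / self.n_predictions[neg].sum())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "y": self.y,
                "n_correct": self.n_correct,
                "n_wrong": self.fn + self.fp,
                "tp": self.tp,
                "fn": self.fn,
                "tn": self.tn,
                "fp": self.fp,
                "n_predictions": self.n_predictions,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PerformanceProfile":
        frame = pd.read_csv(path)
        required = {"subject_id", "y", "tp", "fn", "tn", "fp", "n_predictions"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: profile file lacks columns {sorted(missing)}")
        return cls(
            subject_ids=frame["subject_id"].astype(str).tolist(),
            y=frame["y"].to_numpy(),
            tp=frame["tp"].to_numpy(),
            fn=frame["fn"].to_numpy(),
            tn=frame["tn"].to_numpy(),
            fp=frame["fp"].to_numpy(),
            n_predictions=frame["n_predictions"].to_numpy(),
        )


@dataclasses.dataclass
class FittedModel:
    """Coefficients plus the training-fold min-max scaler."""

    coef: np.ndarray
    intercept: float
    scaler: MinMaxScaler

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xs = np.clip(self.scaler.transform(X), 0.0, 1.0)
        z = Xs @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, X: np.ndarray, alpha: float) -> np.ndarray:
        return predict(self, X, alpha)


def fit_cutoff(y_train: np.ndarray) -> float:
    """Classification cutoff α = proportion of positives in the training sample."""
    y_train = np.asarray(y_train)
    if not np.isin(y_train, (0, 1)).all():
        raise ValueError("y_train must be 0/1")
    alpha = float(y_train.mean())
    if alpha in (0.0, 1.0):
        raise ValueError("y_train must contain both classes")
    return alpha


def l1_logistic_objective(
    coef: np.ndarray, intercept: float, X: np.ndarray, y01: np.ndarray, C: float
) -> float:
    """Value of ||w||_1 + C * Σ log(1 + exp(-y(w·x + w0))) with y mapped to ±1."""
    s = np.where(np.asarray(y01) == 1, 1.0, -1.0)
    z = s * (X @ coef + intercept)
    # stable log(1 + exp(-z))
    loss = np.logaddexp(0.0, -z).sum()
    return float(np.abs(coef).sum() + C * loss)


def fit_model(
    X_train: np.ndarray,
    y_train: np.ndarray,
    C: float = 0.15,
    seed: int = 0,
    max_iter: int = 20_000,
    tol: float = 1e-8,
) -> FittedModel:
    """Fit the L1-penalized logistic regression on min-max scaled predictors.

    The solver is liblinear with a large ``intercept_scaling`` so the
    intercept is effectively unpenalized, as the objective requires (the
    residual intercept penalty is |w0|/1000, negligible against the solver
    tolerance).  Non-convergence is surfaced as a logged warning with
    diagnostics rather than silently accepted.
    """
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("training outcome must contain both classes")
    if np.isnan(X_train).any():
        raise ValueError("X_train must be fully observed")

    scaler = MinMaxScaler().fit(X_train)
    Xs = scaler.transform(X_train)
    clf = LogisticRegression(
        C=C, l1_ratio=1.0, solver="liblinear", intercept_scaling=1000.0,
        max_iter=max_iter, tol=tol, random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(Xs, y_train)
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            logger.warning(
                "solver did not converge (n=%d, m=%d, C=%g, max_iter=%d, tol=%g): %s",
                *Xs.shape, C, max_iter, tol, w.message,
            )
    return FittedModel(coef=clf.coef_.ravel().copy(), intercept=float(clf.intercept_[0]), scaler=scaler)


def predict(model: FittedModel, X_test: np.ndarray, alpha: float) -> np.ndarray:
    """Binary predictions: positive iff P(y=1|x) >= α (ties positive)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return (model.predict_proba(X_test) >= alpha).astype(np.int8)


def run_repeated_cv(cohort: Cohort, config: ModelConfig | None = None) -> PerformanceProfile:
    """Accumulate per-subject tallies over repeated stratified k-fold CV.

    Run r uses a stratified shuffled k-fold partition seeded ``base_seed + r``;
    every fold fits scaler + model on the training folds, takes α from the
    training outcome, predicts the test fold and increments each test
    subject's tally.  Coefficients with |w| > 1e-10 in any fitted model are
    unioned into ``selected_predictors``.
    """
    config = config or ModelConfig()
    y = cohort.y
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.n_folds:
        raise ValueError(
            f"stratified {config.n_folds}-fold CV needs >= {config.n_folds} subjects per class "
            f"(have {counts.tolist()})"
        )
    if np.isnan(cohort.X).any():
        raise ValueError("repeated CV requires a fully observed cohort (impute first)")

    n = cohort.n
    tp = np.zeros(n, dtype=np.int64)
    fn = np.zeros(n, dtype=np.int64)
    tn = np.zeros(n, dtype=np.int64)
    fp = np.zeros(n, dtype=np.int64)
    n_predictions = np.zeros(n, dtype=np.int64)
    selected: set[int] = set()

    for r in range(config.n_runs):
        seed = config.base_seed + r
        splitter = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=seed)
        for train_idx, test_idx in splitter.split(cohort.X, y):
            model = fit_model(
                cohort.X[train_idx], y[train_idx], C=config.shrinkage_c,
                seed=seed, max_iter=config.max_iter, tol=config.tol,
            )
            alpha = fit_cutoff(y[train_idx])
            pred = predict(model, cohort.X[test_idx], alpha)
            truth = y[test_idx]
            n_predictions[test_idx] += 1
            tp[test_idx] += (truth == 1) & (pred == 1)
            fn[test_idx] += (truth == 1) & (pred == 0)
            tn[test_idx] += (truth == 0) & (pred == 0)
            fp[test_idx] += (truth == 0) & (pred == 1)
            selected.update(np.flatnonzero(np.abs(model.coef) > NONZERO_TOL).tolist())

    logger.info(
        "repeated CV done: %d runs x %d folds, accuracy %.4f, %d/%d predictors selected",
        config.n_runs, config.n_folds,
        (tp + tn).sum() / n_predictions.sum(), len(selected), cohort.m,
    )
    return PerformanceProfile(
        subject_ids=list(cohort.subject_ids),
        y=y.copy(),
        tp=tp, fn=fn, tn=tn, fp=fp,
        n_predictions=n_predictions,
        selected_predictors=frozenset(selected),
    )


def filter_selected_predictors(cohort: Cohort, profile: PerformanceProfile) -> Cohort:
    """Keep only predictors the model selected in at least one fitted run."""
    if not profile.selected_predictors:
        raise ValueError("no predictor was ever selected; nothing to keep")
    keep = sorted(profile.selected_predictors)
    if keep[-1] >= cohort.m:
        raise ValueError("profile references predictors beyond this cohort")
    return cohort.select_predictors(keep)
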