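"""Synthetic cohorts with known structure.

The generator emulates a tabular epidemiological dataset: a binary outcome
with class imbalance (default positive fraction 0.26), a mix of dichotomous,
low-cardinality ordinal, and continuous predictors, an optional logistic
signal linking predictors to the outcome, and optional *planted subgroups* —
subject sets defined by predictor-value predicates whose per-subject model
accuracy is forced to a chosen target.  Planted subgroups make every mining
stage testable without any real model: :func:`generate_profile` fabricates a
per-subject CV performance profile directly, with each subject's correct
predictions drawn Binomial(n_runs, target accuracy of its subgroup), baseline
0.72 elsewhere — roughly the operating point of a mid-quality clinical risk
model.

Per-subject correctness is i.i.d. across runs here, a simplification of real
CV dependence (real tallies are correlated through shared training folds);
it is adequate for exercising the rule-mining stages.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .cv_engine import PerformanceProfile
from .data_io import Cohort, infer_kinds

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PlantedSubgroup:
    """Subjects matching all (predictor index, raw value) predicates.

    Use value-coded (dichotomous / low-cardinality) predictors so the planted
    definition survives discretization unchanged.
    """

    predicates: list[tuple[int, float]]
    target_accuracy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_accuracy <= 1.0:
            raise ValueError("target accuracy must lie in [0, 1]")

    def mask(self, cohort: Cohort) -> np.ndarray:
        covered = np.ones(cohort.n, dtype=bool)
        for j, value in self.predicates:
            covered &= cohort.X[:, j] == value
        return covered


@dataclasses.dataclass
class SyntheticSpec:
    """Recipe for a synthetic cohort.

    ``signal_effects`` maps predictor index → log-odds coefficient (applied
    to the standardized predictor); the intercept is calibrated so the mean
    event probability equals ``positive_fraction``.  The predictor mix
    defaults to 60% dichotomous, 20% low-cardinality ordinal (3–6 values),
    20% continuous.
    """

    n: int
    m: int
    positive_fraction: float = 0.26
    n_dichotomous: int | None = None
    n_lowcard: int | None = None
    n_continuous: int | None = None
    signal_effects: dict[int, float] = dataclasses.field(default_factory=dict)
    planted_subgroups: list[PlantedSubgroup] = dataclasses.field(default_factory=list)
    baseline_accuracy: float = 0.72
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1:
            raise ValueError("n and m must be positive")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if not 0.0 <= self.baseline_accuracy <= 1.0:
            raise ValueError("baseline_accuracy must lie in [0, 1]")
        if self.n_dichotomous is None:
            self.n_dichotomous = int(round(0.6 * self.m))
        if self.n_lowcard is None:
            self.n_lowcard = int(round(0.2 * self.m))
        if self.n_continuous is None:
            self.n_continuous = self.m - self.n_dichotomous - self.n_lowcard
        if self.n_dichotomous + self.n_lowcard + self.n_continuous != self.m:
            raise ValueError("predictor mix must sum to m")
        for j in self.signal_effects:
            if not 0 <= j < self.m:
                raise ValueError(f"signal predictor index {j} out of range")
        for sg in self.planted_subgroups:
            for j, _ in sg.predicates:
                if not 0 <= j < self.m:
                    raise ValueError(f"planted predicate references predictor {j} out of range")


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Draw a cohort per the spec; deterministic under the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n, spec.m
    X = np.empty((n, m))
    col = 0
    for _ in range(spec.n_dichotomous):
        p = rng.uniform(0.2, 0.8)
        X[:, col] = rng.random(n) < p
        col += 1
    for _ in range(spec.n_lowcard):
        k = int(rng.integers(3, 7))
        X[:, col] = rng.integers(0, k, size=n)
        col += 1
    for _ in range(spec.n_continuous):
        mu = rng.uniform(-2.0, 2.0)
        sd = rng.uniform(0.5, 2.0)
        X[:, col] = rng.normal(mu, sd, size=n)
        col += 1

    score = np.zeros(n)
    for j, beta in spec.signal_effects.items():
        z = X[:, j]
        sd = z.std()
        score += beta * ((z - z.mean()) / sd if sd > 0 else 0.0)

    # calibrate the intercept so the mean event probability hits the target
    def mean_prob(b0: float) -> float:
        return float(expit(b0 + score).mean())

    try:
        b0 = brentq(lambda b: mean_prob(b) - spec.positive_fraction, -30.0, 30.0)
    except ValueError:
        b0 = 0.0
        logger.warning(
            "intercept calibration infeasible; achieved positive fraction %.3f "
            "(target %.3f)", mean_prob(b0), spec.positive_fraction,
        )
    y = (rng.random(n) < expit(b0 + score)).astype(np.int8)

    names = [f"p{j:03d}" for j in range(m)]
    ids = [f"s{i:04d}" for i in range(n)]
    return Cohort(ids, X, y, names, infer_kinds(X))


def generate_profile(
    cohort: Cohort, spec: SyntheticSpec, n_runs: int = 50
) -> PerformanceProfile:
    """Fabricate a per-subject CV profile with planted accuracy structure.

    Each subject's target accuracy is that of the first planted subgroup it
    matches (first match wins), else the baseline; its correct-prediction
    count is Binomial(n_runs, target).  Tallies land in TP/FN or TN/FP
    according to the subject's outcome.  All predictors are marked selected.
    """
    rng = np.random.default_rng(spec.seed + 1)
    target = np.full(cohort.n, spec.baseline_accuracy)
    unassigned = np.ones(cohort.n, dtype=bool)
    for sg in spec.planted_subgroups:
        members = sg.mask(cohort) & unassigned
        target[members] = sg.target_accuracy
        unassigned &= ~members

    correct = rng.binomial(n_runs, target)
    wrong = n_runs - correct
    pos = cohort.y == 1
    tp = np.where(pos, correct, 0)
    fn = np.where(pos, wrong, 0)
    tn = np.where(~pos, correct, 0)
    fp = np.where(~pos, wrong, 0)
    return PerformanceProfile(
        subject_ids=list(cohort.subject_ids),
        y=cohort.y.copy(),
        tp=tp, fn=fn, tn=tn, fp=fp,
        n_predictions=np.full(cohort.n, n_runs, dtype=np.int64),
        selected_predictors=frozenset(range(cohort.m)),
    )
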