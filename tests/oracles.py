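"""Independent oracles used by the tests.

Everything here is deliberately naive (per-subject Python loops, exhaustive
enumeration, O(R^2) domination filtering) and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from rulepost import PerformanceProfile


def make_profile(y, correct, n_runs):
    """Profile from per-subject correct-prediction counts."""
    y = np.asarray(y, dtype=np.int8)
    correct = np.asarray(correct, dtype=np.int64)
    wrong = n_runs - correct
    return PerformanceProfile(
        subject_ids=[str(i) for i in range(len(y))],
        y=y,
        tp=np.where(y == 1, correct, 0),
        fn=np.where(y == 1, wrong, 0),
        tn=np.where(y == 0, correct, 0),
        fp=np.where(y == 0, wrong, 0),
        n_predictions=np.full(len(y), n_runs, dtype=np.int64),
    )


def naive_metrics(predicates, levels, y, profile):
    """Per-subject loop evaluation of a rule; returns the same fields as
    RuleMetrics with NaN for undefined rates."""
    tp = fn = tn = fp = 0
    n_pos = n_neg = 0
    total = 0
    for i in range(len(y)):
        if all(levels[i][j] == a for j, a in predicates):
            total += profile.n_predictions[i]
            if y[i] == 1:
                n_pos += 1
                tp += profile.tp[i]
                fn += profile.fn[i]
            else:
                n_neg += 1
                tn += profile.tn[i]
                fp += profile.fp[i]
    tpr = tp / (tp + fn) if n_pos else math.nan
    tnr = tn / (tn + fp) if n_neg else math.nan
    acc = (tp + tn) / total if total else math.nan
    return n_pos + n_neg, n_pos, n_neg, tpr, tnr, acc


def naive_objectives(predicates, levels, y, profile, problem):
    """Naive minimization objectives with the problem-worst sentinel for
    undefined rates."""
    _, n_pos, n_neg, tpr, tnr, _ = naive_metrics(predicates, levels, y, profile)
    worst = 0.0 if problem == "easy" else 1.0
    tpr = worst if math.isnan(tpr) else tpr
    tnr = worst if math.isnan(tnr) else tnr
    cov = float(n_pos + n_neg)
    if problem == "easy":
        return (-tpr, -tnr, -cov)
    return (tpr, tnr, -cov)


def enumerate_rules(n_levels):
    """All non-empty rules over value-coded predictors with the given level counts."""
    m = len(n_levels)
    out = []
    for r in range(1, m + 1):
        for j_set in itertools.combinations(range(m), r):
            for combo in itertools.product(*[range(n_levels[j]) for j in j_set]):
                out.append(tuple(zip(j_set, combo)))
    return out


def pareto_front_vectors(F, decimals=12):
    """Set of nondominated objective vectors (minimization), by double loop."""
    F = np.asarray(F, dtype=float)
    front = set()
    for i in range(len(F)):
        dominated = False
        for k in range(len(F)):
            if k != i and np.all(F[k] <= F[i]) and np.any(F[k] < F[i]):
                dominated = True
                break
        if not dominated:
            front.add(tuple(np.round(F[i], decimals)))
    return front
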