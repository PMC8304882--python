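"""NSGA-III search for easy-case and difficult-case rules.

Two three-objective problems are solved over the Gray-coded rule space:

* easy cases:      maximize TPR(rule), TNR(rule), Nsubjects(rule)
* difficult cases: minimize TPR(rule), TNR(rule); maximize Nsubjects(rule)

Internally everything is minimized; maximized objectives are negated.  A rule
with an undefined TPR/TNR (no covered positives/negatives) receives the worst
value for the problem at hand, and a rule with no predicates is worst on all
three objectives, so neither is ever favored by selection.

The optimizer is the reference-point based many-objective NSGA-III:
nondominated sorting, binary tournament on nondomination rank, half-uniform
crossover (exchanges exactly half of the differing bits), per-bit flip
mutation, and environmental selection that niches the last admitted front
against a Das–Dennis simplex lattice of reference points.  The search is run
several times with different seeds and the final populations are pooled and
deduplicated, which is how the whole rule inventory is produced.
"""

from __future__ import annotations

import dataclasses
import logging
from math import comb
from typing import Callable

import numpy as np

from .discretize import DiscretizationScheme
from .rules import (
    MinedRule,
    Rule,
    RuleEvaluator,
    RuleMetrics,
    chromosome_length,
    decode_segments,
    encode,
    segment_offsets,
)

logger = logging.getLogger(__name__)

PROBLEM_EASY = "easy"
PROBLEM_DIFFICULT = "difficult"

N_OBJECTIVES = 3


def das_dennis_points(m: int, p: int) -> np.ndarray:
    """Das–Dennis simplex-lattice reference points.

    All points with coordinates in {0, 1/p, ..., p/p} summing to 1; there are
    C(m+p-1, p) of them.  By the convention used here a layer with p = 0
    contributes no points (so outer divisions 20 + inner divisions 0 for
    three objectives gives exactly 231 points).
    """
    if m < 2:
        raise ValueError("need at least 2 objectives")
    if p < 0:
        raise ValueError("divisions must be >= 0")
    if p == 0:
        return np.empty((0, m))
    points: list[list[int]] = []

    def rec(prefix: list[int], remaining: int, slots: int) -> None:
        if slots == 1:
            points.append(prefix + [remaining])
            return
        for v in range(remaining + 1):
            rec(prefix + [v], remaining - v, slots - 1)

    rec([], p, m)
    pts = np.array(points, dtype=float) / p
    assert len(pts) == comb(m + p - 1, p)
    return pts


def population_size_for(h: int) -> int:
    """Smallest multiple of four strictly greater than the reference-point count."""
    if h < 1:
        raise ValueError("reference-point count must be >= 1")
    return (h // 4 + 1) * 4


@dataclasses.dataclass
class SearchConfig:
    """NSGA-III settings; defaults follow the published configuration."""

    n_objectives: int = N_OBJECTIVES
    outer_divisions: int = 20
    inner_divisions: int = 0
    population_size: int | None = None  # derived from the reference points if None
    generations: int = 200
    n_runs: int = 25
    tournament_size: int = 2
    crossover_prob: float = 1.0
    mutation_prob: float | None = None  # 1 / chromosome length if None
    init_inclusion_prob: float = 0.05
    seed: int = 0

    def reference_points(self) -> np.ndarray:
        outer = das_dennis_points(self.n_objectives, self.outer_divisions)
        inner = das_dennis_points(self.n_objectives, self.inner_divisions)
        if len(inner):
            # inner layer shrunk toward the simplex centre, as in two-layer NSGA-III
            inner = inner / 2.0 + 1.0 / (2.0 * self.n_objectives)
            return np.vstack([outer, inner])
        return outer

    def resolved_population_size(self) -> int:
        if self.population_size is not None:
            if self.population_size % 4 != 0:
                raise ValueError("population size must be a multiple of 4")
            return self.population_size
        return population_size_for(len(self.reference_points()))


def objectives_from_metrics(metrics: RuleMetrics, problem: str, empty: bool = False) -> np.ndarray:
    """Map rule metrics to the internal minimization objectives.

    Undefined rates and empty rules get the problem-worst values.
    """
    if problem == PROBLEM_EASY:
        worst_rate = 0.0
        if empty:
            return np.array([0.0, 0.0, 0.0])
        tpr = worst_rate if np.isnan(metrics.tpr) else metrics.tpr
        tnr = worst_rate if np.isnan(metrics.tnr) else metrics.tnr
        return np.array([-tpr, -tnr, -float(metrics.n_subjects)])
    if problem == PROBLEM_DIFFICULT:
        worst_rate = 1.0
        if empty:
            return np.array([1.0, 1.0, 0.0])
        tpr = worst_rate if np.isnan(metrics.tpr) else metrics.tpr
        tnr = worst_rate if np.isnan(metrics.tnr) else metrics.tnr
        return np.array([tpr, tnr, -float(metrics.n_subjects)])
    raise ValueError(f"unknown problem {problem!r}")


# ---------------------------------------------------------------------------
# Population initialization and variation
# ---------------------------------------------------------------------------

def initialize_population(
    size: int,
    scheme: DiscretizationScheme,
    p_include: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random starting population: each predictor enters a rule with ``p_include``.

    Included predictors get a uniformly random level; everything is encoded
    through the same Gray coding the search uses.
    """
    if not 0.0 <= p_include <= 1.0:
        raise ValueError("p_include must lie in [0, 1]")
    length = chromosome_length(scheme)
    pop = np.empty((size, length), dtype=np.uint8)
    n_levels = scheme.n_levels
    for i in range(size):
        predicates = [
            (j, int(rng.integers(n_levels[j])))
            for j in range(scheme.m)
            if rng.random() < p_include
        ]
        pop[i] = encode(Rule.from_pairs(predicates), scheme)
    return pop


def half_uniform_crossover(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Swap exactly half (rounded down) of the differing bits, chosen uniformly."""
    child_a, child_b = a.copy(), b.copy()
    diff = np.flatnonzero(a != b)
    k = len(diff) // 2
    if k:
        swap = rng.choice(diff, size=k, replace=False)
        child_a[swap], child_b[swap] = b[swap], a[swap]
    return child_a, child_b


def bit_flip_mutation(pop: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    flips = rng.random(pop.shape) < prob
    return pop ^ flips.astype(np.uint8)


# ---------------------------------------------------------------------------
# Nondominated sorting and reference-point niching
# ---------------------------------------------------------------------------

def domination_matrix(F: np.ndarray) -> np.ndarray:
    """dom[i, j] True iff solution i Pareto-dominates j (minimization)."""
    le = (F[:, None, :] <= F[None, :, :]).all(axis=2)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=2)
    return le & lt


def nondominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Fast nondominated sort; returns index arrays per front (best first)."""
    dom = domination_matrix(F)
    n_dominators = dom.sum(axis=0)
    fronts: list[np.ndarray] = []
    remaining = np.ones(len(F), dtype=bool)
    while remaining.any():
        front = np.flatnonzero(remaining & (n_dominators == 0))
        if front.size == 0:  # pragma: no cover - cannot happen with finite objectives
            raise RuntimeError("nondominated sort stalled")
        fronts.append(front)
        remaining[front] = False
        n_dominators = n_dominators - dom[front].sum(axis=0)
    return fronts


def nondominated_indices(F: np.ndarray) -> np.ndarray:
    return nondominated_sort(F)[0]


def _normalize(F: np.ndarray, first_front: np.ndarray) -> np.ndarray:
    """Deb–Jain adaptive normalization: translate by the ideal point, divide by
    intercepts of the hyperplane through per-axis extreme points (achievement
    scalarizing), falling back to the observed range when degenerate."""
    z_min = F.min(axis=0)
    ft = F - z_min
    m = F.shape[1]
    weights = np.full((m, m), 1e-6) + np.eye(m)
    asf = (ft[:, None, :] / weights[None, :, :]).max(axis=2)  # (n, m)
    extremes = ft[np.argmin(asf, axis=0)]  # (m, m)

    intercepts = None
    try:
        plane = np.linalg.solve(extremes, np.ones(m))
        with np.errstate(divide="ignore", over="ignore"):
            candidate = 1.0 / plane
        if np.all(np.isfinite(candidate)) and np.all(candidate > 1e-12):
            intercepts = candidate
    except np.linalg.LinAlgError:
        pass
    if intercepts is None:
        intercepts = ft[first_front].max(axis=0)
    intercepts = np.where(intercepts > 1e-12, intercepts, 1.0)
    return ft / intercepts


def _associate(Fn: np.ndarray, ref_dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest reference line (perpendicular distance) for each normalized point."""
    W = ref_dirs / np.linalg.norm(ref_dirs, axis=1, keepdims=True)
    proj = Fn @ W.T
    sq = (Fn * Fn).sum(axis=1, keepdims=True) - proj**2
    d = np.sqrt(np.maximum(sq, 0.0))
    pi = d.argmin(axis=1)
    return pi, d[np.arange(len(Fn)), pi]


def environmental_selection(
    F: np.ndarray, n_select: int, ref_points: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """NSGA-III survivor selection: whole fronts, then niching on the last."""
    fronts = nondominated_sort(F)
    chosen: list[np.ndarray] = []
    count = 0
    for fi, front in enumerate(fronts):
        if count + front.size <= n_select:
            chosen.append(front)
            count += front.size
            if count == n_select:
                return np.concatenate(chosen)
        else:
            last = front
            break
    else:  # pragma: no cover - n_select never exceeds population here
        return np.concatenate(chosen)

    pool = np.concatenate(chosen + [last]) if chosen else last
    Fn = _normalize(F[pool], np.arange(len(fronts[0])))
    pi, dist = _associate(Fn, ref_points)

    n_pool = len(pool)
    n_last = len(last)
    is_last = np.zeros(n_pool, dtype=bool)
    is_last[n_pool - n_last :] = True

    niche_count = np.zeros(len(ref_points), dtype=int)
    for r in pi[~is_last]:
        niche_count[r] += 1

    # candidates from the last front grouped by associated reference point
    members: dict[int, list[int]] = {}
    for local in np.flatnonzero(is_last):
        members.setdefault(int(pi[local]), []).append(local)

    selected_local: list[int] = []
    k = n_select - count
    active = {r for r in range(len(ref_points))}
    while len(selected_local) < k:
        candidates = [r for r in active if members.get(r)]
        if not candidates:
            active = {r for r in range(len(ref_points)) if members.get(r)}
            candidates = list(active)
        rho = np.array([niche_count[r] for r in candidates])
        min_rho = rho.min()
        tied = [r for r, c in zip(candidates, rho) if c == min_rho]
        r = tied[int(rng.integers(len(tied)))] if len(tied) > 1 else tied[0]
        group = members[r]
        if niche_count[r] == 0:
            pick = min(group, key=lambda local: dist[local])
        else:
            pick = group[int(rng.integers(len(group)))]
        group.remove(pick)
        if not group:
            active.discard(r)
        selected_local.append(pick)
        niche_count[r] += 1

    front_part = pool[np.array(selected_local, dtype=int)]
    return np.concatenate(chosen + [front_part]) if chosen else front_part


# ---------------------------------------------------------------------------
# The generational loop
# ---------------------------------------------------------------------------

def _evaluate_population(
    pop: np.ndarray,
    scheme: DiscretizationScheme,
    evaluator: Callable[[Rule], RuleMetrics],
    problem: str,
) -> tuple[list[Rule], list[RuleMetrics | None], np.ndarray]:
    codes = decode_segments(pop, scheme)
    n_levels = np.array(scheme.n_levels)
    rules: list[Rule] = []
    metrics: list[RuleMetrics | None] = []
    F = np.empty((len(pop), N_OBJECTIVES))
    for i in range(len(pop)):
        live = np.flatnonzero(codes[i] < n_levels)
        rule = Rule(tuple((int(j), int(codes[i, j])) for j in live))
        rules.append(rule)
        if len(rule) == 0:
            metrics.append(None)
            F[i] = objectives_from_metrics(
                RuleMetrics(0, 0, 0, np.nan, np.nan, np.nan), problem, empty=True
            )
        else:
            m = evaluator(rule)
            metrics.append(m)
            F[i] = objectives_from_metrics(m, problem)
    return rules, metrics, F


def _tournament(ranks: np.ndarray, n_parents: int, rng: np.random.Generator) -> np.ndarray:
    n = len(ranks)
    a = rng.integers(n, size=n_parents)
    b = rng.integers(n, size=n_parents)
    pick_a = ranks[a] < ranks[b]
    ties = ranks[a] == ranks[b]
    coin = rng.random(n_parents) < 0.5
    return np.where(pick_a | (ties & coin), a, b)


def nsga3_run(
    problem: str,
    config: SearchConfig,
    scheme: DiscretizationScheme,
    evaluator: Callable[[Rule], RuleMetrics],
    seed: int | None = None,
) -> list[tuple[Rule, RuleMetrics | None, np.ndarray]]:
    """One seeded NSGA-III run; returns the final population decoded to rules.

    Each element is (rule, metrics, internal minimization objectives); empty
    rules carry ``None`` metrics.  Bit-identical across reruns with the same
    seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ref_points = config.reference_points()
    pop_size = config.resolved_population_size()
    length = chromosome_length(scheme)
    p_mut = config.mutation_prob if config.mutation_prob is not None else 1.0 / length

    pop = initialize_population(pop_size, scheme, config.init_inclusion_prob, rng)
    rules, metrics, F = _evaluate_population(pop, scheme, evaluator, problem)

    for gen in range(config.generations):
        fronts = nondominated_sort(F)
        ranks = np.empty(pop_size, dtype=int)
        for rank, front in enumerate(fronts):
            ranks[front] = rank

        parents = _tournament(ranks, pop_size, rng)
        offspring = np.empty_like(pop)
        for i in range(0, pop_size, 2):
            pa, pb = pop[parents[i]], pop[parents[i + 1]]
            if rng.random() < config.crossover_prob:
                ca, cb = half_uniform_crossover(pa, pb, rng)
            else:
                ca, cb = pa.copy(), pb.copy()
            offspring[i], offspring[i + 1] = ca, cb
        offspring = bit_flip_mutation(offspring, p_mut, rng)

        o_rules, o_metrics, o_F = _evaluate_population(offspring, scheme, evaluator, problem)
        comb_pop = np.vstack([pop, offspring])
        comb_rules = rules + o_rules
        comb_metrics = metrics + o_metrics
        comb_F = np.vstack([F, o_F])

        keep = environmental_selection(comb_F, pop_size, ref_points, rng)
        pop = comb_pop[keep]
        rules = [comb_rules[i] for i in keep]
        metrics = [comb_metrics[i] for i in keep]
        F = comb_F[keep]
        logger.debug(
            "gen %d (%s): %d nondominated of %d",
            gen, problem, len(nondominated_indices(F)), pop_size,
        )

    logger.info(
        "%s-problem run finished: %d generations, %d nondominated in final population",
        problem, config.generations, len(nondominated_indices(F)),
    )
    return list(zip(rules, metrics, [F[i] for i in range(len(F))]))


def pooled_search(
    problem: str,
    config: SearchConfig,
    scheme: DiscretizationScheme,
    evaluator: Callable[[Rule], RuleMetrics],
) -> list[MinedRule]:
    """Repeat the search ``config.n_runs`` times (seeds ``seed + r``), pool the
    final populations, and deduplicate by canonical predicate set.

    Empty rules are discarded; the first-seen copy of a duplicate keeps its
    metrics (metrics are deterministic given the profile, so copies agree).
    """
    seen: dict[tuple[tuple[int, int], ...], MinedRule] = {}
    for r in range(config.n_runs):
        final = nsga3_run(problem, config, scheme, evaluator, seed=config.seed + r)
        for rule, metrics, _ in final:
            if len(rule) == 0 or rule.predicates in seen:
                continue
            seen[rule.predicates] = MinedRule(rule, metrics, problem, r)
    logger.info("pooled %s search: %d unique rules from %d runs", problem, len(seen), config.n_runs)
    return list(seen.values())
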