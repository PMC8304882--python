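"""Conjunctive rules, their Gray-coded binary representation, and evaluation.

A rule is a conjunction of ``predictor == level`` predicates (at most one per
predictor).  For the evolutionary search each rule is a fixed-length binary
string: predictor *j* with ``n_levels_j`` levels occupies
``ceil(log2(n_levels_j + 1))`` bits — the ``+1`` reserves one code meaning
"this predictor is absent from the rule".  Segments are interpreted as
reflected binary Gray code; any decoded integer at or above ``n_levels_j``
(the absence code or an overflow of the unused code space) marks the
predictor absent.

Rule quality is measured against a per-subject cross-validation performance
profile: restricted to the subjects a rule covers, TPR is the pooled
true-positive rate of the model's repeated-CV predictions over covered
positives, TNR likewise over covered negatives, and accuracy the pooled
fraction of correct predictions.  A rule covering no positives has no TPR
(reported as NaN); the search layer maps that to the worst value for the
problem at hand.
"""

from __future__ import annotations

import dataclasses
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .cv_engine import PerformanceProfile
    from .discretize import DiscretizationScheme


@dataclasses.dataclass(frozen=True)
class Rule:
    """Conjunction of (predictor index, level) predicates, sorted by predictor."""

    predicates: tuple[tuple[int, int], ...]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]]) -> "Rule":
        pairs = sorted((int(j), int(a)) for j, a in pairs)
        if len({j for j, _ in pairs}) != len(pairs):
            raise ValueError("a rule may contain at most one predicate per predictor")
        return cls(tuple(pairs))

    def __len__(self) -> int:
        return len(self.predicates)

    @property
    def predictor_indices(self) -> tuple[int, ...]:
        return tuple(j for j, _ in self.predicates)


@dataclasses.dataclass(frozen=True)
class RuleMetrics:
    """Profile-based metrics of a rule's covered subgroup.

    ``tpr``/``tnr``/``accuracy`` are NaN when undefined (no covered positives
    / negatives / subjects).
    """

    n_subjects: int
    n_pos: int
    n_neg: int
    tpr: float
    tnr: float
    accuracy: float


@dataclasses.dataclass(frozen=True)
class MinedRule:
    """A rule with its metrics and search provenance."""

    rule: Rule
    metrics: RuleMetrics
    problem: str  # "easy" | "difficult"
    run: int


def n_bits(n_levels: int) -> int:
    """Bits needed to code ``n_levels`` levels plus the absence code."""
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    # ceil(log2(n_levels + 1)) == bit length of n_levels for n_levels >= 1
    return int(n_levels).bit_length()


def gray_encode(value: int, width: int) -> np.ndarray:
    """Gray-code ``value`` as ``width`` bits, most significant first."""
    if not 0 <= value < (1 << width):
        raise ValueError(f"value {value} does not fit in {width} bits")
    g = value ^ (value >> 1)
    return np.array([(g >> (width - 1 - i)) & 1 for i in range(width)], dtype=np.uint8)


def gray_decode(bits: Sequence[int]) -> int:
    """Decode a most-significant-first Gray-coded bit sequence to an integer."""
    value = 0
    acc = 0
    for b in bits:
        acc ^= int(b)
        value = (value << 1) | acc
    return value


def segment_offsets(scheme: "DiscretizationScheme") -> tuple[np.ndarray, np.ndarray]:
    """(start offsets, widths) of each predictor's bit segment."""
    widths = np.array([n_bits(nl) for nl in scheme.n_levels], dtype=int)
    starts = np.concatenate(([0], np.cumsum(widths)[:-1]))
    return starts, widths


def chromosome_length(scheme: "DiscretizationScheme") -> int:
    return int(sum(n_bits(nl) for nl in scheme.n_levels))


def encode(rule: Rule, scheme: "DiscretizationScheme") -> np.ndarray:
    """Encode a rule as a Gray-coded bit string.

    Absent predictors carry the Gray code of their absence level
    (``n_levels_j``); inverse of :func:`decode` on valid rules.
    """
    starts, widths = segment_offsets(scheme)
    bits = np.zeros(int(starts[-1] + widths[-1]), dtype=np.uint8)
    levels = dict(rule.predicates)
    for j, nl in enumerate(scheme.n_levels):
        a = levels.get(j, nl)  # nl == designated absence code
        if a > nl or (j in levels and a >= nl):
            raise ValueError(f"invalid level {a} for predictor {j} ({nl} levels)")
        bits[starts[j] : starts[j] + widths[j]] = gray_encode(a, int(widths[j]))
    return bits


def decode(bits: np.ndarray, scheme: "DiscretizationScheme") -> Rule:
    """Decode a bit string to a rule; codes ≥ n_levels_j mean absence."""
    starts, widths = segment_offsets(scheme)
    if len(bits) != starts[-1] + widths[-1]:
        raise ValueError("chromosome length does not match scheme")
    predicates = []
    for j, nl in enumerate(scheme.n_levels):
        g = gray_decode(bits[starts[j] : starts[j] + widths[j]])
        if g < nl:
            predicates.append((j, g))
    return Rule(tuple(predicates))


def decode_segments(bits_matrix: np.ndarray, scheme: "DiscretizationScheme") -> np.ndarray:
    """Vectorized Gray decode of a (N, L) population to (N, m) level codes.

    Codes ≥ n_levels_j (absence / overflow) are returned as-is; callers test
    against ``scheme.n_levels``.
    """
    starts, widths = segment_offsets(scheme)
    n = bits_matrix.shape[0]
    out = np.empty((n, len(widths)), dtype=np.int64)
    for j, (s, w) in enumerate(zip(starts, widths)):
        seg = bits_matrix[:, s : s + w].astype(np.int64)
        acc = np.zeros(n, dtype=np.int64)
        val = np.zeros(n, dtype=np.int64)
        for col in range(w):
            acc ^= seg[:, col]
            val = (val << 1) | acc
        out[:, j] = val
    return out


def evaluate(
    rule: Rule,
    level_matrix: np.ndarray,
    y: np.ndarray,
    profile: "PerformanceProfile",
) -> RuleMetrics:
    """Metrics of ``rule`` over the subjects it covers.

    A subject is covered iff its level equals the rule's level for every
    predicate.  Rates pool the profile's per-subject tallies over covered
    subjects; undefined rates (no covered positives/negatives) come back NaN.
    """
    if len(rule) == 0:
        raise ValueError("cannot evaluate an empty rule")
    covered = np.ones(level_matrix.shape[0], dtype=bool)
    for j, a in rule.predicates:
        covered &= level_matrix[:, j] == a
    return _metrics_for_mask(covered, y, profile)


def _metrics_for_mask(covered: np.ndarray, y: np.ndarray, profile) -> RuleMetrics:
    pos = covered & (y == 1)
    neg = covered & (y == 0)
    n_pos = int(pos.sum())
    n_neg = int(neg.sum())
    tp = profile.tp[pos].sum()
    fn = profile.fn[pos].sum()
    tn = profile.tn[neg].sum()
    fp = profile.fp[neg].sum()
    tpr = tp / (tp + fn) if n_pos else np.nan
    tnr = tn / (tn + fp) if n_neg else np.nan
    total = profile.n_predictions[covered].sum()
    accuracy = (tp + tn) / total if total else np.nan
    return RuleMetrics(
        n_subjects=n_pos + n_neg,
        n_pos=n_pos,
        n_neg=n_neg,
        tpr=float(tpr),
        tnr=float(tnr),
        accuracy=float(accuracy),
    )


class RuleEvaluator:
    """Caches per-(predictor, level) coverage masks for fast repeated evaluation."""

    def __init__(self, level_matrix: np.ndarray, y: np.ndarray, profile: "PerformanceProfile"):
        self.level_matrix = np.asarray(level_matrix)
        self.y = np.asarray(y)
        self.profile = profile
        self._masks: dict[tuple[int, int], np.ndarray] = {}
        self._cache: dict[tuple[tuple[int, int], ...], RuleMetrics] = {}

    def coverage(self, rule: Rule) -> np.ndarray:
        covered = np.ones(self.level_matrix.shape[0], dtype=bool)
        for key in rule.predicates:
            mask = self._masks.get(key)
            if mask is None:
                j, a = key
                mask = self.level_matrix[:, j] == a
                self._masks[key] = mask
            covered = covered & mask
        return covered

    def __call__(self, rule: Rule) -> RuleMetrics:
        cached = self._cache.get(rule.predicates)
        if cached is None:
            if len(rule) == 0:
                raise ValueError("cannot evaluate an empty rule")
            cached = _metrics_for_mask(self.coverage(rule), self.y, self.profile)
            self._cache[rule.predicates] = cached
        return cached


def describe(rule: Rule, scheme: "DiscretizationScheme") -> str:
    """Human-readable rendering, e.g. ``(SMOKER = 0) and (54 <= AGE <= 55)``."""
    if len(rule) == 0:
        return "(empty rule)"
    return " and ".join(f"({scheme.describe_level(j, a)})" for j, a in rule.predicates)
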