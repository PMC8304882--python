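"""Predictor discretization: map every predictor to a finite set of levels.

Predictors with fewer than eight distinct observed values keep their values
as categories (level = rank of the value among the sorted distinct values, so
0/1 dichotomous coding maps to levels 0/1 unchanged).  Predictors with eight
or more distinct values are binned by one-dimensional k-means (default four
bins) on the raw observed values; bins are ordered by centroid and separated
at the midpoint between the maximum of one bin and the minimum of the next.
Out-of-range values clamp to the outermost bins, which makes the scheme
applicable to unseen data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from .data_io import Cohort

logger = logging.getLogger(__name__)

VALUE_CODED = "values"
BINNED = "binned"

#: distinct-value count at and above which a predictor is binned
BINNING_THRESHOLD = 8

SCHEME_SCHEMA_VERSION = 1


@dataclasses.dataclass
class PredictorLevels:
    """Level definition for one predictor.

    Value-coded: ``values`` lists the sorted distinct observed values, level
    = index.  Binned: ``boundaries`` holds the ``n_levels - 1`` interior cut
    points and ``intervals`` the observed [low, high] per bin (description
    only).
    """

    name: str
    kind: str
    values: np.ndarray | None = None
    boundaries: np.ndarray | None = None
    intervals: list[tuple[float, float]] | None = None

    @property
    def n_levels(self) -> int:
        if self.kind == VALUE_CODED:
            return len(self.values)
        return len(self.boundaries) + 1


@dataclasses.dataclass
class DiscretizationScheme:
    predictors: list[PredictorLevels]

    @property
    def n_levels(self) -> list[int]:
        return [p.n_levels for p in self.predictors]

    @property
    def m(self) -> int:
        return len(self.predictors)

    def describe_level(self, j: int, level: int) -> str:
        p = self.predictors[j]
        if p.kind == VALUE_CODED:
            value = p.values[level]
            text = f"{value:g}" if isinstance(value, float) else str(value)
            return f"{p.name} = {text}"
        lo, hi = p.intervals[level]
        return f"{lo:g} <= {p.name} <= {hi:g}"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": SCHEME_SCHEMA_VERSION,
            "predictors": [
                {
                    "name": p.name,
                    "kind": p.kind,
                    "values": None if p.values is None else [float(v) for v in p.values],
                    "boundaries": None if p.boundaries is None else [float(b) for b in p.boundaries],
                    "intervals": None if p.intervals is None else [[float(a), float(b)] for a, b in p.intervals],
                }
                for p in self.predictors
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscretizationScheme":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema_version") != SCHEME_SCHEMA_VERSION:
            raise ValueError(f"{path}: unsupported scheme schema version")
        preds = []
        for entry in payload["predictors"]:
            preds.append(
                PredictorLevels(
                    name=entry["name"],
                    kind=entry["kind"],
                    values=None if entry["values"] is None else np.array(entry["values"], dtype=float),
                    boundaries=None if entry["boundaries"] is None else np.array(entry["boundaries"], dtype=float),
                    intervals=None if entry["intervals"] is None else [tuple(iv) for iv in entry["intervals"]],
                )
            )
        return cls(preds)


def build_scheme(cohort: Cohort, n_bins: int = 4, seed: int = 0) -> DiscretizationScheme:
    """Build level definitions for every predictor of a fully observed cohort.

    k-means (k-means++ init, 10 restarts, seeded) runs on the raw observed
    values of each high-cardinality predictor; a constant predictor becomes a
    single-level value coding with a warning.
    """
    if np.isnan(cohort.X).any():
        raise ValueError("discretization requires a fully observed cohort (impute first)")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    from sklearn.cluster import KMeans

    preds: list[PredictorLevels] = []
    for j, name in enumerate(cohort.predictor_names):
        col = cohort.X[:, j]
        distinct = np.unique(col)
        if distinct.size == 1:
            logger.warning("predictor %r is constant; single-level coding", name)
        if distinct.size < BINNING_THRESHOLD:
            preds.append(PredictorLevels(name=name, kind=VALUE_CODED, values=distinct))
            continue

        km = KMeans(n_clusters=n_bins, n_init=10, random_state=seed)
        labels = km.fit_predict(col.reshape(-1, 1))
        order = np.argsort(km.cluster_centers_.ravel())
        rank = np.empty(n_bins, dtype=int)
        rank[order] = np.arange(n_bins)
        levels = rank[labels]

        intervals = []
        for b in range(n_bins):
            vals = col[levels == b]
            intervals.append((float(vals.min()), float(vals.max())))
        boundaries = np.array(
            [(intervals[b][1] + intervals[b + 1][0]) / 2.0 for b in range(n_bins - 1)]
        )
        preds.append(
            PredictorLevels(name=name, kind=BINNED, boundaries=boundaries, intervals=intervals)
        )
    return DiscretizationScheme(preds)


def assign_levels(cohort: Cohort, scheme: DiscretizationScheme) -> np.ndarray:
    """n×m integer level matrix for ``cohort`` under ``scheme``.

    Binned predictors clamp out-of-range values to the nearest boundary
    level; a value-coded predictor meeting an unseen value is an error
    (categories are defined by what was observed when the scheme was built).
    """
    if scheme.m != cohort.m:
        raise ValueError("scheme predictor count does not match cohort")
    if np.isnan(cohort.X).any():
        raise ValueError("level assignment requires a fully observed cohort")

    levels = np.empty((cohort.n, cohort.m), dtype=np.int64)
    for j, p in enumerate(scheme.predictors):
        col = cohort.X[:, j]
        if p.kind == VALUE_CODED:
            idx = np.searchsorted(p.values, col)
            idx_clamped = np.clip(idx, 0, len(p.values) - 1)
            if not np.array_equal(p.values[idx_clamped], col):
                bad = col[p.values[idx_clamped] != col]
                raise ValueError(
                    f"predictor {p.name!r}: unseen value(s) {np.unique(bad)[:5]} "
                    "not among the scheme's categories"
                )
            levels[:, j] = idx
        else:
            levels[:, j] = np.searchsorted(p.boundaries, col)
    return levels
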