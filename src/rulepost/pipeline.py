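"""End-to-end orchestration: cohort → CV profile → discretize → mine → report.

The pipeline is driven by a :class:`PipelineConfig` (loadable from YAML) and
is fully reproducible from its global seed: reruns with the same config
produce byte-identical artifacts.  A pre-computed performance profile can be
ingested instead of running the bundled Lasso logistic regression, which is
what makes the tool model-independent — any classifier's per-subject
repeated-CV tallies in the profile CSV format work.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .cv_engine import (
    ModelConfig,
    PerformanceProfile,
    filter_selected_predictors,
    run_repeated_cv,
)
from .data_io import Cohort, filter_sparse, knn_impute, read_cohort, write_rules
from .discretize import DiscretizationScheme, assign_levels, build_scheme
from .nsga3 import PROBLEM_DIFFICULT, PROBLEM_EASY, SearchConfig, pooled_search
from .rules import RuleEvaluator
from .selection import (
    CategoryAssignment,
    SelectionCriteria,
    categorize,
    predictor_importance,
    rule_space_coordinates,
    select_final_rules,
    write_report,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """All stage settings plus paths and the global seed."""

    cohort_path: str | None = None
    outcome_column: str = "outcome"
    id_column: str | None = None
    profile_path: str | None = None  # ingest an external profile instead of CV
    outdir: str = "rulepost_out"
    seed: int = 0
    # preprocessing
    max_missing_row: float = 0.3
    max_missing_col: float = 0.3
    knn_k: int = 5
    # stages
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    n_bins: int = 4
    search: SearchConfig = dataclasses.field(default_factory=SearchConfig)
    criteria: SelectionCriteria = dataclasses.field(default_factory=SelectionCriteria)
    tsne: bool = False

    def __post_init__(self) -> None:
        # dataclass constructors validate their own fields; cross-checks here
        if self.cohort_path is None and self.profile_path is None:
            pass  # cohort may be passed in memory to run_pipeline
        self.search.resolved_population_size()  # raises if inconsistent

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        model = ModelConfig(**raw.pop("model", {}))
        search = SearchConfig(**raw.pop("search", {}))
        criteria = SelectionCriteria(**raw.pop("criteria", {}))
        return cls(model=model, search=search, criteria=criteria, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        raw = dataclasses.asdict(self)
        return raw


@dataclasses.dataclass
class PipelineResult:
    cohort: Cohort
    profile: PerformanceProfile
    scheme: DiscretizationScheme
    pooled_easy: list
    pooled_difficult: list
    easy_rules: list
    difficult_rules: list
    assignment: CategoryAssignment
    importance: object


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> PipelineResult:
    """Execute every stage and write the artifact bundle to ``config.outdir``.

    Stage failures abort with a stage-tagged exception.  ``cohort`` may be
    supplied in memory (e.g. synthetic) instead of ``config.cohort_path``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("pipeline stage: %s", name)
        return name

    current = stage("load")
    try:
        if cohort is None:
            if config.cohort_path is None:
                raise ValueError("no cohort: set cohort_path or pass one in memory")
            cohort = read_cohort(config.cohort_path, config.outcome_column, config.id_column)

        current = stage("preprocess")
        import numpy as np

        if np.isnan(cohort.X).any():
            cohort = filter_sparse(cohort, config.max_missing_row, config.max_missing_col)
            cohort = knn_impute(cohort, config.knn_k)

        current = stage("profile")
        if config.profile_path is not None:
            profile = PerformanceProfile.from_csv(config.profile_path)
            if profile.subject_ids != list(cohort.subject_ids):
                raise ValueError("external profile subject ids do not match the cohort")
        else:
            model = dataclasses.replace(config.model, base_seed=config.model.base_seed + config.seed)
            profile = run_repeated_cv(cohort, model)
        profile.to_csv(outdir / "profile.csv")

        current = stage("predictor-filter")
        if profile.selected_predictors:
            cohort = filter_selected_predictors(cohort, profile)

        current = stage("discretize")
        scheme = build_scheme(cohort, n_bins=config.n_bins, seed=config.seed)
        scheme.to_json(outdir / "scheme.json")
        levels = assign_levels(cohort, scheme)

        current = stage("mine")
        evaluator = RuleEvaluator(levels, cohort.y, profile)
        search = dataclasses.replace(config.search, seed=config.search.seed + config.seed)
        pooled_easy = pooled_search(PROBLEM_EASY, search, scheme, evaluator)
        pooled_difficult = pooled_search(PROBLEM_DIFFICULT, search, scheme, evaluator)
        meta = {"seed": search.seed, "generations": search.generations, "runs": search.n_runs}
        write_rules(outdir / "rules_pooled_easy.json", pooled_easy, scheme, meta)
        write_rules(outdir / "rules_pooled_difficult.json", pooled_difficult, scheme, meta)

        current = stage("select")
        easy_rules, difficult_rules = select_final_rules(
            pooled_easy + pooled_difficult, config.criteria
        )
        write_rules(outdir / "rules_final_easy.json", easy_rules, scheme, meta)
        write_rules(outdir / "rules_final_difficult.json", difficult_rules, scheme, meta)

        current = stage("categorize")
        assignment = categorize(levels, easy_rules, difficult_rules, profile)

        current = stage("report")
        importance = predictor_importance(easy_rules, difficult_rules, assignment, scheme)
        write_report(outdir, easy_rules, difficult_rules, assignment, importance, scheme)
        if config.tsne and (assignment.labels != "non_covered").sum() > 5:
            rule_space_coordinates(assignment, seed=config.seed).to_csv(
                outdir / "rule_space_tsne.csv", index=False
            )

        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "n_subjects": cohort.n,
            "n_predictors": cohort.m,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    return PipelineResult(
        cohort=cohort,
        profile=profile,
        scheme=scheme,
        pooled_easy=pooled_easy,
        pooled_difficult=pooled_difficult,
        easy_rules=easy_rules,
        difficult_rules=difficult_rules,
        assignment=assignment,
        importance=importance,
    )
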