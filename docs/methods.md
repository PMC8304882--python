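# Methods

## Problem and model

`rulepost` answers a post-hoc question about a binary classifier on a
tabular cohort: *which subject characteristics make the model's predictions
reliably right or reliably wrong?* The unit of evidence is a per-subject
performance profile: under repeated stratified k-fold cross-validation each
subject is a test case once per run, and its prediction outcomes are tallied
as TPᵢ/FNᵢ (for outcome-positive subjects) or TNᵢ/FPᵢ (for negatives). Rules
— conjunctions of `predictor = level` predicates — are then evolved so that
the tallies pooled over the covered subjects have extreme accuracy in either
direction. The analysis consumes only the profile, never the model
internals, so it applies to any classifier whose per-subject tallies are
supplied in the profile CSV format.

### Reference model

The bundled model is Lasso logistic regression minimizing
`‖ω‖₁ + C · Σ log(1 + exp(−y⟨ω,x⟩))` with y ∈ {−1, +1}. Note the
parameterization: **C multiplies the loss**, so shrinkage *grows* as C
*falls*; the default C = 0.15 is fairly aggressive and acts as embedded
feature selection. This is identical to scikit-learn's C-parameterization,
to which the convex solve is delegated (liblinear; `intercept_scaling=1000`
so the intercept is effectively unpenalized, as the objective requires —
the residual penalty on the intercept is |ω₀|/1000, far below the solver
tolerance of 1e-8; the saga solver, which is exactly intercept-unpenalized,
was rejected because it empirically stalls short of the optimum on small
problems). The fit is verified in the test suite against a direct scipy
L-BFGS-B minimization of the same objective with the positive/negative split
ω = ω⁺ − ω⁻.

Predictors are min-max scaled to (0, 1) by a scaler fitted on the training
folds only; test values are clipped to [0, 1] afterwards, a choice that
prevents leakage and bounds the influence of out-of-range test extremes.
The classification cutoff α equals the training-fold positive proportion
(0.5 for balanced data), which keeps the operating point sensible under
class imbalance; the boundary case P = α is classified positive. Fold
partitions are stratified, shuffled, and seeded `base_seed + run`, so a
profile is exactly reproducible from its seed. A predictor counts as
"selected" when some fitted model gives it |ω| > 1e-10 (exact zeros are
solver-dependent); predictors never selected in any fold of any run are
dropped before rule mining, since the model demonstrably ignores them.

## Discretization

Rule predicates need finite levels. Predictors with fewer than eight
distinct observed values are value-coded: level = rank of the value among
the sorted distinct values (identical to the raw coding for 0/1 data, and
robust to arbitrary numeric categories). Predictors with eight or more
distinct values are binned by one-dimensional k-means on the **raw**
observed values (k-means++ initialization, 10 restarts, fixed seed) with 4
bins by default; raw units keep rule intervals directly readable. Bins are
ordered by centroid; the boundary between adjacent bins is the midpoint
between the upper observed value of one bin and the lower observed value of
the next. When a scheme is applied to unseen data, out-of-range continuous
values clamp to the outermost bins, while an unseen category of a
value-coded predictor is an error (categories are defined by observation).
A constant predictor degenerates to a single level with a warning.

## Rule search

Each rule is a fixed-length binary chromosome: predictor j with nⱼ levels
occupies ⌈log₂(nⱼ+1)⌉ bits, the +1 reserving a code for "absent from the
rule". Segments are reflected binary Gray code (one-bit neighbourhood
between adjacent levels); every decoded value ≥ nⱼ — the designated absence
code or any overflow of the unused code space — marks the predictor absent.

Two three-objective problems are solved: for easy cases, maximize
(TPR, TNR, N_subjects); for difficult cases, minimize TPR and TNR while
still maximizing N_subjects (coverage pushes toward general patterns).
A rule covering no positives has no TPR; it receives the worst value for
the problem at hand (0 when maximizing, 1 when minimizing) so it is never
favored, and the class-balance filter would exclude it from the final set
regardless. A rule with no predicates is assigned the worst value on all
three objectives rather than raising, so the evolutionary loop handles it
gracefully.

The optimizer is NSGA-III, implemented in-package: fast nondominated
sorting; binary tournament (size 2) on nondomination rank with random tie
breaks; half-uniform crossover (exactly ⌊d/2⌋ of the d differing bits,
chosen uniformly, are exchanged; probability 1.0); per-bit flip mutation
(default rate 1/L for chromosome length L — standard practice, the rate is
configurable); and environmental selection that admits whole fronts and
niches the last front against Das–Dennis simplex-lattice reference points
(ideal-point translation, achievement-scalarizing extreme points, hyperplane
intercepts with a fall-back to the first front's observed range when the
extreme-point system is singular or gives non-positive intercepts;
association by perpendicular distance; niche counts filled preferring the
emptiest reference, closest member first). Defaults follow the published
configuration: 3 objectives, 20 outer divisions and 0 inner divisions
(a zero-division layer contributes no points) giving 231 reference points;
population = smallest multiple of four strictly above that (232); 200
generations; initial rules include each predictor independently with
probability 0.05; 25 independent seeded runs per problem (seed + r) whose
final populations are pooled and deduplicated by canonical predicate set
(duplicates agree on metrics, which are deterministic given the profile, so
the first-seen copy is kept; empty rules are dropped).

Monitoring: the per-generation nondominated count is logged at DEBUG and a
per-run summary at INFO. Hypervolume is not computed — it is pure
monitoring cost in three dimensions and plays no role in selection.

## Final rules, categories, importance

A pooled rule survives iff (1) it covers at least `Supp = 30` subjects;
(2) |TPR − TNR| ≤ γ·max(TPR, TNR) with γ = 0.1, so it describes both
outcome classes comparably (rules with an undefined rate are excluded
first); and (3) its covered accuracy is ≥ α_easy = 0.95 (easy set) or
≤ α_diff = 0.50 (difficult set), both inclusive; rules between the bands
are dropped. Subjects are then partitioned: **easy** (covered by ≥ 1 easy
rule and no difficult rule), **difficult** (the converse), **ambiguous**
(both), **non-covered** (neither). Category aggregates pool the profile
tallies; with complete k-fold coverage every subject has the same number of
predictions, so subject-weighted and prediction-weighted accuracies
coincide. Predictor importance is computed per (predictor, level) predicate
— the same predictor can matter with different values in different
directions — as the number of *unique* subjects per category covered by
final rules containing that predicate (set union across rules, no double
counting).

## Synthetic data: what it does and does not emulate

The generator emulates the shape of a mid-size epidemiological cohort:
imbalanced binary outcome (default positive fraction 0.26), a mix of
dichotomous (60%), low-cardinality ordinal (20%, 3–6 values) and Gaussian
continuous (20%) predictors, an optional logistic signal with the intercept
calibrated by root finding so the mean event probability hits the target
fraction, and planted subgroups defined by predictor-value predicates whose
subjects' per-run correctness is drawn Binomial(n_runs, target accuracy);
everyone else sits at a 0.72 baseline, roughly the operating point of a
mid-quality clinical risk model. Planted definitions use value-coded
predictors so they survive discretization verbatim.

Deliberate simplifications: per-subject correctness is i.i.d. across runs,
whereas real CV tallies are correlated through shared training folds;
predictors are mutually independent, with none of the correlation structure
of real questionnaires and assays; and planted subgroups have sharp
boundaries. Passing the recovery tests therefore shows the mining, filtering
and categorization machinery works when the profile truly contains
rule-shaped structure — it does not certify performance under correlated
predictors or diffuse subgroups.

## Numerical choices and degenerate inputs

- Nonzero-coefficient threshold 1e-10; solver tolerance 1e-8 with
  non-convergence surfaced as a logged warning with (n, m, C, max_iter, tol).
- k-means ties in assignment resolve to the lower-centroid cluster via the
  bin-boundary construction (levels are assigned by `searchsorted` on the
  boundaries, not by nearest centroid).
- `knn_impute` delegates to scikit-learn's KNNImputer (nan-aware Euclidean
  distance, uniform neighbour weights); k > n−1 clamps with a warning; a
  predictor with zero observed values is an error.
- Sparsity filtering removes columns before rows (the order changes the
  result and is fixed); thresholds default to 0.3/0.3 and are configuration,
  not data-derived facts.
- Single-class training folds, infeasible stratification, empty predictor
  selections and empty final rule sets raise or warn explicitly rather than
  propagating NaNs.

## Problem sizes used in tests and the acceptance script

The package's own experiments run at desk scale: Pareto-front equivalence
uses 2–3 predictor instances (24–124 possible rules) where exhaustive
enumeration is the oracle, with the full 232-member population but 30
generations × 3 runs; the planted-subgroup recovery cohort has n = 1500 and
m = 12 with the search reduced to 28 reference points (6 divisions,
population 32), 60 generations × 5 runs; CV calibration uses n = 500,
m = 200 (the high predictor-to-subject ratio keeps the null model from
degenerating to intercept-only, whose predictions sit exactly on the cutoff
boundary). These sizes are the package's choices for fast, deterministic
verification; the defaults remain the published full-scale settings.

## Known limitations

- Binary outcomes only; no time-to-event support.
- Conjunctions of equalities only — no disjunction or negation, by design.
- The search is stochastic; pooling 25 seeded runs mitigates but does not
  guarantee Pareto-completeness on large predictor spaces.
- Category assignments on unseen data require the discretization scheme and
  final rules, and inherit the caveat that value-coded predictors cannot
  absorb unseen categories.
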