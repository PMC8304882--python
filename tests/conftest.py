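import numpy as np
import pytest

from rulepost import Cohort
from rulepost.discretize import DiscretizationScheme, PredictorLevels


def make_value_scheme(n_levels, names=None):
    """Value-coded scheme with levels 0..k-1 per predictor."""
    names = names or [f"x{j}" for j in range(len(n_levels))]
    return DiscretizationScheme(
        [
            PredictorLevels(name=name, kind="values", values=np.arange(k, dtype=float))
            for name, k in zip(names, n_levels)
        ]
    )


@pytest.fixture
def value_scheme():
    return make_value_scheme


@pytest.fixture
def toy_cohort():
    """Six-subject cohort: one binary predictor splitting subjects {0,1,3}."""
    X = np.array([[0.0], [0.0], [1.0], [0.0], [1.0], [1.0]])
    y = np.array([1, 1, 1, 0, 0, 0], dtype=np.int8)
    return Cohort([f"s{i}" for i in range(6)], X, y, ["x0"], ["dichotomous"])


@pytest.fixture
def random_cohort_factory():
    def factory(n=60, m=4, seed=0, p_pos=0.4):
        rng = np.random.default_rng(seed)
        X = np.column_stack(
            [
                (rng.random(n) < 0.5).astype(float),
                *[rng.integers(0, 3, size=n).astype(float) for _ in range(m - 2)],
                rng.normal(size=n),
            ]
        )
        y = (rng.random(n) < p_pos).astype(np.int8)
        if y.sum() == 0:
            y[0] = 1
        if y.sum() == n:
            y[0] = 0
        names = [f"p{j}" for j in range(m)]
        from rulepost import infer_kinds

        return Cohort([str(i) for i in range(n)], X, y, names, infer_kinds(X))

    return factory
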