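import numpy as np
import pandas as pd
import pytest

from rulepost import (
    Cohort,
    filter_sparse,
    knn_impute,
    read_cohort,
    read_rules,
    write_cohort,
    write_rules,
)
from rulepost.rules import MinedRule, Rule, RuleMetrics

from conftest import make_value_scheme


def write_csv(path, frame):
    frame.to_csv(path, index=False)
    return path


class TestReadCohort:
    def test_basic_parse_and_kind_inference(self, tmp_path):
        path = write_csv(
            tmp_path / "c.csv",
            pd.DataFrame(
                {
                    "outcome": [0, 1, 0, 1],
                    "binary": [0, 1, 1, 0],
                    "ordinal": [1, 2, 3, 2],
                    "cont": [0.5, 1.7, 2.9, 3.1],
                }
            ),
        )
        cohort = read_cohort(path, "outcome")
        assert cohort.n == 4 and cohort.m == 3
        assert cohort.predictor_kinds == ["dichotomous", "ordinal", "continuous"]
        assert np.array_equal(cohort.y, [0, 1, 0, 1])

    def test_non_binary_outcome_rejected(self, tmp_path):
        path = write_csv(tmp_path / "c.csv", pd.DataFrame({"outcome": [0, 2], "x": [1, 2]}))
        with pytest.raises(ValueError, match="0/1"):
            read_cohort(path, "outcome")

    def test_missing_outcome_column_rejected(self, tmp_path):
        path = write_csv(tmp_path / "c.csv", pd.DataFrame({"x": [1, 2]}))
        with pytest.raises(ValueError, match="outcome"):
            read_cohort(path, "outcome")

    def test_empty_table_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("outcome,x\n")
        with pytest.raises(ValueError, match="empty"):
            read_cohort(path, "outcome")

    def test_all_missing_predictor_retained(self, tmp_path):
        # filtering is a separate operation; reading keeps the column
        path = tmp_path / "c.csv"
        path.write_text("outcome,x,z\n0,,1\n1,,2\n")
        cohort = read_cohort(path, "outcome")
        assert cohort.m == 2
        assert np.isnan(cohort.X[:, 0]).all()

    def test_roundtrip_exact(self, tmp_path, random_cohort_factory):
        cohort = random_cohort_factory(n=30, m=4, seed=3)
        write_cohort(cohort, tmp_path / "c.csv")
        back = read_cohort(tmp_path / "c.csv", "outcome", id_column="subject_id")
        assert back.subject_ids == cohort.subject_ids
        assert back.predictor_names == cohort.predictor_names
        assert np.array_equal(back.X, cohort.X)
        assert np.array_equal(back.y, cohort.y)


class TestFilterSparse:
    def test_fully_missing_column_removed(self):
        X = np.array([[np.nan, 1.0], [np.nan, 2.0]])
        cohort = Cohort(["a", "b"], X, [0, 1], ["u", "v"], ["continuous"] * 2)
        out = filter_sparse(cohort, max_missing_col=0.5)
        assert out.predictor_names == ["v"]

    def test_thresholds_of_one_are_identity(self):
        X = np.array([[np.nan, 1.0], [2.0, np.nan]])
        cohort = Cohort(["a", "b"], X, [0, 1], ["u", "v"], ["continuous"] * 2)
        out = filter_sparse(cohort, max_missing_row=1.0, max_missing_col=1.0)
        assert out.n == 2 and out.m == 2

    def test_sparse_subject_removed(self):
        # 10 x 5, subject 0 missing 3 of 5 values (fraction 0.6 > 0.5)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 5))
        X[0, :3] = np.nan
        cohort = Cohort([str(i) for i in range(10)], X, [0, 1] * 5,
                        [f"p{j}" for j in range(5)], ["continuous"] * 5)
        out = filter_sparse(cohort, max_missing_row=0.5, max_missing_col=0.5)
        assert out.n == 9
        assert "0" not in out.subject_ids

    def test_columns_filtered_before_rows(self):
        # subject 0's missingness is concentrated in a bad column; once that
        # column is dropped the subject is complete and must survive
        X = np.array(
            [
                [np.nan, 1.0, 1.0],
                [np.nan, 2.0, 0.0],
                [np.nan, 3.0, 1.0],
                [5.0, 4.0, 0.0],
            ]
        )
        cohort = Cohort(list("abcd"), X, [0, 1, 0, 1], ["bad", "u", "v"], ["continuous"] * 3)
        out = filter_sparse(cohort, max_missing_row=0.3, max_missing_col=0.5)
        assert out.predictor_names == ["u", "v"]
        assert out.n == 4

    def test_idempotent(self, random_cohort_factory):
        cohort = random_cohort_factory(n=40, m=4, seed=1)
        rng = np.random.default_rng(2)
        mask = rng.random(cohort.X.shape) < 0.2
        cohort.X[mask] = np.nan
        once = filter_sparse(cohort, 0.3, 0.3)
        twice = filter_sparse(once, 0.3, 0.3)
        assert twice.subject_ids == once.subject_ids
        assert twice.predictor_names == once.predictor_names


class TestKnnImpute:
    def test_no_missing_is_identity(self, random_cohort_factory):
        cohort = random_cohort_factory(seed=4)
        out = knn_impute(cohort, k=3)
        assert np.array_equal(out.X, cohort.X)

    def test_hand_computed_mean_of_two_neighbours(self):
        # subjects 0 and 2 are the only candidates; imputed value = mean(1, 3)
        X = np.array([[1.0, 0.0], [np.nan, 0.0], [3.0, 0.0]])
        cohort = Cohort(list("abc"), X, [0, 1, 0], ["u", "v"], ["continuous"] * 2)
        out = knn_impute(cohort, k=2)
        assert out.X[1, 0] == pytest.approx(2.0)

    def test_observed_cells_bit_identical(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 4))
        miss = rng.random(X.shape) < 0.15
        Xm = X.copy()
        Xm[miss] = np.nan
        cohort = Cohort([str(i) for i in range(20)], Xm, [0, 1] * 10,
                        [f"p{j}" for j in range(4)], ["continuous"] * 4)
        out = knn_impute(cohort, k=3)
        assert np.array_equal(out.X[~miss], X[~miss])
        assert not np.isnan(out.X).any()

    def test_k_clamped_with_warning(self, caplog):
        X = np.array([[1.0, 0.0], [np.nan, 0.0], [3.0, 0.0]])
        cohort = Cohort(list("abc"), X, [0, 1, 0], ["u", "v"], ["continuous"] * 2)
        with caplog.at_level("WARNING"):
            out = knn_impute(cohort, k=10)
        assert "clamping" in caplog.text
        assert out.X[1, 0] == pytest.approx(2.0)

    def test_all_missing_predictor_rejected(self):
        X = np.array([[np.nan, 1.0], [np.nan, 2.0]])
        cohort = Cohort(["a", "b"], X, [0, 1], ["u", "v"], ["continuous"] * 2)
        with pytest.raises(ValueError, match="zero observed"):
            knn_impute(cohort, k=1)


class TestRuleSetFile:
    def test_roundtrip(self, tmp_path):
        scheme = make_value_scheme([2, 3], names=["SMOKER", "GRADE"])
        rules = [
            MinedRule(Rule.from_pairs([(0, 1), (1, 2)]),
                      RuleMetrics(40, 10, 30, 0.5, 0.55, 0.52), "difficult", 3),
            MinedRule(Rule.from_pairs([(1, 0)]),
                      RuleMetrics(100, 30, 70, np.nan, 0.9, 0.9), "easy", 0),
        ]
        write_rules(tmp_path / "r.json", rules, scheme, {"seed": 1})
        back, meta = read_rules(tmp_path / "r.json", scheme)
        assert meta == {"seed": 1}
        assert [mr.rule for mr in back] == [mr.rule for mr in rules]
        assert back[0].metrics == rules[0].metrics
        assert np.isnan(back[1].metrics.tpr)

    def test_invalid_level_rejected(self, tmp_path):
        scheme = make_value_scheme([2, 3])
        rules = [MinedRule(Rule.from_pairs([(1, 2)]), RuleMetrics(1, 1, 0, 1.0, np.nan, 1.0), "easy", 0)]
        write_rules(tmp_path / "r.json", rules, scheme, {})
        small = make_value_scheme([2, 2])  # level 2 no longer valid
        with pytest.raises(ValueError, match="invalid level"):
            read_rules(tmp_path / "r.json", small)
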