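import numpy as np
import pandas as pd
import pytest

from mriqa.classify import (
    ExperimentConfig,
    balanced_subsample,
    build_design_matrix,
    compare_combinations,
    kfold_split,
    permutation_null,
    severity_contrast,
    train_and_evaluate,
)


def _labels(n_usable, n_not):
    return ["usable"] * n_usable + ["not-usable"] * n_not


def _blobs(n_per_class, rng, separation=10.0, sd=0.5):
    x = np.vstack(
        [
            rng.normal(0.0, sd, size=(n_per_class, 2)),
            rng.normal(separation, sd, size=(n_per_class, 2)),
        ]
    )
    y = _labels(n_per_class, n_per_class)
    return x, y


class TestBalancedSubsample:
    def test_equal_class_sizes_from_unbalanced_input(self):
        labels = _labels(1267, 190)
        idx = balanced_subsample(labels, seed=0)
        assert len(idx) == 380
        chosen = np.array(labels)[idx]
        assert (chosen == "usable").sum() == 190
        assert (chosen == "not-usable").sum() == 190

    def test_balanced_input_returns_everything(self):
        idx = balanced_subsample(_labels(7, 7), seed=1)
        np.testing.assert_array_equal(idx, np.arange(14))

    def test_deterministic_under_seed(self):
        labels = _labels(50, 10)
        np.testing.assert_array_equal(
            balanced_subsample(labels, seed=3), balanced_subsample(labels, seed=3)
        )

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_subsample(_labels(5, 0), seed=0)


class TestKfold:
    def test_published_fold_arithmetic(self):
        """380 balanced volumes, 10 folds: 38 test / 342 train each."""
        labels = _labels(190, 190)
        folds = kfold_split(380, k=10, seed=0, labels=labels)
        assert len(folds) == 10
        for train, test in folds:
            assert len(test) == 38 and len(train) == 342

    def test_folds_partition_the_index_range(self):
        folds = kfold_split(53, k=10, seed=2)
        seen = np.concatenate([test for _, test in folds])
        assert sorted(seen) == list(range(53))

    def test_stratification_within_one_sample(self):
        labels = _labels(30, 20)
        folds = kfold_split(50, k=5, seed=0, labels=labels)
        arr = np.array(labels)
        for _, test in folds:
            n_not = (arr[test] == "not-usable").sum()
            assert abs(n_not - 4) <= 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(5, k=10)


class TestTrainAndEvaluate:
    def test_separable_blobs_classified_nearly_perfectly(self, rng):
        x, y = _blobs(100, rng)
        cfg = ExperimentConfig(n_repeats=10, seed=0)
        result = train_and_evaluate(x, y, cfg)
        assert result.accuracy.mean() >= 95.0

    def test_uninformative_features_score_at_chance(self, rng):
        x = rng.normal(size=(120, 3))
        y = _labels(60, 60)
        cfg = ExperimentConfig(n_repeats=30, seed=1)
        result = train_and_evaluate(x, y, cfg)
        se = max(result.accuracy.std(ddof=1) / np.sqrt(30), 100 / np.sqrt(4 * 120))
        assert abs(result.accuracy.mean() - 50.0) < 3 * se

    def test_same_seed_reproduces_result(self, rng):
        x, y = _blobs(30, rng, separation=2.0)
        cfg = ExperimentConfig(n_repeats=5, seed=7, n_folds=5)
        r1 = train_and_evaluate(x, y, cfg)
        r2 = train_and_evaluate(x, y, cfg)
        np.testing.assert_array_equal(r1.accuracy, r2.accuracy)
        np.testing.assert_array_equal(r1.sensitivity, r2.sensitivity)

    def test_balanced_rates_average_to_accuracy(self, rng):
        x, y = _blobs(50, rng, separation=1.5)
        cfg = ExperimentConfig(n_repeats=10, seed=3)
        r = train_and_evaluate(x, y, cfg)
        np.testing.assert_allclose(
            r.accuracy, (r.sensitivity + r.specificity) / 2, atol=1e-9
        )


class TestPermutationNull:
    def test_null_is_at_chance_and_observed_exceeds_it(self, rng):
        x, y = _blobs(40, rng)
        cfg = ExperimentConfig(n_repeats=5, n_permutations=30, seed=2, n_folds=5)
        perm = permutation_null(x, y, cfg)
        se = max(perm.accuracies.std(ddof=1) / np.sqrt(30), 100 / np.sqrt(4 * 80))
        assert abs(perm.accuracies.mean() - 50.0) < 3 * se
        # tiny problem: a lucky shuffle can occasionally match the observed
        # mean, so allow a couple of exceedances out of 30
        assert perm.p_value <= 3 / 31


class TestCompareCombinations:
    @staticmethod
    def _fake_result(mean, sd, n, seed):
        from mriqa.classify import EvaluationResult

        rng = np.random.default_rng(seed)
        acc = np.clip(rng.normal(mean, sd, size=n), 0, 100)
        return EvaluationResult(acc, acc, acc)

    def test_identical_distributions_are_not_different(self):
        a = self._fake_result(80, 2, 200, 0)
        table = compare_combinations({"A": a, "B": a})
        row = table.iloc[0]
        assert row["t"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_clearly_separated_means_flagged(self):
        table = compare_combinations(
            {"hi": self._fake_result(80, 2, 1000, 1),
             "lo": self._fake_result(70, 2, 1000, 2)}
        )
        row = table.iloc[0]
        assert row["p"] < 1e-3 and row["sig_001"]

    def test_unequal_repeat_counts_rejected(self):
        with pytest.raises(ValueError):
            compare_combinations(
                {"a": self._fake_result(80, 2, 100, 0),
                 "b": self._fake_result(80, 2, 50, 1)}
            )


class TestSeverityContrast:
    def test_well_separated_groups_all_significant(self, rng):
        sevs = np.repeat(["none", "slight", "moderate", "heavy"], 20)
        vals = np.concatenate(
            [rng.normal(mu, 0.1, size=20) for mu in (0.0, 1.0, 2.0, 3.0)]
        )
        summary, pairs = severity_contrast(vals, sevs)
        assert list(summary["severity"]) == ["none", "slight", "moderate", "heavy"]
        assert (pairs["p"] < 1e-3).all()

    def test_null_groups_mostly_not_significant(self, rng):
        sevs = np.repeat(["none", "slight"], 30)
        vals = rng.normal(0, 1, size=60)
        _, pairs = severity_contrast(vals, sevs)
        assert pairs.loc[0, "p"] > 0.01

    def test_single_group_gives_empty_pair_table(self, rng):
        summary, pairs = severity_contrast(rng.normal(size=10), ["heavy"] * 10)
        assert len(summary) == 1
        assert pairs.empty

    def test_singleton_group_marked_untestable(self, rng):
        vals = np.concatenate([rng.normal(size=10), [5.0]])
        sevs = ["none"] * 10 + ["heavy"]
        _, pairs = severity_contrast(vals, sevs)
        assert not pairs.loc[0, "testable"]
        assert np.isnan(pairs.loc[0, "p"])


class TestDesignMatrix:
    def test_group_columns_stack_in_order(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["a"],
                "vf3": [1.5],
                "asf1": [2.0],
                "asf2": [3.0],
                "asf3": [4.0],
                **{f"vf1_{i:03d}": [i] for i in range(100)},
                **{
                    f"vf2{c}_{i:03d}": [0]
                    for c in ("gm", "wm", "csf")
                    for i in range(100)
                },
            }
        )
        x = build_design_matrix(frame, ("ASF1", "ASF3", "VF3"))
        np.testing.assert_array_equal(x, [[2.0, 4.0, 1.5]])

    def test_histogram_normalization_divides_by_row_total(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["a"],
                "vf3": [0.0],
                "asf1": [0.0],
                "asf2": [0.0],
                "asf3": [0.0],
                **{f"vf1_{i:03d}": [1] for i in range(100)},
                **{
                    f"vf2{c}_{i:03d}": [0]
                    for c in ("gm", "wm", "csf")
                    for i in range(100)
                },
            }
        )
        x = build_design_matrix(frame, ("VF1",), normalize_histograms=True)
        np.testing.assert_allclose(x, np.full((1, 100), 0.01))

    def test_invalid_combination_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(feature_combination=("VF9",))
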