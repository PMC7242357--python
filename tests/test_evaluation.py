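"""Evaluation stack: weighted F1, stratified folds, repeated CV, learning
curves, the balanced protocol, grid search, BBC-CV and RFE."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import f1_score

from helpers import confusion_f1, gaussian_dataset, one_hot_dataset
from oaprogress import evaluation
from oaprogress.evaluation import (
    CVPlan,
    balanced_comparison,
    balanced_subsample,
    bbc_cv,
    default_tuning_grid,
    grid_search,
    learning_curve,
    prediction_tensor,
    rfe_select,
    run_repeated_cv,
    stratified_folds,
    weighted_f1,
)
from oaprogress.models import ModelConfig


class TestWeightedF1:
    def test_perfect_predictions(self):
        assert weighted_f1(["N", "P", "S"], ["N", "P", "S"]) == 1.0

    def test_hand_confusion_example(self):
        # F1_N = 6/7 with weight 3/4; F1_P = 0 with weight 1/4 -> 9/14
        score = weighted_f1(["N", "N", "N", "P"], ["N", "N", "N", "N"])
        assert score == pytest.approx(9 / 14)

    def test_equals_macro_for_balanced_classes(self):
        truths = ["A", "A", "B", "B"]
        preds = ["A", "B", "B", "B"]
        assert weighted_f1(truths, preds) == pytest.approx(
            f1_score(truths, preds, average="macro"))

    def test_agrees_with_independent_oracles(self):
        rng = np.random.default_rng(0)
        classes = np.array(["N", "P", "S", "P+S"], dtype=object)
        for _ in range(100):
            t = classes[rng.integers(0, 4, 60)]
            p = classes[rng.integers(0, 4, 60)]
            ours = weighted_f1(t, p)
            assert ours == pytest.approx(confusion_f1(t, p), abs=1e-12)
            assert ours == pytest.approx(
                f1_score(t, p, average="weighted", zero_division=0), abs=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            weighted_f1([], [])


class TestStratifiedFolds:
    def test_fold_counts_within_one(self):
        y = ["A"] * 63 + ["B"] * 12 + ["C"] * 20 + ["D"] * 5
        folds = stratified_folds(y, 10, seed=1)
        y = np.asarray(y, dtype=object)
        for cls, total in (("A", 63), ("B", 12), ("C", 20), ("D", 5)):
            per_fold = [int(((folds == k) & (y == cls)).sum()) for k in range(10)]
            assert max(per_fold) - min(per_fold) <= 1
            assert sum(per_fold) == total

    def test_partition_properties(self):
        y = ["A"] * 30 + ["B"] * 10
        folds = stratified_folds(y, 4, seed=2)
        assert sorted(np.unique(folds)) == [0, 1, 2, 3]
        assert len(folds) == 40

    def test_single_fold_is_whole_set(self):
        assert (stratified_folds(["A", "B"], 1, seed=0) == 0).all()

    def test_more_folds_than_instances_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(["A", "B"], 3, seed=0)

    def test_deterministic(self):
        y = ["A"] * 20 + ["B"] * 20
        assert (stratified_folds(y, 5, 7) == stratified_folds(y, 5, 7)).all()


class TestRepeatedCV:
    def test_oracle_features_score_one(self):
        X, y = one_hot_dataset(200, seed=1)
        plan = CVPlan(n_folds=5, n_repeats=2, n_seeds=2, master_seed=0)
        res = run_repeated_cv(X, y, ModelConfig(n_trees=20, max_depth=6), plan)
        assert (res.scores["score"] == 1.0).all()
        assert res.median_of_medians().iloc[0] == 1.0

    def test_single_run_equals_direct_pooled_score(self):
        X, y = gaussian_dataset(200, seed=2)
        plan = CVPlan(n_folds=5, n_repeats=1, n_seeds=1, master_seed=3)
        cfg = ModelConfig(n_trees=20, max_depth=4)
        res = run_repeated_cv(X, y, cfg, plan)
        assert len(res.scores) == 1
        direct = weighted_f1(res.predictions["true"], res.predictions["pred"])
        assert res.scores["score"].iloc[0] == pytest.approx(direct)

    def test_pooled_score_is_order_invariant(self):
        X, y = gaussian_dataset(200, seed=3)
        plan = CVPlan(n_folds=4, n_repeats=1, n_seeds=1, master_seed=1)
        res = run_repeated_cv(X, y, ModelConfig(n_trees=10, max_depth=3), plan)
        preds = res.predictions.sample(frac=1.0, random_state=0)
        assert weighted_f1(preds["true"], preds["pred"]) == pytest.approx(
            res.scores["score"].iloc[0])

    def test_median_of_medians_within_score_range(self):
        X, y = gaussian_dataset(250, seed=4)
        plan = CVPlan(n_folds=5, n_repeats=2, n_seeds=3, master_seed=5)
        res = run_repeated_cv(X, y, ModelConfig(n_trees=20, max_depth=4), plan)
        mom = res.median_of_medians().iloc[0]
        assert res.scores["score"].min() <= mom <= res.scores["score"].max()

    def test_every_instance_predicted_once_per_run(self):
        X, y = gaussian_dataset(120, seed=5)
        plan = CVPlan(n_folds=4, n_repeats=2, n_seeds=1, master_seed=2)
        res = run_repeated_cv(X, y, ModelConfig(n_trees=10, max_depth=3), plan)
        counts = res.predictions.groupby(["repeat", "seed", "config_id"])[
            "instance_id"].nunique()
        assert (counts == len(X)).all()

    def test_deterministic_given_plan(self):
        X, y = gaussian_dataset(150, seed=6)
        plan = CVPlan(n_folds=3, n_repeats=1, n_seeds=2, master_seed=11)
        cfg = ModelConfig(n_trees=10, max_depth=3)
        a = run_repeated_cv(X, y, cfg, plan)
        b = run_repeated_cv(X, y, cfg, plan)
        pd.testing.assert_frame_equal(a.scores, b.scores)
        pd.testing.assert_frame_equal(a.predictions, b.predictions)


class TestLearningCurve:
    def test_full_fraction_reproduces_repeated_cv(self):
        X, y = gaussian_dataset(200, seed=7)
        plan = CVPlan(n_folds=4, n_repeats=1, n_seeds=2, master_seed=4)
        cfg = ModelConfig(n_trees=15, max_depth=4)
        curve = learning_curve(X, y, cfg, [1.0], plan)
        res = run_repeated_cv(X, y, cfg, plan)
        a = curve.sort_values(["repeat", "seed"])["score"].to_numpy()
        b = res.scores.sort_values(["repeat", "seed"])["score"].to_numpy()
        np.testing.assert_allclose(a, b)

    def test_non_decreasing_on_strong_signal(self):
        X, y = gaussian_dataset(400, seed=8, separation=2.5)
        plan = CVPlan(n_folds=4, n_repeats=1, n_seeds=1, master_seed=6)
        cfg = ModelConfig(n_trees=30, max_depth=6)
        curve = learning_curve(X, y, cfg, [0.2, 0.5, 1.0], plan)
        summary = evaluation.summarize_curve(curve)
        medians = summary.sort_values("fraction")["median"].to_numpy()
        assert all(b >= a - 0.05 for a, b in zip(medians, medians[1:]))


class TestBalancedProtocol:
    def test_subsample_sizes_and_error(self):
        y = ["N"] * 70 + ["P"] * 12 + ["S"] * 20 + ["P+S"] * 8
        idx = balanced_subsample(y, 8, seed=0)
        sub = np.asarray(y, dtype=object)[idx]
        assert len(idx) == 32
        assert all((sub == c).sum() == 8 for c in ("N", "P", "S", "P+S"))
        with pytest.raises(ValueError):
            balanced_subsample(y, 9, seed=0)

    def test_arms_share_test_partitions(self):
        X, y = gaussian_dataset(200, seed=9)
        plan = CVPlan(n_folds=4, n_repeats=2, n_seeds=1, master_seed=7)
        out = balanced_comparison(X, y, ModelConfig(n_trees=10, max_depth=3),
                                  plan, n_samplings=2)
        for repeat in range(plan.n_repeats):
            np.testing.assert_array_equal(
                out["folds"][repeat],
                stratified_folds(y, plan.n_folds, plan.fold_seed(repeat)))
        assert out["balanced"]["sampling"].nunique() == 2


class TestGridSearch:
    def test_tuning_grid_size(self):
        assert len(default_tuning_grid()) == 84

    def test_grid_of_one(self):
        X, y = gaussian_dataset(150, seed=10)
        cfg = ModelConfig(n_trees=10, max_depth=3)
        plan = CVPlan(n_folds=3, n_repeats=1, n_seeds=1, master_seed=8)
        assert grid_search(X, y, [cfg], plan).best_config == cfg

    def test_tie_breaks_to_lower_depth(self):
        X, y = one_hot_dataset(200, seed=11)  # every config scores 1.0
        grid = [ModelConfig(n_trees=20, max_depth=8),
                ModelConfig(n_trees=20, max_depth=4)]
        plan = CVPlan(n_folds=3, n_repeats=1, n_seeds=1, master_seed=9)
        assert grid_search(X, y, grid, plan).best_config.max_depth == 4

    def test_tie_breaks_to_fewer_trees_then_gini(self):
        X, y = one_hot_dataset(200, seed=12)
        grid = [ModelConfig(n_trees=40, max_depth=4, criterion="entropy"),
                ModelConfig(n_trees=20, max_depth=4, criterion="entropy"),
                ModelConfig(n_trees=20, max_depth=4, criterion="gini")]
        plan = CVPlan(n_folds=3, n_repeats=1, n_seeds=1, master_seed=10)
        best = grid_search(X, y, grid, plan).best_config
        assert (best.n_trees, best.criterion) == (20, "gini")

    def test_recovers_required_depth(self):
        """Signal realizable only at depth >= 2 (XOR): the deeper
        configuration must win in at least 4 of 5 seeds."""
        wins = 0
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            n = 400
            x1, x2 = rng.integers(0, 2, n), rng.integers(0, 2, n)
            X = pd.DataFrame({"x1": x1 + rng.normal(0, 0.05, n),
                              "x2": x2 + rng.normal(0, 0.05, n)})
            y = pd.Series(np.where((x1 ^ x2) == 1, "P", "N"))
            grid = [ModelConfig(strategy="single", n_trees=30, max_depth=d)
                    for d in (1, 2)]
            plan = CVPlan(n_folds=5, n_repeats=1, n_seeds=1, master_seed=s)
            wins += grid_search(X, y, grid, plan).best_config.max_depth >= 2
        assert wins >= 4


class TestBBCCV:
    def make_tensor(self, n=300, c=1, r=2, seed=0):
        rng = np.random.default_rng(seed)
        true = rng.choice(4, n, p=[0.63, 0.12, 0.20, 0.05])
        # predictions correct with probability .7
        preds = np.where(rng.random((c, r, n)) < 0.7, true,
                         rng.integers(0, 4, (c, r, n)))
        return preds, true

    def test_single_configuration_estimate_near_pooled_score(self):
        preds, true = self.make_tensor()
        pooled = evaluation._score_runs(preds[0], true, 4, "concatenate")
        res = bbc_cv(preds, true, B=400, seed=1)
        assert res.estimate == pytest.approx(pooled, abs=0.02)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_duplicated_configurations_change_nothing(self):
        preds, true = self.make_tensor()
        dup = np.concatenate([preds, preds, preds], axis=0)
        a = bbc_cv(preds, true, B=200, seed=2)
        b = bbc_cv(dup, true, B=200, seed=2)
        assert a.estimate == pytest.approx(b.estimate)

    def test_aggregation_variants_agree_on_identical_runs(self):
        preds, true = self.make_tensor(r=1)
        preds = np.repeat(preds, 3, axis=1)  # identical runs
        a = bbc_cv(preds, true, B=100, seed=3, aggregation="concatenate")
        b = bbc_cv(preds, true, B=100, seed=3, aggregation="mean_over_runs")
        assert a.estimate == pytest.approx(b.estimate)

    def test_prediction_tensor_roundtrip(self):
        X, y = gaussian_dataset(120, seed=13)
        plan = CVPlan(n_folds=3, n_repeats=2, n_seeds=2, master_seed=12)
        res = run_repeated_cv(X, y, ModelConfig(n_trees=10, max_depth=3), plan)
        preds, true, configs, labels = prediction_tensor(res.predictions)
        assert preds.shape == (1, 4, len(X))
        assert len(true) == len(X)
        assert (preds >= 0).all()


class TestRFE:
    def make_features(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        y_idx = rng.choice(4, n, p=[0.63, 0.12, 0.20, 0.05])
        X = pd.DataFrame(rng.normal(0, 1, (n, 5)),
                         columns=[f"n{i}" for i in range(5)])
        X["signal"] = y_idx + rng.normal(0, 0.3, n)
        classes = np.array(["N", "P", "S", "P+S"], dtype=object)
        return X, pd.Series(classes[y_idx], index=X.index)

    def test_elimination_path_length(self):
        X, y = self.make_features()
        cfg = ModelConfig(strategy="single", n_trees=15, max_depth=4)
        selected, path = rfe_select(X, y, cfg, seed=1)
        assert list(path["n_features"]) == list(range(X.shape[1], 0, -1))
        assert len(path) == X.shape[1]

    def test_informative_feature_survives(self):
        X, y = self.make_features()
        cfg = ModelConfig(strategy="single", n_trees=15, max_depth=4)
        selected, path = rfe_select(X, y, cfg, seed=2)
        assert "signal" in selected
        assert path.iloc[-1]["features"] == ("signal",)

    def test_requires_two_features(self):
        X, y = self.make_features()
        with pytest.raises(ValueError):
            rfe_select(X[["signal"]], y, ModelConfig(strategy="single"))
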