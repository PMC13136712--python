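"""Fold construction, leakage guarantees and training contracts."""

import numpy as np
import pytest

from featkit.core_io import FeatureMatrix
from featkit.encoders import EncoderSpec
from featkit.modeling import (
    ModelSpec,
    assert_no_group_leakage,
    load_model,
    make_folds,
    predict,
    random_search,
    run_experiment,
    save_model,
    train,
)
from featkit.preprocess import inverse_log_transform
from featkit.synthetic_data import KOSimParams, simulate_ko

TINY_SPEC = ModelSpec(n_trees=30, max_depth=3, seed=0)


def _matrix(rng, n=200, p=10, names=None):
    names = names or [f"f{i}" for i in range(p)]
    return FeatureMatrix("OH", names, rng.normal(size=(n, p)))


class TestMakeFolds:
    def test_110_groups_into_10_folds_of_11(self):
        groups = [f"g{i}" for i in range(110) for _ in range(3)]
        plan = make_folds(groups, "leave_k_groups_out", k=10, seed=0)
        test_sets = [set(chunk) for chunk in plan.test_groups]
        assert all(len(s) == 11 for s in test_sets)
        for a, b in zip(test_sets, test_sets[1:]):
            assert not (a & b)
        assert set().union(*test_sets) == set(groups)

    def test_leave_one_group_out(self):
        groups = ["a", "a", "b", "c", "c", "c"]
        plan = make_folds(groups, "leave_one_group_out", seed=1)
        assert plan.n_folds == 3
        assert sorted(len(chunk) for chunk in plan.test_groups) == [1, 1, 1]

    def test_test_sets_exhaustive_and_disjoint(self):
        groups = [f"g{i % 7}" for i in range(50)]
        plan = make_folds(groups, "leave_k_groups_out", k=3, seed=2)
        all_test = np.concatenate([test for _, test in plan.folds])
        assert sorted(all_test) == list(range(50))
        assert_no_group_leakage(plan, groups)

    def test_kfold_ignores_groups(self):
        plan = make_folds(["g"] * 20, "kfold", k=4, seed=0)
        assert plan.n_folds == 4
        all_test = np.concatenate([test for _, test in plan.folds])
        assert sorted(all_test) == list(range(20))

    def test_k_larger_than_groups_errors(self):
        with pytest.raises(ValueError, match="exceed"):
            make_folds(["a", "b"], "leave_k_groups_out", k=3)

    def test_leakage_assertion_fires(self):
        plan = make_folds(["a", "a", "b", "b"], "leave_one_group_out")
        # corrupt the plan: put one test sample into train as well
        bad = plan.folds[0][1][:1]
        plan.folds[0] = (np.concatenate([plan.folds[0][0], bad]), plan.folds[0][1])
        with pytest.raises(AssertionError):
            assert_no_group_leakage(plan, ["a", "a", "b", "b"])


class TestTrainPredict:
    def test_training_is_deterministic(self, rng):
        X = _matrix(rng)
        y = (rng.random(200) < 0.3).astype(float)
        probe = _matrix(np.random.default_rng(1), n=50)
        p1 = predict(train(X, y, None, TINY_SPEC), probe)
        p2 = predict(train(X, y, None, TINY_SPEC), probe)
        assert np.array_equal(p1, p2)

    def test_probabilities_bounded(self, rng):
        X = _matrix(rng)
        y = (rng.random(200) < 0.3).astype(float)
        scores = predict(train(X, y, None, TINY_SPEC), X)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_permuted_columns_error_not_silent_reorder(self, rng):
        X = _matrix(rng)
        y = (rng.random(200) < 0.3).astype(float)
        model = train(X, y, None, TINY_SPEC)
        permuted = FeatureMatrix("OH", X.feature_names[::-1], X.values[:, ::-1])
        with pytest.raises(ValueError, match="schema"):
            predict(model, permuted)

    def test_nan_features_rejected(self, rng):
        X = _matrix(rng)
        X.values[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            train(X, np.ones(200), None, TINY_SPEC)

    def test_single_class_target_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            train(_matrix(rng), np.ones(200), None, TINY_SPEC)

    def test_regression_back_transform_bound(self, rng):
        X = _matrix(rng)
        y = np.log1p(rng.integers(0, 1000, size=200).astype(float))
        spec = ModelSpec(task="regression", n_trees=30, seed=0)
        counts = inverse_log_transform(predict(train(X, y, None, spec), X))
        assert np.all(counts >= -1.0)

    def test_pure_noise_targets_score_near_prevalence(self):
        # held-out AUPR of a model fit to noise ~ class prevalence
        from featkit.metrics import pr_curve

        prevalence, auprs = 0.1, []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = _matrix(rng, n=600)
            y = (rng.random(600) < prevalence).astype(float)
            model = train(
                FeatureMatrix("OH", X.feature_names, X.values[:400]),
                y[:400],
                None,
                ModelSpec(n_trees=30, max_depth=3, seed=seed),
            )
            held = FeatureMatrix("OH", X.feature_names, X.values[400:])
            auprs.append(pr_curve(y[400:], predict(model, held)).aupr)
        assert 0.03 < np.mean(auprs) < 0.25

    def test_save_load_round_trip(self, rng, tmp_path):
        X = _matrix(rng)
        y = (rng.random(200) < 0.3).astype(float)
        model = train(X, y, None, TINY_SPEC)
        path = save_model(model, tmp_path / "model.json")
        loaded = load_model(path)
        assert loaded.feature_names == model.feature_names
        assert np.allclose(predict(loaded, X), predict(model, X))


class TestRandomSearch:
    def test_single_iteration_returns_that_spec(self, rng):
        X = _matrix(rng, n=80)
        y = (rng.random(80) < 0.4).astype(float)
        plan = make_folds(["g"] * 80, "kfold", k=2, seed=0)
        space = {"max_depth": ("int", 2, 4), "n_trees": ("int", 10, 20)}
        best, table = random_search(X, y, None, plan, space, n_iter=1, seed=3)
        assert len(table) == 1
        assert best.max_depth == int(table.iloc[0]["max_depth"])

    def test_fixed_seed_reproducible_candidates(self, rng):
        X = _matrix(rng, n=80)
        y = (rng.random(80) < 0.4).astype(float)
        plan = make_folds(["g"] * 80, "kfold", k=2, seed=0)
        space = {"max_depth": ("int", 2, 5), "n_trees": ("int", 10, 25)}
        _, t1 = random_search(X, y, None, plan, space, n_iter=4, seed=7)
        _, t2 = random_search(X, y, None, plan, space, n_iter=4, seed=7)
        assert t1[["max_depth", "n_trees", "cv_score"]].equals(
            t2[["max_depth", "n_trees", "cv_score"]]
        )

    def test_best_is_argmax_over_sampled_set(self, rng):
        X = _matrix(rng, n=80)
        y = (rng.random(80) < 0.4).astype(float)
        plan = make_folds(["g"] * 80, "kfold", k=2, seed=0)
        space = {"max_depth": ("int", 2, 6)}
        best, table = random_search(X, y, None, plan, space, n_iter=5, seed=1)
        assert table["cv_score"].max() == table.loc[
            table["max_depth"] == best.max_depth, "cv_score"
        ].max()


@pytest.fixture(scope="module")
def small_ko():
    return simulate_ko(KOSimParams(n_guides=6, sites_per_guide=120, seed=4))


class TestRunExperiment:
    def test_every_record_predicted_exactly_once(self, small_ko):
        plan = make_folds(small_ko.guide_ids, "leave_one_group_out", seed=0)
        result = run_experiment(
            small_ko, EncoderSpec("MM", with_distance=True), "classification",
            plan, ModelSpec(n_trees=40, seed=0),
        )
        assert sorted(result.predictions["index"]) == list(range(len(small_ko)))

    def test_no_test_guide_seen_in_training(self, small_ko):
        plan = make_folds(small_ko.guide_ids, "leave_k_groups_out", k=3, seed=0)
        result = run_experiment(
            small_ko, EncoderSpec("MM"), "classification", plan,
            ModelSpec(n_trees=40, seed=0),
        )
        for fold_id, chunk in enumerate(result.fold_plan.test_groups):
            fold_rows = result.predictions[result.predictions["fold"] == fold_id]
            assert set(fold_rows["guide_id"]) <= set(chunk)

    def test_weighting_changes_predictions_on_imbalanced_data(self, small_ko):
        from featkit.encoders import encode_dataset
        from featkit.preprocess import binary_labels, label_ko_by_count, sample_weights

        labeled = label_ko_by_count(small_ko)
        X = encode_dataset(labeled, EncoderSpec("OH", with_distance=True))
        y = binary_labels(labeled)
        spec = ModelSpec(n_trees=40, seed=0)
        weighted = predict(train(X, y, sample_weights(labeled), spec), X)
        unweighted = predict(train(X, y, None, spec), X)
        assert not np.allclose(weighted, unweighted)

    def test_regression_experiment_reports_active_only_correlation(self, small_ko):
        plan = make_folds(small_ko.guide_ids, "leave_k_groups_out", k=3, seed=0)
        result = run_experiment(
            small_ko, EncoderSpec("MM", with_distance=True), "regression",
            plan, ModelSpec(task="regression", n_trees=40, seed=0),
        )
        assert "pearson" in result.aggregate
        assert all("rmse" in fold for fold in result.per_fold)
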