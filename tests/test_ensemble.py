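import numpy as np
import pytest

from pssmstack import (
    BASE_ORDER,
    BaseConfig,
    FeatureTable,
    TrainedStack,
    build_estimator,
    combine_votes,
    default_base_configs,
    fit_stack,
    generate_oof,
    grid_search,
    make_folds,
    predict,
    voting_predict,
)

from .conftest import fast_configs


def separable_table(n_per_class=30, d=6, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1] * n_per_class + [0] * n_per_class)
    X = rng.normal(size=(2 * n_per_class, d))
    X[: n_per_class, :3] += gap
    return FeatureTable(
        ids=[f"s{i}" for i in range(2 * n_per_class)],
        names=[f"f{j}" for j in range(d)],
        values=X,
        labels=y,
    )


class TestConfigs:
    def test_default_hyperparameters(self):
        gbm, svm, ert = default_base_configs()
        assert gbm.param_dict["n_estimators"] == 400
        assert gbm.param_dict["learning_rate"] == 0.05
        assert gbm.param_dict["max_depth"] == 7
        assert gbm.param_dict["subsample"] == 0.8
        assert svm.param_dict["C"] == 19.0
        assert svm.param_dict["gamma"] == 0.018
        assert ert.param_dict["n_estimators"] == 100
        assert ert.param_dict["min_samples_split"] == 2
        assert ert.param_dict["min_samples_leaf"] == 1
        assert tuple(c.family for c in (gbm, svm, ert)) == BASE_ORDER

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            BaseConfig("random_forest")

    def test_built_estimators_carry_the_configured_values(self):
        gbm, svm, ert = (build_estimator(c, seed=0) for c in default_base_configs())
        assert gbm.n_estimators == 400 and gbm.max_depth == 7
        assert ert.n_estimators == 100
        assert svm.estimator.C == 19.0 and svm.estimator.gamma == 0.018


class TestFolds:
    def test_even_partition(self):
        folds = make_folds([f"s{i}" for i in range(100)], k=10, seed=0)
        sizes = np.bincount(list(folds.values()))
        assert np.all(sizes == 10)

    def test_uneven_sizes_differ_by_at_most_one(self):
        folds = make_folds([f"s{i}" for i in range(23)], k=10, seed=1)
        sizes = np.bincount(list(folds.values()), minlength=10)
        assert set(sizes) <= {2, 3} and sizes.sum() == 23

    def test_union_is_everything_and_deterministic(self):
        ids = [f"s{i}" for i in range(37)]
        a = make_folds(ids, k=5, seed=3)
        b = make_folds(ids, k=5, seed=3)
        assert set(a) == set(ids) and a == b

    def test_stratified_folds_keep_both_classes(self):
        t = separable_table(10)
        folds = make_folds(t.ids, k=5, seed=0, labels=t.labels)
        for f in range(5):
            members = [i for i, fold in folds.items() if fold == f]
            labs = {t.labels[t.ids.index(m)] for m in members}
            assert labs == {0, 1}

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError, match="at least"):
            make_folds(["a", "b"], k=10, seed=0)


class TestOof:
    def test_probabilities_in_unit_interval_and_definition(self):
        t = separable_table(15, seed=2)
        folds = make_folds(t.ids, k=5, seed=0, labels=t.labels)
        oof, names = generate_oof(t, fast_configs(), folds, seed=0)
        assert oof.shape == (30, 3)
        assert names == ["lightgbm", "svm_rbf", "extra_trees"]
        assert np.all((oof >= 0) & (oof <= 1))
        # definition restated: retraining base m without fold(i) reproduces (i, m)
        fold_of = np.array([folds[i] for i in t.ids])
        check_fold = 0
        train = fold_of != check_fold
        val = ~train
        for m, config in enumerate(fast_configs()):
            est = build_estimator(config, seed=0)
            est.fit(t.values[train], t.labels[train])
            proba = est.predict_proba(t.values[val])[:, list(est.classes_).index(1)]
            np.testing.assert_allclose(oof[val, m], proba, rtol=1e-9)

    def test_separable_data_oof_columns_are_accurate(self):
        t = separable_table(40, gap=5.0, seed=3)
        folds = make_folds(t.ids, k=5, seed=0, labels=t.labels)
        oof, _ = generate_oof(t, fast_configs(), folds, seed=0)
        for m in range(3):
            acc = np.mean((oof[:, m] >= 0.5).astype(int) == t.labels)
            assert acc > 0.95

    def test_single_class_training_complement_errors(self):
        t = separable_table(6, seed=4)
        # adversarial folds: all positives in fold 0, all negatives in fold 1
        folds = {i: (0 if t.labels[j] == 1 else 1) for j, i in enumerate(t.ids)}
        with pytest.raises(ValueError, match="single class"):
            generate_oof(t, fast_configs(), folds, seed=0)

    def test_no_leakage_label_perturbation(self):
        """Flipping one sample's label never changes that sample's OOF row."""
        t = separable_table(10, seed=5)
        folds = make_folds(t.ids, k=4, seed=0, labels=t.labels)
        baseline, _ = generate_oof(t, fast_configs(), folds, seed=0)
        for i in (0, 7, 19):
            flipped = FeatureTable(
                ids=t.ids, names=t.names, values=t.values, labels=t.labels.copy()
            )
            flipped.labels[i] = 1 - flipped.labels[i]
            perturbed, _ = generate_oof(flipped, fast_configs(), folds, seed=0)
            np.testing.assert_array_equal(perturbed[i], baseline[i])


class TestStack:
    def test_fit_predict_and_oof_floor(self):
        t = separable_table(25, gap=4.0, seed=6)
        stack = fit_stack(t, fast_configs(), k=5, seed=0)
        labels, proba = predict(stack, t)
        assert np.all((proba >= 0) & (proba <= 1))
        stack_acc = np.mean(labels == t.labels)
        for m in range(3):
            base_acc = np.mean((stack.oof_matrix[:, m] >= 0.5).astype(int) == t.labels)
            assert stack_acc >= base_acc - 0.02

    def test_determinism_of_meta_coefficients(self):
        t = separable_table(20, seed=7)
        a = fit_stack(t, fast_configs(), k=5, seed=11)
        b = fit_stack(t, fast_configs(), k=5, seed=11)
        np.testing.assert_allclose(a.meta_model.coef_, b.meta_model.coef_, rtol=1e-8)
        np.testing.assert_array_equal(a.oof_matrix, b.oof_matrix)

    def test_n_smaller_than_k_errors(self):
        t = separable_table(3, seed=8)
        with pytest.raises(ValueError, match="at least"):
            fit_stack(t, fast_configs(), k=10, seed=0)

    def test_feature_mismatch_errors_with_names(self):
        t = separable_table(20, seed=9)
        stack = fit_stack(t, fast_configs(), k=5, seed=0)
        wrong = FeatureTable(
            ids=t.ids, names=[f"g{j}" for j in range(6)], values=t.values, labels=t.labels
        )
        with pytest.raises(ValueError, match="feature mismatch"):
            predict(stack, wrong)

    def test_persistence_round_trip(self, tmp_path):
        t = separable_table(20, seed=10)
        stack = fit_stack(t, fast_configs(), k=5, seed=0)
        path = tmp_path / "stack.joblib"
        stack.save(path)
        loaded = TrainedStack.load(path)
        l1, p1 = predict(stack, t)
        l2, p2 = predict(loaded, t)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_allclose(p1, p2)


class TestVoting:
    def test_unanimous_and_majority_agreement(self):
        t = separable_table(20, gap=5.0, seed=11)
        hard = voting_predict(t, fast_configs(), mode="hard", k=5, seed=0)
        soft = voting_predict(t, fast_configs(), mode="soft", k=5, seed=0)
        # on cleanly separable data, both voting modes recover the labels
        assert np.mean(hard == t.labels) > 0.95
        assert np.mean(soft == t.labels) > 0.95

    def test_soft_and_hard_disagree_on_crafted_probabilities(self):
        # mean 0.6 -> soft positive, but only 1 of 3 bases votes positive
        proba = np.array([[0.9, 0.45, 0.45]])
        assert combine_votes(proba, "soft")[0] == 1
        assert combine_votes(proba, "hard")[0] == 0
        unanimous = np.array([[0.8, 0.7, 0.9], [0.1, 0.2, 0.3]])
        np.testing.assert_array_equal(combine_votes(unanimous, "hard"), [1, 0])
        np.testing.assert_array_equal(combine_votes(unanimous, "soft"), [1, 0])

    def test_held_out_voting(self):
        train = separable_table(20, gap=4.0, seed=12)
        test = separable_table(10, gap=4.0, seed=13)
        pred = voting_predict(train, fast_configs(), mode="soft", test_table=test, seed=0)
        assert np.mean(pred == test.labels) > 0.9

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            voting_predict(separable_table(10), fast_configs(), mode="average")


class TestGridSearch:
    def test_singleton_grid_returns_it(self):
        t = separable_table(15, seed=14)
        only = fast_configs()[2]
        assert grid_search([only], t, cv=3, seed=0) == only

    def test_degenerate_config_loses_on_separable_data(self):
        t = separable_table(25, gap=4.0, seed=15)
        weak = BaseConfig("extra_trees", (("n_estimators", 1), ("min_samples_leaf", 20)))
        strong = BaseConfig("extra_trees", (("n_estimators", 50),))
        best = grid_search([weak, strong], t, cv=3, seed=0)
        assert best == strong

    def test_determinism(self):
        t = separable_table(15, seed=16)
        space = [fast_configs()[0], fast_configs()[2]]
        assert grid_search(space, t, cv=3, seed=5) == grid_search(space, t, cv=3, seed=5)
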