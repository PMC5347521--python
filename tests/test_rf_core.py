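import numpy as np
import pytest

from cropshift.rf_core import (
    FeatureTable,
    Forest,
    RegressionTree,
    default_mtry,
    fit_forest,
    fit_tree,
    oob_error,
    permutation_importance,
    predict,
)


def make_constant_forest(values, n_rows):
    """Hand-built forest of single-leaf trees (each in-bag on row 0 only,
    so every other row is OOB for every tree)."""
    trees = [RegressionTree.constant(v) for v in values]
    boots = [np.array([0]) for _ in values]
    return Forest(trees, boots, n_rows, mtry=1, min_leaf=1, seed=None,
                  categorical=np.zeros(1, dtype=bool), columns=["x0"])


class TestFitTree:
    def test_constant_response_gives_single_leaf(self, table_factory):
        t = table_factory(np.arange(8).reshape(8, 1), np.full(8, 0.3))
        tree = fit_tree(t, np.arange(8), mtry=1, min_leaf=1,
                        rng=np.random.default_rng(0))
        assert tree.n_leaves == 1
        assert tree.predict(t.X, t.categorical) == pytest.approx(0.3)

    def test_fully_grown_tree_fits_training_exactly(self, table_factory):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0.1, 0.7, 0.2, 0.9])
        t = table_factory(X, y)
        tree = fit_tree(t, np.arange(4), mtry=1, min_leaf=1,
                        rng=np.random.default_rng(0))
        assert np.allclose(tree.predict(X, t.categorical), y)

    def test_root_split_finds_informative_binary_feature(self, table_factory, oracles):
        # feature 1 separates y perfectly; feature 0 is noise
        X = np.array([[0.3, 0.0], [0.9, 0.0], [0.1, 0.0],
                      [0.5, 1.0], [0.2, 1.0], [0.8, 1.0]])
        y = np.array([0.1, 0.12, 0.11, 0.8, 0.82, 0.81])
        t = table_factory(X, y)
        tree = fit_tree(t, np.arange(6), mtry=2, min_leaf=1,
                        rng=np.random.default_rng(0))
        want = oracles["best_split"](X, y, min_leaf=1)
        assert tree.feature[0] == want[1] == 1
        assert tree.threshold[0] == pytest.approx(want[3])

    @pytest.mark.parametrize("seed", range(8))
    def test_splits_match_exhaustive_enumeration(self, table_factory, oracles, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        p = int(rng.integers(1, 4))
        X = np.round(rng.random((n, p)) * 4) / 4  # coarse values force ties
        y = np.round(rng.random(n) * 8) / 8
        t = table_factory(X, y)
        tree = fit_tree(t, np.arange(n), mtry=p, min_leaf=1,
                        rng=np.random.default_rng(0))
        want = oracles["best_split"](X, y, min_leaf=1)
        if want is None or np.all(y == y[0]):
            return
        assert tree.feature[0] == want[1]
        assert tree.threshold[0] == pytest.approx(want[3])

    def test_categorical_split_matches_enumeration(self, table_factory, oracles):
        X = np.array([[0.0], [1.0], [2.0], [0.0], [1.0], [2.0], [3.0], [3.0]])
        y = np.array([0.1, 0.9, 0.15, 0.12, 0.88, 0.1, 0.92, 0.9])
        t = table_factory(X, y, categorical=[True],
                          categories={0: np.arange(4.0)})
        tree = fit_tree(t, np.arange(8), mtry=1, min_leaf=1,
                        rng=np.random.default_rng(0))
        want = oracles["best_split"](X, y, min_leaf=1, features={0})
        assert tree.feature[0] == 0
        got_mask = int(tree.mask_left[0])
        # oracle mask always contains level 0; the implementation's mask may
        # be either side of the same bipartition
        seen = int(tree.mask_seen[0])
        assert got_mask in (want[3], seen ^ want[3])

    def test_empty_rows_rejected(self, table_factory):
        t = table_factory(np.zeros((3, 1)), np.zeros(3))
        with pytest.raises(ValueError, match="empty"):
            fit_tree(t, np.array([]), mtry=1)


class TestForest:
    def test_seed_determinism(self, noisy_table):
        a = fit_forest(noisy_table, B=10, seed=3)
        b = fit_forest(noisy_table, B=10, seed=3)
        X = noisy_table.X
        assert np.array_equal(predict(a, X), predict(b, X))
        for ba, bb in zip(a.boot_rows, b.boot_rows):
            assert np.array_equal(ba, bb)

    def test_bagging_identity_is_exact(self, noisy_table):
        forest = fit_forest(noisy_table, B=20, seed=1)
        X = noisy_table.X
        per_tree = forest.tree_predictions(X)
        assert np.max(np.abs(predict(forest, X) - per_tree.mean(axis=0))) <= 1e-12

    def test_single_tree_forest_equals_its_tree(self, noisy_table):
        forest = fit_forest(noisy_table, B=1, seed=2)
        X = noisy_table.X
        single = forest.trees[0].predict(X, forest.categorical)
        assert np.array_equal(predict(forest, X), single)

    def test_constant_trees_predict_the_constant(self):
        forest = make_constant_forest([0.4, 0.4, 0.4], n_rows=5)
        X = np.linspace(0, 1, 5).reshape(5, 1)
        assert np.allclose(predict(forest, X), 0.4)

    def test_hand_built_three_tree_mean(self):
        forest = make_constant_forest([0.2, 0.5, 0.8], n_rows=4)
        X = np.zeros((4, 1))
        assert np.allclose(predict(forest, X), (0.2 + 0.5 + 0.8) / 3.0)

    def test_bootstrap_and_oob_partition_rows(self, noisy_table):
        forest = fit_forest(noisy_table, B=5, seed=4)
        n = noisy_table.n
        for b in range(forest.n_trees):
            in_bag = np.unique(forest.boot_rows[b])
            oob = np.nonzero(forest.oob_mask(b))[0]
            assert np.array_equal(np.union1d(in_bag, oob), np.arange(n))
            assert np.intersect1d(in_bag, oob).size == 0

    def test_predictions_within_training_range(self, noisy_table):
        forest = fit_forest(noisy_table, B=30, seed=5)
        rng = np.random.default_rng(0)
        X_new = rng.random((50, noisy_table.p)) * 3 - 1  # outside training box
        pred = predict(forest, X_new)
        assert pred.min() >= noisy_table.y.min()
        assert pred.max() <= noisy_table.y.max()

    def test_zero_trees_rejected(self, noisy_table):
        with pytest.raises(ValueError, match="B"):
            fit_forest(noisy_table, B=0)

    def test_json_round_trip_preserves_predictions(self, noisy_table):
        forest = fit_forest(noisy_table, B=8, seed=6)
        clone = Forest.from_json(forest.to_json())
        X = noisy_table.X
        assert np.array_equal(predict(forest, X), predict(clone, X))
        assert clone.seed == forest.seed

    def test_unseen_categorical_level_routes_to_bigger_child(self, table_factory):
        X = np.array([[0.0], [0.0], [0.0], [1.0], [1.0]])
        y = np.array([0.2, 0.2, 0.2, 0.9, 0.9])
        t = table_factory(X, y, categorical=[True], categories={0: np.arange(5.0)})
        tree = fit_tree(t, np.arange(5), mtry=1, min_leaf=1,
                        rng=np.random.default_rng(0))
        pred = tree.predict(np.array([[4.0]]), t.categorical)
        # level 4 was never seen; the bigger child holds the three 0.2 rows
        assert pred.item() == pytest.approx(0.2)


class TestOOB:
    def test_constant_mean_trees_give_variance_of_y(self, table_factory):
        rng = np.random.default_rng(7)
        y = rng.random(40)
        t = table_factory(rng.random((40, 1)), y)
        forest = make_constant_forest([y.mean()] * 5, n_rows=40)
        res = oob_error(forest, t)
        # rows 1..39 are OOB everywhere and predicted by the global mean
        expect = np.var(y[1:])
        assert res.mse == pytest.approx(np.mean((y[1:] - y.mean()) ** 2))
        assert res.n_uncovered == 1
        assert res.r2 == pytest.approx(1 - res.mse / expect)

    def test_strong_signal_recovers_r2_near_one(self, table_factory):
        rng = np.random.default_rng(8)
        X = rng.random((400, 3))
        y = np.clip(0.8 * (X[:, 0] > 0.5) + 0.1, 0, 1)  # noiseless step
        t = table_factory(X, y)
        forest = fit_forest(t, B=100, mtry=3, min_leaf=2, seed=9)
        assert oob_error(forest, t).r2 >= 0.95

    def test_pure_noise_gives_no_skill(self, table_factory):
        rng = np.random.default_rng(10)
        X = rng.random((300, 3))
        y = rng.random(300)
        t = table_factory(X, y)
        forest = fit_forest(t, B=100, seed=11)
        assert oob_error(forest, t).r2 <= 0.05

    def test_more_trees_reduce_oob_mse(self, noisy_table):
        small = fit_forest(noisy_table, B=5, seed=12)
        large = fit_forest(noisy_table, B=200, seed=12)
        assert oob_error(large, noisy_table).mse <= oob_error(small, noisy_table).mse


class TestPermutationImportance:
    def test_constant_feature_scores_zero(self, table_factory):
        rng = np.random.default_rng(13)
        X = np.column_stack([rng.random(100), np.full(100, 0.7)])
        y = np.clip(X[:, 0], 0, 1)
        t = table_factory(X, y)
        forest = fit_forest(t, B=30, mtry=2, seed=14)
        rep = permutation_importance(forest, t, rng=0)
        assert rep.pct_inc_mse[1] == 0.0

    def test_perfect_predictor_ranks_first(self, table_factory):
        rng = np.random.default_rng(15)
        X = np.column_stack([rng.random(150), rng.random(150)])
        y = np.clip(X[:, 1], 0, 1)
        t = table_factory(X, y)
        forest = fit_forest(t, B=40, mtry=1, seed=16)
        rep = permutation_importance(forest, t, rng=1)
        assert rep.ranking[0] == "x1"
        assert rep.pct_inc_mse[1] > rep.pct_inc_mse[0]


def test_default_mtry_is_p_over_three():
    assert default_mtry(8) == 2
    assert default_mtry(2) == 1
    assert default_mtry(9) == 3


def test_matches_sklearn_forest_accuracy(noisy_table):
    """Independent cross-check: on the same data our ensemble's holdout R²
    must track scikit-learn's random-forest regressor."""
    sklearn_ensemble = pytest.importorskip("sklearn.ensemble")
    rng = np.random.default_rng(17)
    X = rng.random((500, 5))
    y = np.clip(0.5 * X[:, 0] + 0.3 * np.sin(3 * X[:, 1]) + 0.1, 0, 1)
    train, test = np.arange(350), np.arange(350, 500)
    t = FeatureTable(X[train], y[train], [f"x{j}" for j in range(5)],
                     np.zeros(5, dtype=bool))
    ours = fit_forest(t, B=100, mtry=2, min_leaf=5, seed=18)
    pred_ours = predict(ours, X[test])
    ref = sklearn_ensemble.RandomForestRegressor(
        n_estimators=100, max_features=2, min_samples_leaf=5, random_state=0
    ).fit(X[train], y[train])
    pred_ref = ref.predict(X[test])

    def r2(pred):
        return 1 - np.mean((y[test] - pred) ** 2) / np.var(y[test])

    assert abs(r2(pred_ours) - r2(pred_ref)) < 0.1
    assert r2(pred_ours) > 0.7
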