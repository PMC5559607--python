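"""Model tree: greedy split search vs brute force, CV metrics, serialization."""

import numpy as np
import pandas as pd
import pytest

from sibfate.cycle_model import (
    CyclePositionModel,
    ModelTree,
    cross_validate,
    fit_model_tree,
    predict_position,
)
from sibfate.features import FEATURE_NAMES, FeatureVector


def random_table(n, seed, target="linear"):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "Lb": rng.uniform(1.5, 3.5, n),
            "dt": rng.uniform(0, 25, n),
            "dL": rng.uniform(0, 3, n),
            "GR": rng.normal(0.03, 0.003, n),
            "dF": rng.normal(100, 40, n),
            "F": rng.normal(300, 60, n),
        }
    )
    if target == "linear":
        y = 0.03 * X.dt + 0.1 * X.dL - 0.2
    else:
        y = np.where(X.dt <= 10, 0.02 * X.dt, 0.2 + 0.06 * (X.dt - 10))
        y = y + 0.05 * rng.standard_normal(n)
    return X.assign(x=y)


def brute_force_best_split(X, y, min_leaf):
    """Independent exhaustive enumeration via per-candidate lstsq fits."""
    n, k = X.shape
    A = np.column_stack([X, np.ones(n)])

    def sse(rows):
        beta, *_ = np.linalg.lstsq(A[rows], y[rows], rcond=None)
        r = y[rows] - A[rows] @ beta
        return float(r @ r)

    best = None
    for fi in range(k):
        xs = np.sort(np.unique(X[:, fi]))
        for lo, hi in zip(xs[:-1], xs[1:]):
            thr = 0.5 * (lo + hi)
            left = X[:, fi] <= thr
            if left.sum() < min_leaf or (~left).sum() < min_leaf:
                continue
            total = sse(np.nonzero(left)[0]) + sse(np.nonzero(~left)[0])
            if best is None or total < best[2] - 1e-9:
                best = (fi, thr, total)
    return best


class TestSplitSearch:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("n", [60, 150, 200])
    def test_greedy_matches_exhaustive_enumeration(self, seed, n):
        table = random_table(n, seed, target="piecewise")
        X = table[list(FEATURE_NAMES)].to_numpy()
        y = table.x.to_numpy()
        tree = fit_model_tree(table, max_depth=1, min_leaf=10)
        want = brute_force_best_split(X, y, min_leaf=10)
        assert want is not None and not tree.root.is_leaf
        assert tree.root.feature == FEATURE_NAMES[want[0]]
        assert tree.root.threshold == pytest.approx(want[1], rel=1e-9)
        got_sse = float(np.sum((tree.predict(table, clip=False) - y) ** 2))
        assert got_sse == pytest.approx(want[2], rel=1e-6, abs=1e-9)

    def test_piecewise_fixture_splits_at_break(self):
        table = random_table(120, 3, target="piecewise")
        tree = fit_model_tree(table, max_depth=1, min_leaf=10)
        root = tree.root
        assert root.feature == "dt"
        assert root.threshold == pytest.approx(10.0, abs=1.5)

    def test_exact_linear_target_yields_single_exact_leaf(self):
        table = random_table(100, 4, target="linear")
        tree = fit_model_tree(table, max_depth=3, min_leaf=25)
        assert tree.n_leaves == 1
        pred = tree.predict(table, clip=False)
        np.testing.assert_allclose(pred, table.x, atol=1e-8)

    def test_too_few_rows_for_any_split_gives_single_leaf(self):
        table = random_table(49, 5, target="piecewise")
        tree = fit_model_tree(table, max_depth=3, min_leaf=25)
        assert tree.n_leaves == 1

    def test_fewer_rows_than_min_leaf_rejected(self):
        with pytest.raises(ValueError, match="min_leaf"):
            fit_model_tree(random_table(10, 0), min_leaf=25)

    def test_constant_feature_set_yields_leaf_not_crash(self):
        table = random_table(80, 6, target="piecewise")
        for c in FEATURE_NAMES:
            table[c] = 1.0
        tree = fit_model_tree(table, max_depth=3, min_leaf=10)
        assert tree.n_leaves == 1
        assert np.isfinite(tree.predict(table, clip=False)).all()

    def test_training_sse_never_increases_with_depth(self):
        table = random_table(200, 7, target="piecewise")
        sses = []
        for depth in range(4):
            tree = fit_model_tree(table, max_depth=depth, min_leaf=10)
            pred = tree.predict(table, clip=False)
            sses.append(np.sum((pred - table.x) ** 2))
        assert all(b <= a + 1e-9 for a, b in zip(sses, sses[1:]))

    def test_deterministic(self):
        table = random_table(150, 8, target="piecewise")
        t1 = fit_model_tree(table).to_text()
        t2 = fit_model_tree(table.copy()).to_text()
        assert t1 == t2


class TestPrediction:
    def _constant_tree(self, value=0.5):
        from sibfate.cycle_model import TreeNode

        root = TreeNode(coef=np.zeros(6), intercept=value, n=50, sse=0.0)
        return ModelTree(root, 3, 25)

    def test_constant_leaf_returns_intercept(self):
        tree = self._constant_tree(0.5)
        fv = FeatureVector(2.0, 5.0, 0.5, 0.03, 10.0, 200.0)
        assert predict_position(tree, fv) == 0.5

    def test_out_of_range_prediction_clipped(self):
        tree = self._constant_tree(1.3)
        fv = FeatureVector(2.0, 5.0, 0.5, 0.03, 10.0, 200.0)
        assert predict_position(tree, fv) == 1.0
        assert self._constant_tree(-0.2).predict(
            np.ones((1, 6)), clip=True
        )[0] == 0.0

    def test_predictions_in_unit_interval(self, training_table):
        tree = fit_model_tree(training_table)
        pred = tree.predict(training_table)
        assert ((pred >= 0) & (pred <= 1)).all()

    def test_missing_feature_values_rejected(self):
        tree = self._constant_tree()
        X = np.ones((2, 6))
        X[1, 3] = np.nan
        with pytest.raises(ValueError, match="missing|non-finite"):
            tree.predict(X)


class TestSplitCounts:
    def test_single_leaf_all_zero(self):
        table = random_table(100, 4, target="linear")
        counts = fit_model_tree(table).feature_split_counts()
        assert counts.sum() == 0

    def test_full_depth3_tree_has_seven_internal_nodes(self):
        # a tree of depth 3 with 8 leaves must have exactly 7 splits
        table = random_table(400, 9, target="piecewise")
        tree = fit_model_tree(table, max_depth=3, min_leaf=10)
        counts = tree.feature_split_counts()
        assert counts.sum() == tree.n_leaves - 1


class TestSerialization:
    def test_round_trip_preserves_predictions(self, training_table):
        tree = fit_model_tree(training_table)
        tree2 = ModelTree.from_text(tree.to_text())
        np.testing.assert_allclose(
            tree.predict(training_table), tree2.predict(training_table), atol=1e-12
        )
        assert tree2.max_depth == tree.max_depth
        assert tree2.min_leaf == tree.min_leaf


class TestCrossValidation:
    def test_perfect_predictions_metrics(self):
        # a linear target inside [0,1] is fit exactly: R^2 = 1, RMSE = 0
        table = random_table(120, 10, target="linear")
        table["x"] = 0.2 + 0.02 * table.dt
        cv = cross_validate(table, k=5, seed=0, min_leaf=10)
        assert cv.r2 == pytest.approx(1.0, abs=1e-6)
        assert cv.rmse == pytest.approx(0.0, abs=1e-6)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(random_table(100, 0), k=1)

    def test_deterministic_given_seed(self, training_table):
        cv1 = CyclePositionModel(training_table).cross_validate(k=10, seed=3)
        cv2 = CyclePositionModel(training_table).cross_validate(k=10, seed=3)
        np.testing.assert_array_equal(cv1.predicted, cv2.predicted)
        assert cv1.r2 == cv2.r2

    def test_fold_assignments_partition_data(self, training_table):
        cv = CyclePositionModel(training_table).cross_validate(k=10, seed=3)
        counts = np.bincount(cv.fold_assignments, minlength=10)
        assert counts.sum() == len(training_table)
        assert counts.min() >= len(training_table) // 10

    def test_summary_mentions_key_metrics(self, training_table):
        res = CyclePositionModel(training_table).fit()
        s = res.summary()
        assert "R^2" in s and "RMSE" in s and "leaves" in s
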