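"""CART regression tree vs an independent exhaustive brute-force oracle."""

import numpy as np
import pytest

from quinoscreen.models import export_text, feature_importances, fit_cart


# ---------------------------------------------------------------------------
# independent oracle: plain-python recursive exhaustive search
# ---------------------------------------------------------------------------

def _sse(y):
    m = sum(y) / len(y)
    return sum((v - m) ** 2 for v in y)


def _oracle_predictions(X, y, max_depth):
    """Training predictions of a brute-force CART with the same split rules:
    midpoint thresholds, first-best tie-break in (feature, ascending
    threshold) order, split only on a strictly positive SSE decrease."""

    def build(rows, depth):
        ys = [y[i] for i in rows]
        mean = sum(ys) / len(ys)
        if depth == 0 or len(rows) < 2:
            return {i: mean for i in rows}
        parent = _sse(ys)
        best = None  # (decrease, j, t)
        for j in range(X.shape[1]):
            values = sorted({X[i, j] for i in rows})
            for a, b in zip(values, values[1:]):
                t = (a + b) / 2.0
                if t <= a:
                    t = b
                left = [i for i in rows if X[i, j] < t]
                right = [i for i in rows if X[i, j] >= t]
                if not left or not right:
                    continue
                dec = parent - _sse([y[i] for i in left]) - _sse([y[i] for i in right])
                if dec > 1e-12 and (best is None or dec > best[0]):
                    best = (dec, j, t, left, right)
        if best is None:
            return {i: mean for i in rows}
        _, _, _, left, right = best
        out = build(left, depth - 1)
        out.update(build(right, depth - 1))
        return out

    preds = build(list(range(len(y))), max_depth)
    return np.array([preds[i] for i in range(len(y))])


class TestKnownSplits:
    def test_step_function_split(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0.0, 0.0, 10.0, 10.0])
        model = fit_cart(X, y, max_depth=1)
        assert model.root.threshold == pytest.approx(2.5)
        assert model.root.left.value == 0.0
        assert model.root.right.value == 10.0
        assert np.mean((model.predict(X) - y) ** 2) == 0.0

    def test_constant_target_single_leaf(self):
        model = fit_cart(np.arange(8.0)[:, None], np.full(8, 3.3), max_depth=5)
        assert model.root.is_leaf
        assert model.root.value == pytest.approx(3.3)

    def test_depth_zero_predicts_mean(self):
        y = np.array([1.0, 2.0, 6.0])
        model = fit_cart(np.arange(3.0)[:, None], y, max_depth=0)
        assert model.root.is_leaf
        assert model.predict(np.arange(3.0)[:, None]) == pytest.approx([3.0] * 3)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            fit_cart(np.empty((0, 1)), [])

    def test_unlimited_depth_interpolates_distinct_rows(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        model = fit_cart(X, y, max_depth=None)
        assert np.mean((model.predict(X) - y) ** 2) < 1e-20

    def test_min_samples_leaf_respected(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        model = fit_cart(X, y, max_depth=None, min_samples_leaf=5)

        def check(node):
            if node.is_leaf:
                assert node.n_samples >= 5
            else:
                check(node.left), check(node.right)

        check(model.root)


class TestOracleEquivalence:
    def test_identical_training_predictions_100_instances(self):
        """Exhaustive-split CART vs the independent brute-force oracle."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 26))
            m = int(rng.integers(1, 4))
            depth = int(rng.integers(1, 4))
            X = np.round(rng.normal(size=(n, m)), 2)  # ties made likely
            y = np.round(rng.normal(size=n), 2)
            model = fit_cart(X, y, max_depth=depth)
            ours = model.predict(X)
            oracle = _oracle_predictions(X, y, depth)
            assert ours == pytest.approx(oracle, abs=1e-12)


class TestPoissonCost:
    def test_requires_positive_targets(self):
        with pytest.raises(ValueError, match="positive"):
            fit_cart(np.arange(4.0)[:, None], [1.0, 0.0, 2.0, 3.0], cost="poisson")

    def test_separates_rate_groups(self):
        X = np.array([[0.0], [0.1], [0.9], [1.0]])
        y = np.array([1.0, 1.2, 9.0, 10.0])
        model = fit_cart(X, y, max_depth=1, cost="poisson")
        assert not model.root.is_leaf
        assert model.root.left.value < model.root.right.value


class TestImportances:
    def test_single_split_full_importance(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0], [4.0, 5.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        model = fit_cart(X, y, max_depth=1)
        imp = feature_importances(model)
        assert imp["x0"] == pytest.approx(1.0)
        assert imp["x1"] == 0.0

    def test_splitless_model_warns_all_zero(self):
        model = fit_cart(np.arange(4.0)[:, None], np.ones(4), max_depth=3)
        with pytest.warns(UserWarning, match="no splits"):
            imp = feature_importances(model)
        assert set(imp.values()) == {0.0}

    def test_planted_informative_feature_ranks_first(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(150, 4))
            y = 2.0 * X[:, 2] + 0.3 * rng.normal(size=150)
            imp = feature_importances(fit_cart(X, y, max_depth=3))
            hits += max(imp, key=imp.get) == "x2"
        assert hits >= 8


class TestAgainstReferenceImplementation:
    def test_prediction_rmse_close_to_sklearn(self):
        from sklearn.tree import DecisionTreeRegressor

        rng = np.random.default_rng(11)
        X = rng.normal(size=(120, 4))
        y = X @ [1.0, -0.5, 0.0, 0.2] + 0.2 * rng.normal(size=120)
        ours = fit_cart(X, y, max_depth=3).predict(X)
        ref = (
            DecisionTreeRegressor(max_depth=3, random_state=0).fit(X, y).predict(X)
        )
        rmse = np.sqrt(np.mean((ours - ref) ** 2))
        assert rmse <= 0.05 * y.std()


def test_export_text_lists_conditions_and_leaves():
    import pandas as pd

    X = pd.DataFrame({"lumo": [1.0, 2.0, 3.0, 4.0]})
    y = [0.0, 0.0, 1.0, 1.0]
    text = export_text(fit_cart(X, y, max_depth=1))
    assert "if lumo < 2.5000:" in text
    assert text.count("leaf:") == 2
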