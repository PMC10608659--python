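"""Tree ensembles: random forest, extra trees, gradient boosting.

Random forest: each tree sees a bootstrap resample (with replacement, size
n) and a fresh random feature subset of size ceil(m/3) at every split;
thresholds are optimized exhaustively.  Extra trees: each tree sees a
subsample WITHOUT replacement (fraction 0.8 by default) and one uniformly
random threshold per candidate feature.  Both predict the mean over member
trees.  Gradient boosting fits each tree to the residuals of the running
model and adds it scaled by the learning rate gamma:

    F_0 = mean(y),    F_m = F_{m-1} + gamma * h_m.

All randomness flows from one integer seed through spawned generators, so
fits are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from quinoscreen.models._util import as_matrix, as_vector
from quinoscreen.models.tree import TreeNode, _build

MODES = ("random_forest", "extra_trees", "gradient_boosting")


@dataclass
class EnsembleModel:
    mode: str
    trees: list[TreeNode]
    columns: tuple[str, ...]
    params: dict = field(default_factory=dict)
    seed: int | None = None
    learning_rate: float = 1.0  # gradient boosting only
    initial_value: float = 0.0  # F_0 for gradient boosting

    def _tree_predictions(self, mat: np.ndarray) -> np.ndarray:
        return np.array(
            [[t.predict_row(row) for row in mat] for t in self.trees]
        )

    def predict(self, X) -> np.ndarray:
        mat, _ = as_matrix(X, columns=self.columns)
        if self.mode == "gradient_boosting":
            out = np.full(mat.shape[0], self.initial_value)
            for tree in self.trees:
                out = out + self.learning_rate * np.array(
                    [tree.predict_row(row) for row in mat]
                )
            return out
        if not self.trees:
            raise ValueError("ensemble has no trees")
        return self._tree_predictions(mat).mean(axis=0)


def fit_forest(
    X,
    y,
    mode: str = "random_forest",
    n_estimators: int = 10,
    max_depth: int | None = 3,
    min_samples_leaf: int = 1,
    seed: int = 0,
    max_features: int | None = None,
    subsample_fraction: float = 0.8,
    bootstrap: bool | None = None,
) -> EnsembleModel:
    """Fit a bagged ensemble.

    ``max_features`` defaults to ceil(m/3) (regression convention); pass
    ``m`` to disable feature subsampling.  For random forest ``bootstrap``
    defaults on (size-n resampling with replacement); for extra trees each
    tree sees a without-replacement subsample of ``subsample_fraction``
    (1.0 = the full training set).
    """
    if mode not in ("random_forest", "extra_trees"):
        raise ValueError(f"unknown forest mode {mode!r}")
    if n_estimators < 1:
        raise ValueError("n_estimators must be >= 1")
    if not (0.0 < subsample_fraction <= 1.0):
        raise ValueError("subsample_fraction must be in (0, 1]")
    mat, names = as_matrix(X)
    target = as_vector(y)
    n, m = mat.shape
    if max_features is None:
        max_features = math.ceil(m / 3)
    if bootstrap is None:
        bootstrap = mode == "random_forest"

    random_threshold = mode == "extra_trees"
    trees: list[TreeNode] = []
    seeds = np.random.SeedSequence(seed).spawn(n_estimators)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        if mode == "random_forest":
            idx = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        else:
            k = max(2 * min_samples_leaf, int(round(subsample_fraction * n)))
            k = min(k, n)
            idx = np.sort(rng.choice(n, size=k, replace=False))
        trees.append(
            _build(
                mat[idx], target[idx], 0, max_depth, min_samples_leaf, "mse",
                max_features=max_features, random_threshold=random_threshold,
                rng=rng,
            )
        )
    return EnsembleModel(
        mode=mode,
        trees=trees,
        columns=names,
        params={
            "n_estimators": n_estimators,
            "max_depth": max_depth,
            "min_samples_leaf": min_samples_leaf,
            "max_features": max_features,
            "subsample_fraction": subsample_fraction,
            "bootstrap": bool(bootstrap),
        },
        seed=seed,
    )


def fit_gbr(
    X,
    y,
    n_estimators: int = 50,
    learning_rate: float = 0.05,
    max_depth: int | None = 3,
    min_samples_leaf: int = 1,
    seed: int = 0,
) -> EnsembleModel:
    """Gradient boosting with squared-error cost.

    Each stage fits a CART tree (exhaustive splits, all features) to the
    current residuals — the squared-error minimizer of the stagewise cost —
    and the model advances by ``learning_rate`` times the tree's prediction.
    ``n_estimators=0`` yields the constant mean-of-y model.
    """
    if n_estimators < 0:
        raise ValueError("n_estimators must be >= 0")
    if not (0.0 < learning_rate <= 1.0):
        raise ValueError("learning_rate must be in (0, 1]")
    mat, names = as_matrix(X)
    target = as_vector(y)
    f0 = float(target.mean())
    current = np.full(len(target), f0)
    trees: list[TreeNode] = []
    for _ in range(n_estimators):
        residual = target - current
        tree = _build(
            mat, residual, 0, max_depth, min_samples_leaf, "mse",
            max_features=None, random_threshold=False, rng=None,
        )
        trees.append(tree)
        current = current + learning_rate * np.array(
            [tree.predict_row(row) for row in mat]
        )
    return EnsembleModel(
        mode="gradient_boosting",
        trees=trees,
        columns=names,
        params={
            "n_estimators": n_estimators,
            "max_depth": max_depth,
            "min_samples_leaf": min_samples_leaf,
        },
        seed=seed,
        learning_rate=learning_rate,
        initial_value=f0,
    )
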