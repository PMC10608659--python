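"""CART regression trees with exhaustive split search.

At each node every candidate (feature, threshold) pair is scored; thresholds
are the midpoints between consecutive distinct sorted feature values, rows
with ``x_j < t`` go left, and the pair maximizing the weighted cost decrease

    n H(Q) - n_l H(Q_l) - n_r H(Q_r)

is kept.  The cost H is the node mean squared error by default; the Poisson
half-deviance H = mean(y log(y/ybar) - y + ybar) is available for strictly
positive targets.  Leaves predict their training-target mean.

Tie-breaking is fully deterministic: features are scanned in column order,
thresholds in ascending order, and the first strictly best pair wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from quinoscreen.models._util import as_matrix, as_vector

#: cost decreases below this are treated as zero (guards float noise on pure nodes)
_MIN_DECREASE = 1e-12


@dataclass
class TreeNode:
    """Internal node (feature/threshold/children) or leaf (children None)."""

    value: float  # training-target mean at this node
    n_samples: int
    cost: float  # H(Q_m)
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def predict_row(self, row: np.ndarray) -> float:
        node = self
        while not node.is_leaf:
            node = node.left if row[node.feature] < node.threshold else node.right
        return node.value


@dataclass
class CartModel:
    root: TreeNode
    columns: tuple[str, ...]
    max_depth: int | None
    min_samples_leaf: int
    cost: str

    def predict(self, X) -> np.ndarray:
        mat, _ = as_matrix(X, columns=self.columns)
        return np.array([self.root.predict_row(row) for row in mat])


def _node_cost(y: np.ndarray, cost: str) -> float:
    mean = y.mean()
    if cost == "mse":
        return float(np.mean((y - mean) ** 2))
    # poisson half-deviance
    return float(np.mean(y * np.log(y / mean) - y + mean))


def _prefix_costs(ys: np.ndarray, cost: str) -> tuple[np.ndarray, np.ndarray]:
    """Total (not mean) cost of every prefix/suffix split of sorted targets.

    Returns (left_totals, right_totals) indexed by split position i
    (left = ys[:i+1], right = ys[i+1:]), for i = 0..n-2.
    """
    n = len(ys)
    counts = np.arange(1, n, dtype=float)
    csum = np.cumsum(ys)[:-1]
    rsum = ys.sum() - csum
    if cost == "mse":
        csum2 = np.cumsum(ys**2)[:-1]
        rsum2 = (ys**2).sum() - csum2
        left = csum2 - csum**2 / counts
        right = rsum2 - rsum**2 / (n - counts)
    else:
        ylogy = ys * np.log(ys)
        c_ylogy = np.cumsum(ylogy)[:-1]
        r_ylogy = ylogy.sum() - c_ylogy
        left = c_ylogy - csum * np.log(csum / counts)
        right = r_ylogy - rsum * np.log(rsum / (n - counts))
    return left, right


def _best_split_feature(
    x: np.ndarray,
    y: np.ndarray,
    parent_total: float,
    min_leaf: int,
    cost: str,
    rng: np.random.Generator | None = None,
) -> tuple[float, float] | None:
    """Best (decrease, threshold) for one feature, or None.

    With ``rng`` given, a single uniformly random threshold in (min, max) is
    scored instead of the exhaustive scan (extra-trees mode).
    """
    n = len(y)
    if rng is not None:
        lo, hi = x.min(), x.max()
        if lo == hi:
            return None
        t = rng.uniform(lo, hi)
        mask = x < t
        n_l = int(mask.sum())
        if n_l < min_leaf or n - n_l < min_leaf or n_l == 0 or n_l == n:
            return None
        dec = parent_total - _node_cost(y[mask], cost) * n_l - _node_cost(
            y[~mask], cost
        ) * (n - n_l)
        return (dec, float(t)) if dec > _MIN_DECREASE else None

    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    if xs[0] == xs[-1]:
        return None
    left, right = _prefix_costs(ys, cost)
    counts = np.arange(1, n)
    valid = (xs[:-1] < xs[1:]) & (counts >= min_leaf) & (n - counts >= min_leaf)
    if not valid.any():
        return None
    decrease = np.where(valid, parent_total - left - right, -np.inf)
    i = int(np.argmax(decrease))  # first occurrence = smallest threshold
    if decrease[i] <= _MIN_DECREASE:
        return None
    t = (xs[i] + xs[i + 1]) / 2.0
    if t <= xs[i]:  # midpoint rounded down between adjacent floats
        t = xs[i + 1]
    return float(decrease[i]), float(t)


def _build(
    X: np.ndarray,
    y: np.ndarray,
    depth: int,
    max_depth: int | None,
    min_leaf: int,
    cost: str,
    max_features: int | None,
    random_threshold: bool,
    rng: np.random.Generator | None,
) -> TreeNode:
    n, m = X.shape
    node_cost = _node_cost(y, cost)
    node = TreeNode(value=float(y.mean()), n_samples=n, cost=node_cost)
    if (max_depth is not None and depth >= max_depth) or n < 2 * min_leaf:
        return node
    parent_total = node_cost * n

    if max_features is not None and max_features < m:
        features = np.sort(rng.choice(m, size=max_features, replace=False))
    else:
        features = np.arange(m)

    best = None  # (decrease, feature, threshold)
    for j in features:
        found = _best_split_feature(
            X[:, j], y, parent_total, min_leaf, cost,
            rng=rng if random_threshold else None,
        )
        if found is not None and (best is None or found[0] > best[0]):
            best = (found[0], int(j), found[1])
    if best is None:
        return node

    _, j, t = best
    mask = X[:, j] < t
    node.feature = j
    node.threshold = t
    node.left = _build(
        X[mask], y[mask], depth + 1, max_depth, min_leaf, cost,
        max_features, random_threshold, rng,
    )
    node.right = _build(
        X[~mask], y[~mask], depth + 1, max_depth, min_leaf, cost,
        max_features, random_threshold, rng,
    )
    return node


def fit_cart(
    X,
    y,
    max_depth: int | None = None,
    min_samples_leaf: int = 1,
    cost: str = "mse",
) -> CartModel:
    """Fit a CART regression tree by exhaustive greedy split search."""
    if cost not in ("mse", "poisson"):
        raise ValueError("cost must be 'mse' or 'poisson'")
    if max_depth is not None and max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    mat, names = as_matrix(X)
    target = as_vector(y)
    if mat.shape[0] == 0:
        raise ValueError("cannot fit a tree on empty data")
    if cost == "poisson" and np.any(target <= 0):
        raise ValueError("poisson cost requires strictly positive targets")
    root = _build(
        mat, target, 0, max_depth, min_samples_leaf, cost,
        max_features=None, random_threshold=False, rng=None,
    )
    return CartModel(
        root=root, columns=names, max_depth=max_depth,
        min_samples_leaf=min_samples_leaf, cost=cost,
    )


# ---------------------------------------------------------------------------
# introspection
# ---------------------------------------------------------------------------

def _accumulate_importance(node: TreeNode, acc: np.ndarray) -> None:
    if node.is_leaf:
        return
    decrease = (
        node.n_samples * node.cost
        - node.left.n_samples * node.left.cost
        - node.right.n_samples * node.right.cost
    )
    acc[node.feature] += max(decrease, 0.0)
    _accumulate_importance(node.left, acc)
    _accumulate_importance(node.right, acc)


def feature_importances(model) -> dict[str, float]:
    """Total weighted cost decrease per feature, normalized to sum 1.

    Accepts a :class:`CartModel` or an ensemble; ensemble importances are the
    mean of member-tree importances, renormalized.  A splitless model yields
    an all-zero map with a warning.
    """
    from quinoscreen.models.ensembles import EnsembleModel  # cycle guard

    if isinstance(model, EnsembleModel):
        per_tree = np.zeros(len(model.columns))
        for root in model.trees:
            acc = np.zeros(len(model.columns))
            _accumulate_importance(root, acc)
            if acc.sum() > 0:
                per_tree += acc / acc.sum()
        total = per_tree
        columns = model.columns
    else:
        total = np.zeros(len(model.columns))
        _accumulate_importance(model.root, total)
        columns = model.columns
    s = total.sum()
    if s <= 0:
        warnings.warn("model contains no splits; importances are all zero")
        return {c: 0.0 for c in columns}
    return {c: float(v / s) for c, v in zip(columns, total)}


def export_text(model: CartModel, decimals: int = 4) -> str:
    """Indented textual rendering of the tree (split conditions and leaves)."""
    lines: list[str] = []

    def walk(node: TreeNode, indent: int) -> None:
        pad = "  " * indent
        if node.is_leaf:
            lines.append(
                f"{pad}leaf: value={node.value:.{decimals}f} (n={node.n_samples})"
            )
            return
        name = model.columns[node.feature]
        lines.append(f"{pad}if {name} < {node.threshold:.{decimals}f}:")
        walk(node.left, indent + 1)
        lines.append(f"{pad}else:  # {name} >= {node.threshold:.{decimals}f}")
        walk(node.right, indent + 1)

    walk(model.root, 0)
    return "\n".join(lines)
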