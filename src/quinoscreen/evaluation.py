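"""Dataset splitting, cross-validation, grid search and trendline diagnostics.

Model assessment follows one protocol throughout: a seeded 80/20
shuffle-split into training and test rows, 5-fold cross-validation on the
training rows (mean of per-fold validation R^2 is the model statistic), and
a final linear trendline of reference against predicted potentials on the
held-out test set.  Folds are a seeded shuffle followed by contiguous
chunking; fold sizes differ by at most one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from quinoscreen.models import fit_cart, fit_forest, fit_gbr, fit_ridge

FitFunction = Callable[[object, np.ndarray], object]


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint, exhaustive train/test row split; |train| = floor(fraction n)."""

    seed: int
    train_ids: tuple[int, ...]
    test_ids: tuple[int, ...]
    fraction: float = 0.8


@dataclass
class CVResult:
    fold_train_r2: list[float]
    fold_val_r2: list[float]
    fold_seed: int

    @property
    def mean_train_r2(self) -> float:
        return float(np.mean(self.fold_train_r2))

    @property
    def mean_val_r2(self) -> float:
        return float(np.mean(self.fold_val_r2))


@dataclass
class GridSearchResult:
    grid: list[dict]
    results: list[CVResult]
    selected_index: int
    criterion: str

    @property
    def selected_params(self) -> dict:
        return self.grid[self.selected_index]

    @property
    def selected_result(self) -> CVResult:
        return self.results[self.selected_index]


@dataclass(frozen=True)
class TrendlineStats:
    slope: float
    intercept: float
    r_squared: float


def split_dataset(n: int, fraction: float = 0.8, seed: int = 0) -> SplitPlan:
    """Uniform seeded shuffle; first floor(fraction n) rows train, rest test."""
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    if not (0.0 < fraction < 1.0):
        raise ValueError("train fraction must be in (0, 1)")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = math.floor(fraction * n)
    return SplitPlan(
        seed=seed,
        train_ids=tuple(int(i) for i in perm[:n_train]),
        test_ids=tuple(int(i) for i in perm[n_train:]),
        fraction=fraction,
    )


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.size < 2:
        raise ValueError("need equal-length vectors of size >= 2")
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for zero-variance reference")
    return 1.0 - float(np.sum((yt - yp) ** 2)) / ss_tot


def _fold_indices(n: int, folds: int, fold_seed: int) -> list[np.ndarray]:
    perm = np.random.default_rng(fold_seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


def _rows(X, idx: np.ndarray):
    return X.iloc[idx] if isinstance(X, pd.DataFrame) else np.asarray(X)[idx]


def cross_validate(
    fit: FitFunction, X, y, folds: int = 5, fold_seed: int = 0
) -> CVResult:
    """Per-fold train/validation R^2, averaged across folds (not pooled)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < folds:
        raise ValueError(f"{n} rows cannot form {folds} folds")
    train_scores, val_scores = [], []
    for val_idx in _fold_indices(n, folds, fold_seed):
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        model = fit(_rows(X, train_idx), y[train_idx])
        train_scores.append(r_squared(y[train_idx], model.predict(_rows(X, train_idx))))
        val_scores.append(r_squared(y[val_idx], model.predict(_rows(X, val_idx))))
    return CVResult(fold_train_r2=train_scores, fold_val_r2=val_scores, fold_seed=fold_seed)


def grid_search(
    fitter_factory: Callable[..., FitFunction],
    grid: Sequence[dict],
    X,
    y,
    criterion: str = "max_val_r2",
    folds: int = 5,
    fold_seed: int = 0,
) -> GridSearchResult:
    """Exhaustive grid evaluation.

    ``criterion``: ``max_val_r2`` picks the highest mean validation R^2;
    ``min_train_val_gap`` picks the smallest (mean train - mean validation)
    R^2 difference.  Ties keep the earlier grid point, so grids should be
    ordered from the most regularized / smallest model upward.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if criterion not in ("max_val_r2", "min_train_val_gap"):
        raise ValueError(f"unknown criterion {criterion!r}")
    results = [
        cross_validate(fitter_factory(**params), X, y, folds=folds, fold_seed=fold_seed)
        for params in grid
    ]
    if criterion == "max_val_r2":
        scores = [r.mean_val_r2 for r in results]
        selected = int(np.argmax(scores))
    else:
        gaps = [r.mean_train_r2 - r.mean_val_r2 for r in results]
        selected = int(np.argmin(gaps))
    return GridSearchResult(
        grid=list(grid), results=results, selected_index=selected, criterion=criterion
    )


def trendline(y_model, y_reference) -> TrendlineStats:
    """Least-squares line of reference potentials on model predictions.

    A perfect model gives slope 1, intercept 0, R^2 1.
    """
    xm = np.asarray(y_model, dtype=float)
    yr = np.asarray(y_reference, dtype=float)
    if xm.size < 3 or xm.shape != yr.shape:
        raise ValueError("trendline needs >= 3 paired points")
    var = float(np.var(xm))
    if var == 0:
        raise ValueError("trendline undefined for constant model predictions")
    slope = float(np.cov(xm, yr, bias=True)[0, 1] / var)
    intercept = float(yr.mean() - slope * xm.mean())
    return TrendlineStats(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared(yr, slope * xm + intercept),
    )


# ---------------------------------------------------------------------------
# model family registry (used by grid search and the pipeline)
# ---------------------------------------------------------------------------

#: the paper-protocol hyperparameters found optimal by grid search
DEFAULT_FAMILY_PARAMS: dict[str, dict] = {
    "ridge": {"lam": 0.1},
    "cart": {"max_depth": 3},
    "random_forest": {"n_estimators": 10, "max_depth": 3, "seed": 0},
    "extra_trees": {"n_estimators": 15, "max_depth": 3, "seed": 0},
    "gradient_boosting": {"n_estimators": 50, "learning_rate": 0.05, "max_depth": 3, "seed": 0},
}

MODEL_FAMILIES = tuple(DEFAULT_FAMILY_PARAMS)


def make_fitter(family: str, **params) -> FitFunction:
    """A fit(X, y) closure for one model family with fixed hyperparameters."""
    if family == "ridge":
        return lambda X, y: fit_ridge(X, y, **params)
    if family == "cart":
        return lambda X, y: fit_cart(X, y, **params)
    if family == "random_forest":
        return lambda X, y: fit_forest(X, y, mode="random_forest", **params)
    if family == "extra_trees":
        return lambda X, y: fit_forest(X, y, mode="extra_trees", **params)
    if family == "gradient_boosting":
        return lambda X, y: fit_gbr(X, y, **params)
    raise ValueError(f"unknown model family {family!r}")


#: default grids, ordered from most regularized / smallest model upward so
#: grid-search ties resolve toward the simpler point
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "ridge": [{"lam": lam} for lam in (100.0, 10.0, 1.0, 0.1, 0.01, 0.0)],
    "cart": [{"max_depth": d} for d in range(2, 21)],
    "random_forest": [
        {"n_estimators": n, "max_depth": 3, "seed": 0} for n in (5, 10, 15, 25, 50)
    ],
    "extra_trees": [
        {"n_estimators": n, "max_depth": 3, "seed": 0} for n in (5, 10, 15, 25, 50)
    ],
    "gradient_boosting": [
        {"n_estimators": n, "learning_rate": lr, "max_depth": 3, "seed": 0}
        for lr in (0.05, 0.1, 0.5)
        for n in (25, 50, 100)
    ],
}
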