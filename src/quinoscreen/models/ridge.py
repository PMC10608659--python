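"""Closed-form ridge regression.

The design matrix carries a leading ones column, so the coefficient vector
has length m+1 with the intercept first, and the estimator is

    beta = (X^T X + lambda I)^(-1) X^T y.

By default the penalty matrix is the full identity, i.e. the intercept is
shrunk along with the slopes — the literal closed form above.  The
conventional unpenalized-intercept variant is available via
``penalize_intercept=False`` (the top-left entry of the penalty is zeroed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from quinoscreen.models._util import as_matrix, as_vector


class SingularDesignError(np.linalg.LinAlgError):
    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(
            "singular normal equations at lambda=0; linearly dependent "
            f"columns: {columns}"
        )


def _dependent_columns(X: np.ndarray, names: tuple[str, ...]) -> list[str]:
    """Columns (beyond the intercept) that do not enlarge the column space."""
    dependent = []
    kept = X[:, :1]
    for j in range(1, X.shape[1]):
        trial = np.hstack([kept, X[:, j : j + 1]])
        if np.linalg.matrix_rank(trial) == kept.shape[1]:
            dependent.append(names[j - 1] if j - 1 < len(names) else f"x{j - 1}")
        else:
            kept = trial
    return dependent


@dataclass
class RidgeModel:
    """Fitted ridge model; ``coefficients[0]`` is the intercept."""

    coefficients: np.ndarray
    lam: float
    columns: tuple[str, ...]
    penalize_intercept: bool = True
    feature_means: np.ndarray | None = None
    feature_scales: np.ndarray | None = None

    def predict(self, X) -> np.ndarray:
        mat, _ = as_matrix(X, columns=self.columns)
        if self.feature_means is not None:
            mat = (mat - self.feature_means) / self.feature_scales
        design = np.hstack([np.ones((mat.shape[0], 1)), mat])
        return design @ self.coefficients


def fit_ridge(
    X,
    y,
    lam: float = 0.1,
    penalize_intercept: bool = True,
    standardize: bool = False,
    singular_fallback: bool = True,
) -> RidgeModel:
    """Fit the closed-form ridge estimator.

    At ``lam=0`` a singular normal system falls back to the Moore-Penrose
    pseudo-inverse (minimum-norm OLS) unless ``singular_fallback=False``, in
    which case the linearly dependent columns are named in the error.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    mat, names = as_matrix(X)
    target = as_vector(y)
    if mat.shape[0] != target.shape[0]:
        raise ValueError("X and y row counts differ")
    if mat.shape[0] < 1:
        raise ValueError("need at least one training row")

    means = scales = None
    if standardize:
        means = mat.mean(axis=0)
        scales = mat.std(axis=0)
        scales = np.where(scales > 0, scales, 1.0)
        mat = (mat - means) / scales

    design = np.hstack([np.ones((mat.shape[0], 1)), mat])
    p = design.shape[1]
    penalty = np.eye(p)
    if not penalize_intercept:
        penalty[0, 0] = 0.0
    gram = design.T @ design + lam * penalty
    rhs = design.T @ target
    try:
        beta = np.linalg.solve(gram, rhs)
        # `solve` can succeed numerically on a singular system; validate
        if not np.all(np.isfinite(beta)) or (
            lam == 0.0 and np.linalg.matrix_rank(design) < p
        ):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        if not singular_fallback:
            raise SingularDesignError(_dependent_columns(design, names)) from None
        beta = np.linalg.pinv(design) @ target if lam == 0.0 else np.linalg.lstsq(
            gram, rhs, rcond=None
        )[0]
    return RidgeModel(
        coefficients=beta,
        lam=lam,
        columns=names,
        penalize_intercept=penalize_intercept,
        feature_means=means,
        feature_scales=scales,
    )
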