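"""Shared helpers for the model implementations."""

from __future__ import annotations

import numpy as np
import pandas as pd


def as_matrix(
    X: "pd.DataFrame | np.ndarray", columns: tuple[str, ...] | None = None
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Coerce a feature table to float matrix + column names.

    When ``columns`` is given (prediction time), a DataFrame is reindexed to
    the training column order and any discrepancy is reported by name.
    """
    if isinstance(X, pd.DataFrame):
        if columns is not None:
            missing = [c for c in columns if c not in X.columns]
            if missing:
                raise ValueError(f"missing feature columns: {missing}")
            X = X[list(columns)]
            names = tuple(columns)
        else:
            names = tuple(str(c) for c in X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        if columns is not None:
            if mat.shape[1] != len(columns):
                raise ValueError(
                    f"expected {len(columns)} feature columns, got {mat.shape[1]}"
                )
            names = tuple(columns)
        else:
            names = tuple(f"x{i}" for i in range(mat.shape[1]))
    if not np.all(np.isfinite(mat)):
        raise ValueError("feature matrix contains non-finite values")
    return mat, names


def as_vector(y) -> np.ndarray:
    arr = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError("target vector contains non-finite values")
    return arr
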