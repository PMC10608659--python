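"""Four-stage descriptor selection.

1. Low-variance removal: a descriptor whose value equals its mode for at
   least ``mode_fraction`` (default 60%) of the molecules is dropped.
2. Weak target correlation: descriptors whose covariance with the target,
   both z-scored, falls below ``target_corr_min`` (default 0.25) are dropped.
3. Mutual correlation: among the survivors, descriptors correlated above
   ``mutual_corr_max`` (default 0.7) with an already-kept descriptor are
   dropped; the scan is greedy in descending target-correlation order so the
   most label-relevant member of each correlated cluster survives.
4. Backward stepwise regression: descriptors are removed one at a time, each
   time the one whose removal gives the best 5-fold cross-validated R^2 of an
   ordinary least-squares fit, until the best removal would cost more than
   ``stepwise_tolerance`` of CV R^2.

z-scoring uses the population standard deviation (divide by n), which makes
the covariance of two z-scored variables exactly the Pearson correlation.
Correlation thresholds apply to ABSOLUTE values by default: a strong
negative predictor is informative and redundancy is sign-agnostic.  A
signed mode is available for stages 2/3 via ``use_absolute_correlations``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from quinoscreen.models import fit_ridge


@dataclass
class SelectionConfig:
    mode_fraction: float = 0.60
    target_corr_min: float = 0.25
    mutual_corr_max: float = 0.70
    cv_folds: int = 5
    stepwise_tolerance: float = 0.001
    fold_seed: int = 0
    use_absolute_correlations: bool = True
    min_survivors: int = 1


@dataclass
class RemovedColumn:
    column: str
    reason: str
    statistic: float


@dataclass
class StageReport:
    stage: str
    removed: list[RemovedColumn]
    survivors: list[str]

    @property
    def n_survivors(self) -> int:
        return len(self.survivors)


@dataclass
class SelectionReport:
    initial_columns: list[str]
    stages: list[StageReport] = field(default_factory=list)

    @property
    def survivors(self) -> list[str]:
        return self.stages[-1].survivors if self.stages else list(self.initial_columns)

    @property
    def removed_columns(self) -> list[str]:
        return [r.column for st in self.stages for r in st.removed]

    def to_dict(self) -> dict:
        return {
            "initial_columns": self.initial_columns,
            "stages": [asdict(s) for s in self.stages],
            "survivors": self.survivors,
        }


def normalize(values) -> np.ndarray:
    """z-score with the population standard deviation; errors on constants."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("normalization needs at least 2 values")
    sd = arr.std()  # population convention (ddof=0)
    if sd == 0:
        raise ValueError("cannot normalize a constant vector")
    return (arr - arr.mean()) / sd


def _pearson(x: np.ndarray, zy: np.ndarray) -> float:
    """Covariance of z-scored vectors = Pearson r (population convention)."""
    return float(np.mean(normalize(x) * zy))


def low_variance_filter(table: pd.DataFrame, mode_fraction: float = 0.60) -> StageReport:
    """Stage 1: drop columns whose modal value covers >= mode_fraction of rows."""
    if table.shape[0] == 0:
        raise ValueError("empty table")
    removed, survivors = [], []
    n = len(table)
    for col in table.columns:
        top = table[col].value_counts().iloc[0]
        frac = top / n
        if frac >= mode_fraction:
            removed.append(RemovedColumn(col, "low_variance", float(frac)))
        else:
            survivors.append(col)
    return StageReport("low_variance", removed, survivors)


def target_correlation_filter(
    table: pd.DataFrame,
    y,
    threshold: float = 0.25,
    use_absolute: bool = True,
) -> StageReport:
    """Stage 2: drop columns whose (|)correlation(|) with y is below threshold.

    The boundary value (exactly equal) is kept.
    """
    if y is None:
        raise ValueError("target correlation filter requires labels")
    zy = normalize(y)
    removed, survivors = [], []
    for col in table.columns:
        c = _pearson(table[col].to_numpy(), zy)
        stat = abs(c) if use_absolute else c
        if stat < threshold:
            removed.append(RemovedColumn(col, "weak_target_correlation", float(c)))
        else:
            survivors.append(col)
    return StageReport("target_correlation", removed, survivors)


def mutual_correlation_filter(
    table: pd.DataFrame,
    y,
    threshold: float = 0.70,
    use_absolute: bool = True,
) -> StageReport:
    """Stage 3: greedy redundancy removal.

    Columns are ranked by descending |target correlation| (ties by column
    order); a column is kept iff its correlation with every already-kept
    column does not exceed the threshold (boundary kept).
    """
    zy = normalize(y)
    cols = list(table.columns)
    target_corr = {c: _pearson(table[c].to_numpy(), zy) for c in cols}
    ranked = sorted(
        range(len(cols)), key=lambda i: (-abs(target_corr[cols[i]]), i)
    )
    kept: list[str] = []
    removed_map: dict[str, RemovedColumn] = {}
    z = {c: normalize(table[c].to_numpy()) for c in cols}
    for i in ranked:
        col = cols[i]
        clash = None
        for other in kept:
            r = float(np.mean(z[col] * z[other]))
            stat = abs(r) if use_absolute else r
            if stat > threshold:
                clash = (other, r)
                break
        if clash is None:
            kept.append(col)
        else:
            removed_map[col] = RemovedColumn(
                col, f"mutually_correlated_with:{clash[0]}", float(clash[1])
            )
    survivors = [c for c in cols if c not in removed_map]
    return StageReport("mutual_correlation", list(removed_map.values()), survivors)


def _cv_r2_ols(table: pd.DataFrame, y: np.ndarray, folds: int, fold_seed: int) -> float:
    """Mean validation R^2 of an OLS fit (ridge machinery at lambda=0)."""
    from quinoscreen.evaluation import cross_validate  # late import, no cycle at module load

    result = cross_validate(
        lambda X, t: fit_ridge(X, t, lam=0.0),
        table,
        y,
        folds=folds,
        fold_seed=fold_seed,
    )
    return result.mean_val_r2


def backward_stepwise(
    table: pd.DataFrame,
    y,
    folds: int = 5,
    tolerance: float = 0.001,
    fold_seed: int = 0,
    min_survivors: int = 1,
) -> StageReport:
    """Stage 4: iteratively drop the column whose removal best preserves CV R^2.

    Stops when the best removal would lower the current CV R^2 by more than
    ``tolerance``, or when only ``min_survivors`` columns remain.  With fewer
    than 2 columns this is a no-op.
    """
    y = np.asarray(y, dtype=float)
    cols = list(table.columns)
    removed: list[RemovedColumn] = []
    if len(cols) < 2:
        return StageReport("backward_stepwise", removed, cols)
    current = _cv_r2_ols(table[cols], y, folds, fold_seed)
    while len(cols) > max(min_survivors, 1):
        scores = [
            _cv_r2_ols(table[[c for c in cols if c != col]], y, folds, fold_seed)
            for col in cols
        ]
        best_i = int(np.argmax(scores))
        if scores[best_i] < current - tolerance:
            break
        removed.append(
            RemovedColumn(cols[best_i], "stepwise_removal", float(scores[best_i]))
        )
        del cols[best_i]
        current = scores[best_i]
    return StageReport("backward_stepwise", removed, cols)


def select_descriptors(
    table: pd.DataFrame, y, config: SelectionConfig = SelectionConfig()
) -> SelectionReport:
    """Run stages 1-4 in order and return the full audit report."""
    report = SelectionReport(initial_columns=list(table.columns))
    s1 = low_variance_filter(table, config.mode_fraction)
    report.stages.append(s1)
    s2 = target_correlation_filter(
        table[s1.survivors], y, config.target_corr_min, config.use_absolute_correlations
    )
    report.stages.append(s2)
    s3 = mutual_correlation_filter(
        table[s2.survivors], y, config.mutual_corr_max, config.use_absolute_correlations
    )
    report.stages.append(s3)
    s4 = backward_stepwise(
        table[s3.survivors],
        y,
        folds=config.cv_folds,
        tolerance=config.stepwise_tolerance,
        fold_seed=config.fold_seed,
        min_survivors=config.min_survivors,
    )
    report.stages.append(s4)
    return report
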