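"""End-to-end screening pipeline.

Orchestrates the full workflow: obtain a dataset (simulated, or descriptor
and label files), split 80/20, run descriptor selection on the training rows
only, tune each model family by grid search (or use the fixed
study-protocol hyperparameters), fit the final models, and evaluate on the
sealed test rows with trendline diagnostics.  The test rows are never
visible to selection or tuning; a config that asks to lift that guard is
refused outright.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from quinoscreen.evaluation import (
    DEFAULT_FAMILY_PARAMS,
    DEFAULT_GRIDS,
    MODEL_FAMILIES,
    cross_validate,
    grid_search,
    make_fitter,
    r_squared,
    split_dataset,
    trendline,
)
from quinoscreen.models import feature_importances
from quinoscreen.selection import SelectionConfig, select_descriptors
from quinoscreen.synthetic import SyntheticSpec, generate_dataset


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    descriptors_csv: str | None = None  # None -> simulate
    labels_csv: str | None = None
    synthetic: SyntheticSpec | None = None
    train_fraction: float = 0.8
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    families: tuple[str, ...] = MODEL_FAMILIES
    do_grid_search: bool = True
    grids: dict[str, list[dict]] | None = None
    grid_criterion: str = "max_val_r2"
    cv_folds: int = 5
    allow_test_leakage: bool = False  # guard only; True is refused
    out_dir: str | None = None


def _fold_seed(seed: int) -> int:
    """Fold seed decoupled from the split seed, derived deterministically."""
    return int(np.random.SeedSequence([seed, 0xF01D]).generate_state(1)[0] % 2**31)


def _load_tables(config: PipelineConfig) -> tuple[pd.DataFrame, pd.Series]:
    if config.descriptors_csv is None:
        spec = config.synthetic or SyntheticSpec(seed=config.seed)
        ds = generate_dataset(spec)
        return ds.features, ds.labels
    features = pd.read_csv(config.descriptors_csv, index_col=0)
    labels = pd.read_csv(config.labels_csv, index_col=0).iloc[:, 0]
    labels = labels.reindex(features.index)
    if labels.isna().any():
        raise PipelineError("labels missing for some molecules in the descriptor table")
    return features, labels


def run_pipeline(config: PipelineConfig = PipelineConfig()) -> dict:
    """Run the whole workflow and return (and optionally write) the report."""
    if config.allow_test_leakage:
        raise PipelineError(
            "refusing to run with allow_test_leakage=True: descriptor selection "
            "and hyperparameter tuning must never see the test rows, or the "
            "reported test metrics become meaningless"
        )
    features, labels = _load_tables(config)
    n = len(labels)
    split = split_dataset(n, fraction=config.train_fraction, seed=config.seed)
    train_idx, test_idx = list(split.train_ids), list(split.test_ids)
    X_train = features.iloc[train_idx]
    y_train = labels.iloc[train_idx].to_numpy()
    fold_seed = _fold_seed(config.seed)

    sel_config = config.selection
    sel_config.fold_seed = fold_seed
    selection_report = select_descriptors(X_train, y_train, sel_config)
    survivors = selection_report.survivors
    if not survivors:
        raise PipelineError("descriptor selection removed every column")
    X_train_sel = X_train[survivors]

    report: dict = {
        "seed": config.seed,
        "fold_seed": fold_seed,
        "n_molecules": n,
        "n_train": len(train_idx),
        "n_test": len(test_idx),
        "selection": selection_report.to_dict(),
        "models": {},
    }
    predictions = pd.DataFrame(
        {"E_reference": labels.iloc[test_idx].to_numpy()},
        index=features.index[test_idx],
    )

    # test rows stay sealed until this final evaluation loop
    X_test_sel = features.iloc[test_idx][survivors]
    y_test = labels.iloc[test_idx].to_numpy()

    for family in config.families:
        if config.do_grid_search:
            grids = config.grids or DEFAULT_GRIDS
            gs = grid_search(
                lambda **p: make_fitter(family, **p),
                grids[family],
                X_train_sel,
                y_train,
                criterion=config.grid_criterion,
                folds=config.cv_folds,
                fold_seed=fold_seed,
            )
            params = gs.selected_params
            cv = gs.selected_result
            grid_summary = {
                "criterion": gs.criterion,
                "points": [
                    {"params": p, "val_r2": r.mean_val_r2, "train_r2": r.mean_train_r2}
                    for p, r in zip(gs.grid, gs.results)
                ],
            }
        else:
            params = DEFAULT_FAMILY_PARAMS[family]
            cv = cross_validate(
                make_fitter(family, **params),
                X_train_sel,
                y_train,
                folds=config.cv_folds,
                fold_seed=fold_seed,
            )
            grid_summary = None

        model = make_fitter(family, **params)(X_train_sel, y_train)
        y_pred = model.predict(X_test_sel)
        trend = trendline(y_pred, y_test)
        entry = {
            "params": params,
            "cv_train_r2": cv.mean_train_r2,
            "cv_val_r2": cv.mean_val_r2,
            "test_r2": r_squared(y_test, y_pred),
            "trendline": {
                "slope": trend.slope,
                "intercept": trend.intercept,
                "r_squared": trend.r_squared,
            },
        }
        if grid_summary is not None:
            entry["grid_search"] = grid_summary
        if family != "ridge":
            entry["feature_importances"] = feature_importances(model)
        report["models"][family] = entry
        predictions[f"E_{family}"] = y_pred

    ranking = sorted(
        report["models"], key=lambda f: report["models"][f]["cv_val_r2"], reverse=True
    )
    report["cv_ranking"] = ranking

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        predictions.to_csv(out / "predictions.csv", index_label="canonical_smiles")
    report["_predictions"] = predictions
    return report
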