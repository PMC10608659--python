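"""JSON serialization for fitted models.

Floats survive the round trip exactly (Python's repr-based JSON float
encoding is lossless for IEEE doubles), so load -> predict is bit-identical
to the original model.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from quinoscreen.models.ensembles import EnsembleModel
from quinoscreen.models.ridge import RidgeModel
from quinoscreen.models.tree import CartModel, TreeNode


def _node_to_dict(node: TreeNode) -> dict:
    out = {"value": node.value, "n": node.n_samples, "cost": node.cost}
    if not node.is_leaf:
        out.update(
            feature=node.feature,
            threshold=node.threshold,
            left=_node_to_dict(node.left),
            right=_node_to_dict(node.right),
        )
    return out


def _node_from_dict(d: dict) -> TreeNode:
    node = TreeNode(value=d["value"], n_samples=d["n"], cost=d["cost"])
    if "feature" in d:
        node.feature = d["feature"]
        node.threshold = d["threshold"]
        node.left = _node_from_dict(d["left"])
        node.right = _node_from_dict(d["right"])
    return node


def model_to_dict(model) -> dict:
    if isinstance(model, RidgeModel):
        return {
            "kind": "ridge",
            "lambda": model.lam,
            "penalize_intercept": model.penalize_intercept,
            "columns": list(model.columns),
            "intercept": float(model.coefficients[0]),
            "coefficients": {
                c: float(v) for c, v in zip(model.columns, model.coefficients[1:])
            },
            "feature_means": None
            if model.feature_means is None
            else list(map(float, model.feature_means)),
            "feature_scales": None
            if model.feature_scales is None
            else list(map(float, model.feature_scales)),
        }
    if isinstance(model, CartModel):
        return {
            "kind": "cart",
            "columns": list(model.columns),
            "max_depth": model.max_depth,
            "min_samples_leaf": model.min_samples_leaf,
            "cost": model.cost,
            "root": _node_to_dict(model.root),
        }
    if isinstance(model, EnsembleModel):
        return {
            "kind": "ensemble",
            "mode": model.mode,
            "columns": list(model.columns),
            "params": model.params,
            "seed": model.seed,
            "learning_rate": model.learning_rate,
            "initial_value": model.initial_value,
            "trees": [_node_to_dict(t) for t in model.trees],
        }
    raise TypeError(f"cannot serialize {type(model).__name__}")


def model_from_dict(d: dict):
    kind = d["kind"]
    if kind == "ridge":
        columns = tuple(d["columns"])
        coeffs = np.array([d["intercept"]] + [d["coefficients"][c] for c in columns])
        return RidgeModel(
            coefficients=coeffs,
            lam=d["lambda"],
            columns=columns,
            penalize_intercept=d["penalize_intercept"],
            feature_means=None
            if d["feature_means"] is None
            else np.array(d["feature_means"]),
            feature_scales=None
            if d["feature_scales"] is None
            else np.array(d["feature_scales"]),
        )
    if kind == "cart":
        return CartModel(
            root=_node_from_dict(d["root"]),
            columns=tuple(d["columns"]),
            max_depth=d["max_depth"],
            min_samples_leaf=d["min_samples_leaf"],
            cost=d["cost"],
        )
    if kind == "ensemble":
        return EnsembleModel(
            mode=d["mode"],
            trees=[_node_from_dict(t) for t in d["trees"]],
            columns=tuple(d["columns"]),
            params=d["params"],
            seed=d["seed"],
            learning_rate=d["learning_rate"],
            initial_value=d["initial_value"],
        )
    raise ValueError(f"unknown model kind {kind!r}")


def save_model(model, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path: str | Path):
    with open(path) as fh:
        return model_from_dict(json.load(fh))
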