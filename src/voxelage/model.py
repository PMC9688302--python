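"""Gradient-boosted age regression and a faithful internal tree export.

The regression ``y = f(x, beta) + e`` (age as a function of voxel GMV) is
fitted with XGBoost, but the fitted booster is immediately exported into an
explicit :class:`TreeNode` representation carrying split features,
thresholds, per-node covers (training-sample weight reaching the node) and
leaf values.  Everything downstream — prediction and the entire Shapley
engine — consumes only this internal form, so the decomposition is defined
by a model we can walk and audit, not by library internals.

Split convention: a sample goes **left iff x[feature] < threshold**,
matching the booster's "yes" branch.  XGBoost stores features and
accumulates predictions in float32; :func:`predict` therefore routes
samples after casting to float32 and offers a float32-mirrored accumulation
mode that reproduces the library's output bitwise, alongside the float64
mode used internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import xgboost as xgb

from .config import GBTParams


@dataclass
class TreeNode:
    """One node of a regression tree: either a split or a leaf.

    ``cover`` is the (weighted) number of training samples reaching the
    node; it is the weight used for conditional expectations over features
    outside the conditioning set, so ``cover(parent) = cover(left) +
    cover(right)`` is load-bearing.
    """

    cover: float
    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    leaf_value: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf_value is not None

    def validate(self) -> None:
        if self.cover <= 0:
            raise ValueError(f"node cover must be > 0, got {self.cover}")
        if self.is_leaf:
            if self.feature is not None or self.left is not None:
                raise ValueError("node is both leaf and split")
        else:
            if self.feature is None or self.left is None or self.right is None:
                raise ValueError("split node missing feature or children")
            child_sum = self.left.cover + self.right.cover
            if not np.isclose(child_sum, self.cover, rtol=1e-6, atol=1e-6):
                raise ValueError(
                    f"cover mismatch: parent {self.cover} vs children {child_sum}"
                )
            self.left.validate()
            self.right.validate()


@dataclass
class EnsembleModel:
    """An additive tree ensemble: prediction = base_score + sum of leaf values."""

    trees: list[TreeNode]
    base_score: float
    n_features: int
    meta: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        for t in self.trees:
            t.validate()


@dataclass
class SplitResult:
    train_idx: np.ndarray
    test_idx: np.ndarray
    test_fraction: float
    seed: int


def train_test_split(n: int, test_fraction: float = 0.15, seed: int = 0) -> SplitResult:
    """Uniform random train/test split with |test| = round(test_fraction * n)."""
    if n < 2:
        raise ValueError(f"need >= 2 subjects to split, got {n}")
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    n_test = int(round(test_fraction * n))
    if n_test == 0 or n_test == n:
        raise ValueError(
            f"test_fraction={test_fraction} yields an empty train or test set for n={n}"
        )
    perm = np.random.default_rng(seed).permutation(n)
    return SplitResult(
        train_idx=np.sort(perm[n_test:]),
        test_idx=np.sort(perm[:n_test]),
        test_fraction=test_fraction,
        seed=seed,
    )


# -- booster export ----------------------------------------------------------


def _parse_dump_node(node: dict[str, Any]) -> TreeNode:
    if "leaf" in node:
        return TreeNode(cover=float(node["cover"]), leaf_value=float(node["leaf"]))
    children = {c["nodeid"]: c for c in node["children"]}
    split = node["split"]
    feature = int(split[1:]) if split.startswith("f") else int(split)
    return TreeNode(
        cover=float(node["cover"]),
        feature=feature,
        threshold=float(node["split_condition"]),
        left=_parse_dump_node(children[node["yes"]]),
        right=_parse_dump_node(children[node["no"]]),
    )


def export_booster(booster: xgb.Booster, n_features: int) -> EnsembleModel:
    """Export a fitted booster into the internal TreeNode representation."""
    dump = booster.get_dump(with_stats=True, dump_format="json")
    trees = [_parse_dump_node(json.loads(t)) for t in dump]
    cfg = json.loads(booster.save_config())
    base_score = float(cfg["learner"]["learner_model_param"]["base_score"])
    model = EnsembleModel(trees=trees, base_score=base_score, n_features=n_features)
    model.validate()
    return model


def fit(
    X_train: np.ndarray,
    y_train: np.ndarray,
    params: GBTParams | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Fit the boosted regression and export it to the internal form.

    Single-threaded and seeded, so refitting with the same inputs is
    bit-reproducible.  The exported model's float32-mirrored predictions
    match the booster's exactly (checked here on the training rows).
    """
    params = params or GBTParams()
    params.validate()
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if not np.all(np.isfinite(y_train)):
        raise ValueError("y_train contains non-finite values")
    if not np.all(np.isfinite(X_train)):
        raise ValueError("X_train contains non-finite values")
    if X_train.shape[0] < 10:
        raise ValueError(f"need >= 10 training subjects, got {X_train.shape[0]}")

    dtrain = xgb.DMatrix(X_train, label=y_train)
    booster = xgb.train(
        {
            "objective": "reg:squarederror",
            "max_depth": params.max_depth,
            "eta": params.learning_rate,
            "subsample": params.subsample,
            "colsample_bytree": params.colsample_bytree,
            "base_score": float(np.mean(y_train)),
            "seed": seed,
            "nthread": 1,
        },
        dtrain,
        num_boost_round=params.n_rounds,
    )
    model = export_booster(booster, n_features=X_train.shape[1])
    model.meta = {
        "rounds": params.n_rounds,
        "depth": params.max_depth,
        "learning_rate": params.learning_rate,
        "subsample": params.subsample,
        "seed": seed,
    }
    lib = booster.predict(dtrain)
    mine = predict(model, X_train, accumulate="float32")
    fidelity = float(np.max(np.abs(lib - mine))) if len(lib) else 0.0
    model.meta["export_fidelity"] = fidelity
    if fidelity > 1e-9:
        raise RuntimeError(f"tree export does not reproduce booster predictions ({fidelity})")
    return model


def _route(node: TreeNode, x32: np.ndarray) -> float:
    while not node.is_leaf:
        node = node.left if x32[node.feature] < np.float32(node.threshold) else node.right
    return node.leaf_value


def predict(model: EnsembleModel, X: np.ndarray, accumulate: str = "float64") -> np.ndarray:
    """Predict ages from the exported trees.

    Routing always compares features to thresholds in float32, as the
    originating library does.  ``accumulate="float64"`` (default) sums leaf
    values in double precision — the canonical internal prediction that the
    Shapley decomposition reproduces exactly.  ``accumulate="float32"``
    mirrors the library's float32 running sum and matches its output bitwise.
    """
    X = np.atleast_2d(np.asarray(X))
    if X.shape[1] != model.n_features:
        raise ValueError(f"X has {X.shape[1]} features, model expects {model.n_features}")
    X32 = X.astype(np.float32)
    out = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        if accumulate == "float32":
            acc = np.float32(model.base_score)
            for t in model.trees:
                acc = np.float32(acc + np.float32(_route(t, X32[i])))
            out[i] = acc
        else:
            out[i] = model.base_score + sum(_route(t, X32[i]) for t in model.trees)
    return out


def mae(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute error in years."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    return float(np.mean(np.abs(y_true - y_pred)))


def select_peak_voxels(importance: np.ndarray, k: int) -> np.ndarray:
    """Top-``k`` features by an importance score (e.g. mean |Shapley value|).

    Stable ranking: importance descending, ties broken by ascending feature
    index.  Correlated neighboring voxels share signal, so the top-ranked
    voxel of a neighborhood stands in for the region ("peak voxel").
    """
    importance = np.asarray(importance, dtype=float)
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    if k > importance.size:
        raise ValueError(f"k={k} exceeds feature count {importance.size}")
    order = np.lexsort((np.arange(importance.size), -importance))
    return order[:k]


# -- serialization -----------------------------------------------------------


def _node_to_dict(node: TreeNode) -> dict[str, Any]:
    if node.is_leaf:
        return {"cover": node.cover, "leaf": node.leaf_value}
    return {
        "cover": node.cover,
        "feature": node.feature,
        "threshold": node.threshold,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
    }


def _node_from_dict(d: dict[str, Any]) -> TreeNode:
    if "leaf" in d:
        return TreeNode(cover=d["cover"], leaf_value=d["leaf"])
    return TreeNode(
        cover=d["cover"],
        feature=d["feature"],
        threshold=d["threshold"],
        left=_node_from_dict(d["left"]),
        right=_node_from_dict(d["right"]),
    )


def save_model(model: EnsembleModel, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "base_score": model.base_score,
                "n_features": model.n_features,
                "meta": model.meta,
                "trees": [_node_to_dict(t) for t in model.trees],
            },
            fh,
        )


def load_model(path: str) -> EnsembleModel:
    with open(path) as fh:
        d = json.load(fh)
    model = EnsembleModel(
        trees=[_node_from_dict(t) for t in d["trees"]],
        base_score=d["base_score"],
        n_features=d["n_features"],
        meta=d.get("meta", {}),
    )
    model.validate()
    return model
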