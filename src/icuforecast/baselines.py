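"""Comparator models: Random Forest regression and the sampling baseline.

The RF regresses the observed remaining length of stay directly on the 19
predictors — censored entries' observed times are used as-is, with no
censoring adjustment, mirroring how a plain regression comparator treats the
data. Trees are grown on bootstrap samples with residual-sum-of-squares
splits over ``mtry`` random candidate variables; a terminal node predicts the
mean of its in-node targets (a single-case node predicts that case's
target), and the ensemble prediction is the arithmetic mean over trees.

The sampling baseline predicts a patient's remaining stay by drawing a
random entry from the training data and using its remaining-stay value, so
predictions follow the training distribution exactly but ignore the
patient's covariates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from ._tree import BinnedFeatures, Tree, best_rss_split, grow_tree, route
from .dataset import SupervisedDataset

__all__ = ["RfParams", "RfModel", "fit_rf", "predict_rf", "baseline_sample_los"]


@dataclass(frozen=True)
class RfParams:
    """Random Forest regression hyperparameters.

    ``mtry`` defaults to ceil(p/3) (7 for the 19 occupancy predictors);
    nodes with at most ``min_node_size`` cases are not split further.
    """

    n_trees: int = 1000
    mtry: Optional[int] = None
    min_node_size: int = 5
    max_depth: Optional[int] = None
    seed: int = 0
    bootstrap: bool = True

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError("max_depth must be >= 0 or None")
        # max_depth=0 grows root-only trees predicting the in-bag mean.

    def resolved_mtry(self, n_features: int) -> int:
        if self.mtry is not None:
            return min(self.mtry, n_features)
        return min(n_features, math.ceil(n_features / 3))


@dataclass
class RfModel:
    """A fitted Random Forest regressor."""

    trees: list[Tree]
    leaf_values: list[np.ndarray]
    oob_indices: list[np.ndarray]
    params: RfParams
    feature_names: list[str]
    n_train: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def predict(self, X) -> np.ndarray:
        """Ensemble prediction: mean over trees of the reached leaf values."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} predictors, got {X.shape[1]}"
            )
        out = np.zeros(len(X))
        for tree, values in zip(self.trees, self.leaf_values):
            out += values[route(tree, X)]
        return out / self.n_trees

    def to_dict(self) -> dict:
        return {
            "model": "random_forest_regression",
            "params": {
                "n_trees": self.params.n_trees,
                "mtry": self.params.mtry,
                "min_node_size": self.params.min_node_size,
                "max_depth": self.params.max_depth,
                "seed": self.params.seed,
                "bootstrap": self.params.bootstrap,
            },
            "feature_names": list(self.feature_names),
            "n_train": self.n_train,
            "trees": [
                {**tree.to_dict(), "leaves": values.tolist(), "oob": oob.tolist()}
                for tree, values, oob in zip(
                    self.trees, self.leaf_values, self.oob_indices
                )
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "RfModel":
        if d.get("model") != "random_forest_regression":
            raise ValueError("not a serialized random forest regressor")
        return cls(
            trees=[Tree.from_dict(td) for td in d["trees"]],
            leaf_values=[np.asarray(td["leaves"], dtype=float) for td in d["trees"]],
            oob_indices=[np.asarray(td["oob"], dtype=int) for td in d["trees"]],
            params=RfParams(**d["params"]),
            feature_names=list(d["feature_names"]),
            n_train=int(d["n_train"]),
        )

    @classmethod
    def from_json(cls, path) -> "RfModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_rf(
    dataset: Union[SupervisedDataset, tuple], params: RfParams = RfParams()
) -> RfModel:
    """Fit a Random Forest regression of remaining length of stay."""
    if isinstance(dataset, SupervisedDataset):
        X = dataset.X
        y = dataset.remaining_los.astype(float)
        feature_names = list(dataset.feature_names)
    else:
        X, y = dataset[0], dataset[1]
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    n, p = X.shape
    if n == 0:
        raise ValueError("dataset is empty")
    mtry = params.resolved_mtry(p)
    binned = BinnedFeatures(X)

    trees: list[Tree] = []
    leaf_values: list[np.ndarray] = []
    oob_indices: list[np.ndarray] = []
    for b in range(params.n_trees):
        rng = np.random.default_rng(np.random.SeedSequence((params.seed, b)))
        if params.bootstrap:
            in_bag = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), in_bag)
        else:
            in_bag = np.arange(n)
            oob = np.empty(0, dtype=int)

        def split_fn(idx: np.ndarray, depth: int):
            if len(idx) <= params.min_node_size:
                return None
            if params.max_depth is not None and depth >= params.max_depth:
                return None
            feats = np.sort(rng.choice(p, size=mtry, replace=False))
            best = best_rss_split(binned, y, idx, feats)
            if best is None:
                return None
            return best[0], best[1]

        def leaf_fn(idx: np.ndarray) -> float:
            return float(y[idx].mean())

        tree, payloads = grow_tree(X, in_bag, split_fn, leaf_fn)
        trees.append(tree)
        leaf_values.append(np.asarray(payloads, dtype=float))
        oob_indices.append(oob)

    return RfModel(
        trees=trees,
        leaf_values=leaf_values,
        oob_indices=oob_indices,
        params=params,
        feature_names=feature_names,
        n_train=n,
    )


def predict_rf(model: RfModel, X) -> np.ndarray:
    """Predicted remaining length of stay (days) for each row of ``X``."""
    return model.predict(X)


def baseline_sample_los(
    training_targets, rng: np.random.Generator, size: Optional[int] = None
):
    """Sampling baseline: draw predicted remaining stays from the training pool.

    Each prediction is a uniform draw (with replacement across calls) from
    the observed remaining-stay values of the training entries, so predictions
    follow the data distribution but ignore covariates. With ``size=None`` a
    single scalar is returned, otherwise an array of draws.
    """
    pool = np.asarray(training_targets, dtype=float)
    if pool.ndim != 1 or len(pool) == 0:
        raise ValueError("training_targets must be a non-empty 1-D array")
    picks = rng.integers(0, len(pool), size=size)
    return pool[picks]
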