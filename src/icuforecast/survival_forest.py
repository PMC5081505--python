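"""Random Survival Forest for right-censored remaining length of stay.

Each of B trees is grown on a bootstrap sample of the dataset entries. At
every node a random subset of ``mtry`` predictors is considered; for each
candidate variable every midpoint between consecutive distinct values is a
candidate cut, and the split chosen maximizes the absolute standardized
two-sample log-rank statistic between the daughters. A node becomes terminal
when no cut would leave both daughters with more than ``min_unique_deaths``
distinct event times (or no valid cut exists). Terminal nodes carry the
Nelson-Aalen cumulative hazard estimated from the in-bag cases that reached
them; a case dropped through a tree lands in exactly one terminal node and
receives that node's hazard. The ensemble cumulative hazard of a case is the
plain average of its B terminal hazards, and the corresponding survival
function is ``S(t) = exp(-CHF(t))`` — the probability of still occupying a
bed ``t`` days after the prediction morning.

Out-of-bag (OOB) index sets are recorded per tree so the forest supports an
internal error estimate (1 - Harrell concordance of ensemble OOB mortality)
and Breiman-Cutler permutation importance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from ._tree import BinnedFeatures, Tree, best_logrank_split, grow_tree, route
from .dataset import SupervisedDataset
from .stats import harrell_concordance, nelson_aalen
from .stepfun import StepFunction

__all__ = [
    "RsfParams",
    "SurvivalForestModel",
    "fit_rsf",
    "ensemble_chf",
    "survival_function",
    "oob_concordance_error",
]


@dataclass(frozen=True)
class RsfParams:
    """Random Survival Forest hyperparameters.

    ``n_trees`` defaults to 1000 and ``mtry`` to ceil(sqrt(p)) (5 for the 19
    occupancy predictors); ``min_unique_deaths`` is the d0 > 0 of the
    stopping rule: a split must leave each daughter with more than d0
    distinct event times. With heavily tied daily times a handful of unique
    event times can still mean a tiny risk set, whose Nelson-Aalen estimate
    saturates well short of the true cumulative hazard; ``min_node_size``
    therefore additionally forbids daughters smaller than the given number
    of cases (15 is the survival default of mainstream RSF software), which
    keeps terminal hazards stable. ``bootstrap=False`` trains every tree on
    the full dataset (useful for oracle checks).
    """

    n_trees: int = 1000
    mtry: Optional[int] = None
    min_unique_deaths: int = 3
    min_node_size: int = 15
    max_depth: Optional[int] = None
    seed: int = 0
    bootstrap: bool = True

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_unique_deaths < 1:
            raise ValueError("min_unique_deaths (d0) must be > 0")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError("max_depth must be >= 0 or None")
        # max_depth=0 grows root-only trees: each tree is the plain
        # Nelson-Aalen estimator of its (in-bag) sample.

    def resolved_mtry(self, n_features: int) -> int:
        if self.mtry is not None:
            return min(self.mtry, n_features)
        return min(n_features, math.ceil(math.sqrt(n_features)))


@dataclass
class SurvivalForestModel:
    """A fitted Random Survival Forest."""

    trees: list[Tree]
    leaf_chfs: list[list[StepFunction]]
    oob_indices: list[np.ndarray]
    params: RsfParams
    feature_names: list[str]
    n_train: int
    event_times: np.ndarray  # distinct observed event times in training data

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def _check_x(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} predictors, got {X.shape[1]}"
            )
        return X

    def predict_chf_matrix(self, X, times) -> np.ndarray:
        """Ensemble cumulative hazard for each row of ``X`` at each time.

        Returns an (n, len(times)) array: the average over trees of the
        terminal-node Nelson-Aalen estimator reached by each case.
        """
        X = self._check_x(X)
        times = np.asarray(times, dtype=float)
        out = np.zeros((len(X), len(times)))
        for tree, chfs in zip(self.trees, self.leaf_chfs):
            leaf_vals = np.stack([sf(times) for sf in chfs])
            out += leaf_vals[route(tree, X)]
        return out / self.n_trees

    def predict_survival_matrix(self, X, times) -> np.ndarray:
        """Per-case survival probabilities ``exp(-CHF)`` at each time."""
        return np.exp(-self.predict_chf_matrix(X, times))

    def to_dict(self) -> dict:
        return {
            "model": "random_survival_forest",
            "params": {
                "n_trees": self.params.n_trees,
                "mtry": self.params.mtry,
                "min_unique_deaths": self.params.min_unique_deaths,
                "min_node_size": self.params.min_node_size,
                "max_depth": self.params.max_depth,
                "seed": self.params.seed,
                "bootstrap": self.params.bootstrap,
            },
            "feature_names": list(self.feature_names),
            "n_train": self.n_train,
            "event_times": self.event_times.tolist(),
            "trees": [
                {
                    **tree.to_dict(),
                    "leaves": [
                        {"x": sf.x.tolist(), "y": sf.y.tolist()} for sf in chfs
                    ],
                    "oob": oob.tolist(),
                }
                for tree, chfs, oob in zip(
                    self.trees, self.leaf_chfs, self.oob_indices
                )
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalForestModel":
        if d.get("model") != "random_survival_forest":
            raise ValueError("not a serialized random survival forest")
        trees, chfs, oobs = [], [], []
        for td in d["trees"]:
            trees.append(Tree.from_dict(td))
            chfs.append(
                [StepFunction(np.asarray(lf["x"]), np.asarray(lf["y"]))
                 for lf in td["leaves"]]
            )
            oobs.append(np.asarray(td["oob"], dtype=int))
        return cls(
            trees=trees,
            leaf_chfs=chfs,
            oob_indices=oobs,
            params=RsfParams(**d["params"]),
            feature_names=list(d["feature_names"]),
            n_train=int(d["n_train"]),
            event_times=np.asarray(d["event_times"], dtype=float),
        )

    @classmethod
    def from_json(cls, path) -> "SurvivalForestModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _extract_arrays(
    dataset: Union[SupervisedDataset, tuple],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    if isinstance(dataset, SupervisedDataset):
        return (
            dataset.X,
            dataset.remaining_los.astype(float),
            dataset.event,
            list(dataset.feature_names),
        )
    X, y, e = dataset
    X = np.asarray(X, dtype=float)
    return X, np.asarray(y, dtype=float), np.asarray(e, dtype=bool), [
        f"f{j}" for j in range(X.shape[1])
    ]


def fit_rsf(
    dataset: Union[SupervisedDataset, tuple], params: RsfParams = RsfParams()
) -> SurvivalForestModel:
    """Fit a Random Survival Forest.

    ``dataset`` is a :class:`SupervisedDataset` or an ``(X, time, event)``
    tuple. Raises when the data holds fewer distinct event times than the
    ``min_unique_deaths`` stopping parameter requires.
    """
    X, y, e, feature_names = _extract_arrays(dataset)
    n, p = X.shape
    if n == 0:
        raise ValueError("dataset is empty")
    unique_event_times = np.unique(y[e])
    if len(unique_event_times) < params.min_unique_deaths:
        raise ValueError(
            f"{len(unique_event_times)} unique event times in the dataset, "
            f"need at least min_unique_deaths={params.min_unique_deaths}"
        )
    all_times = np.unique(y)
    t_idx = np.searchsorted(all_times, y)
    n_times = len(all_times)
    mtry = params.resolved_mtry(p)
    d0 = params.min_unique_deaths
    binned = BinnedFeatures(X)

    trees: list[Tree] = []
    leaf_chfs: list[list[StepFunction]] = []
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
            if len(idx) < 2:
                return None
            if params.max_depth is not None and depth >= params.max_depth:
                return None
            feats = np.sort(rng.choice(p, size=mtry, replace=False))
            best = best_logrank_split(
                binned, t_idx, e, idx, feats, n_times, d0, params.min_node_size
            )
            if best is None:
                return None
            return best[0], best[1]

        def leaf_fn(idx: np.ndarray) -> StepFunction:
            return nelson_aalen(y[idx], e[idx])

        tree, payloads = grow_tree(X, in_bag, split_fn, leaf_fn)
        trees.append(tree)
        leaf_chfs.append(payloads)
        oob_indices.append(oob)

    return SurvivalForestModel(
        trees=trees,
        leaf_chfs=leaf_chfs,
        oob_indices=oob_indices,
        params=params,
        feature_names=feature_names,
        n_train=n,
        event_times=unique_event_times,
    )


def ensemble_chf(model: SurvivalForestModel, x) -> StepFunction:
    """Ensemble cumulative hazard for one case, as a step function.

    The knots are the union of all terminal-node knots reached by ``x``;
    the value at each knot is the average of the B terminal hazards there.
    """
    x = np.asarray(x, dtype=float).reshape(1, -1)
    reached: list[StepFunction] = []
    for tree, chfs in zip(model.trees, model.leaf_chfs):
        reached.append(chfs[route(tree, x)[0]])
    knots = np.unique(np.concatenate([sf.x for sf in reached] or [np.empty(0)]))
    if len(knots) == 0:
        return StepFunction(np.empty(0), np.empty(0))
    values = np.mean([sf(knots) for sf in reached], axis=0)
    return StepFunction(knots, values)


def survival_function(chf: StepFunction) -> StepFunction:
    """Survival function ``S(t) = exp(-CHF(t))`` of a cumulative hazard.

    ``S`` is 1 before the first event knot, non-increasing, and in (0, 1].
    Raises when the input is not a valid cumulative hazard (negative or
    decreasing).
    """
    if len(chf.y) and (np.any(chf.y < 0) or not chf.is_nondecreasing):
        raise ValueError("input is not a valid cumulative hazard function")
    return StepFunction(chf.x.copy(), np.exp(-chf.y), baseline=1.0)


def oob_concordance_error(
    model: SurvivalForestModel, dataset: Union[SupervisedDataset, tuple]
) -> float:
    """Out-of-bag prediction error: 1 - Harrell concordance.

    Each case's OOB mortality is its ensemble cumulative hazard — averaged
    over only the trees for which the case is out of bag — summed over the
    training event-time grid. Raises when some case is in bag in every tree
    (increase ``n_trees``).
    """
    X, y, e, _ = _extract_arrays(dataset)
    n = len(X)
    grid = model.event_times
    mortality = np.zeros(n)
    counts = np.zeros(n)
    for tree, chfs, oob in zip(model.trees, model.leaf_chfs, model.oob_indices):
        if len(oob) == 0:
            continue
        leaf_sums = np.array([sf(grid).sum() for sf in chfs])
        mortality[oob] += leaf_sums[route(tree, X[oob])]
        counts[oob] += 1
    if np.any(counts == 0):
        missing = int(np.sum(counts == 0))
        raise ValueError(
            f"{missing} case(s) never out of bag; increase n_trees"
        )
    return 1.0 - harrell_concordance(y, e, mortality / counts)
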