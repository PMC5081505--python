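"""Evaluation: the resampled occupancy error E, cross-validation, importance.

The error measure E scores a method on one test fold: 100 times, a group of
25 test entries is sampled without replacement — a random occupation of a
25-bed unit — the method's predicted occupancy curve and the actual
occupancy curve are built, both truncated to days 0..10, and their mean
absolute error is taken; E is the average over the 100 rounds, in beds.

Cross-validation runs this over k folds (grouped by patient by default so a
patient's sliding-window entries never straddle train and test) for several
methods, and compares methods pairwise with the Wilcoxon rank-sum test with
continuity correction on the k per-fold E values.

Permutation importance is the Breiman-Cutler measure: per tree, each
feature is permuted among that tree's out-of-bag cases and the increase in
the tree's OOB error (1 - Harrell concordance for the survival forest, mean
squared error for the regression forest) is recorded, then averaged over
trees and normalized to relative scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, runtime_checkable

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._tree import route
from .baselines import RfModel, RfParams, baseline_sample_los, fit_rf
from .dataset import SupervisedDataset
from .occupancy import pointwise_curve_matrix
from .stats import harrell_concordance
from .survival_forest import RsfParams, SurvivalForestModel, fit_rsf

__all__ = [
    "EvalConfig",
    "EvaluationReport",
    "RsfOccupancyMethod",
    "RfPointwiseMethod",
    "SamplingBaselineMethod",
    "OracleMethod",
    "error_measure_E",
    "cross_validate",
    "permutation_importance",
]


@dataclass(frozen=True)
class EvalConfig:
    """Parameters of the E protocol and the cross-validation design."""

    k_folds: int = 10
    group_size: int = 25
    repetitions: int = 100
    horizon: int = 10
    seed: int = 0
    fold_grouping: str = "by_patient"

    def __post_init__(self) -> None:
        for name in ("k_folds", "group_size", "repetitions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        if self.fold_grouping not in ("by_patient", "by_entry"):
            raise ValueError("fold_grouping must be 'by_patient' or 'by_entry'")


@runtime_checkable
class OccupancyMethod(Protocol):  # pragma: no cover - structural type
    name: str
    per_round: bool
    uses_truth: bool

    def fit(self, dataset: SupervisedDataset) -> None: ...

    def entry_curves(self, X, horizon: int, rng=None) -> np.ndarray: ...


class RsfOccupancyMethod:
    """Survival-forest occupancy: per-entry survival curves summed per group."""

    per_round = False
    uses_truth = False

    def __init__(self, params: Optional[RsfParams] = None, name: str = "rsf"):
        self.params = params or RsfParams()
        self.name = name
        self.model: Optional[SurvivalForestModel] = None

    def fit(self, dataset: SupervisedDataset) -> None:
        self.model = fit_rsf(dataset, self.params)

    def entry_curves(self, X, horizon: int, rng=None) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("method not fitted")
        days = np.arange(horizon + 1, dtype=float)
        return self.model.predict_survival_matrix(X, days)


class RfPointwiseMethod:
    """RF regression of remaining stay, turned into 0/1 occupancy rows."""

    per_round = False
    uses_truth = False

    def __init__(self, params: Optional[RfParams] = None, name: str = "rf"):
        self.params = params or RfParams()
        self.name = name
        self.model: Optional[RfModel] = None

    def fit(self, dataset: SupervisedDataset) -> None:
        self.model = fit_rf(dataset, self.params)

    def entry_curves(self, X, horizon: int, rng=None) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("method not fitted")
        return pointwise_curve_matrix(self.model.predict(X), horizon)


class SamplingBaselineMethod:
    """Baseline: predict each patient's stay by sampling a training entry."""

    per_round = True
    uses_truth = False

    def __init__(self, name: str = "baseline"):
        self.name = name
        self.targets: Optional[np.ndarray] = None

    def fit(self, dataset: SupervisedDataset) -> None:
        self.targets = dataset.remaining_los.astype(float)

    def entry_curves(self, X, horizon: int, rng=None) -> np.ndarray:
        if self.targets is None:
            raise RuntimeError("method not fitted")
        if rng is None:
            raise ValueError("the sampling baseline needs an rng per round")
        preds = baseline_sample_los(self.targets, rng, size=len(X))
        return pointwise_curve_matrix(preds, horizon)


class OracleMethod:
    """Perfect forecaster: load_pred := load_real. E is identically 0."""

    per_round = False
    uses_truth = True
    name = "oracle"

    def fit(self, dataset: SupervisedDataset) -> None:
        pass

    def entry_curves(self, X, horizon: int, rng=None) -> np.ndarray:
        raise RuntimeError("the oracle reads the actual occupancy directly")


def error_measure_E(
    method,
    train_fold: SupervisedDataset,
    test_fold: SupervisedDataset,
    config: EvalConfig = EvalConfig(),
    fold_id: int = 0,
) -> float:
    """Resampled occupancy error E of one method on one fold, in beds.

    The method is fitted on ``train_fold`` only. Group sampling positions are
    drawn from a canonicalized ordering of the test entries (sorted by
    patient and index day), so E does not depend on the order the entries
    arrive in. Deterministic given ``config.seed`` and ``fold_id``.
    """
    n_test = len(test_fold)
    if n_test < config.group_size:
        raise ValueError(
            f"test fold has {n_test} entries, smaller than "
            f"group_size={config.group_size}"
        )
    order = np.lexsort((test_fold.index_day, test_fold.patient_id))
    test = test_fold.subset(order)
    method.fit(train_fold)

    sampling_rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, 101, fold_id))
    )
    pred_rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, 202, fold_id))
    )
    real_rows = pointwise_curve_matrix(test.remaining_los, config.horizon)
    curves = None
    if not method.per_round and not method.uses_truth:
        curves = method.entry_curves(test.X, config.horizon)
    maes = np.empty(config.repetitions)
    for r in range(config.repetitions):
        idx = sampling_rng.choice(n_test, size=config.group_size, replace=False)
        load_real = real_rows[idx].sum(axis=0)
        if method.uses_truth:
            load_pred = load_real
        elif method.per_round:
            load_pred = method.entry_curves(
                test.X[idx], config.horizon, pred_rng
            ).sum(axis=0)
        else:
            load_pred = curves[idx].sum(axis=0)
        maes[r] = np.mean(np.abs(load_pred - load_real))
    return float(maes.mean())


@dataclass
class EvaluationReport:
    """Per-method, per-fold E values plus pairwise rank-sum comparisons."""

    e_values: dict[str, list[float]]
    pairwise_p: dict[str, float]
    config: EvalConfig
    fold_sizes: list[int] = field(default_factory=list)

    def median(self, method: str) -> float:
        return float(np.median(self.e_values[method]))

    def to_dict(self) -> dict:
        return {
            "e_values": {k: list(map(float, v)) for k, v in self.e_values.items()},
            "median_E": {k: self.median(k) for k in self.e_values},
            "pairwise_wilcoxon_ranksum_p": dict(self.pairwise_p),
            "fold_sizes": list(self.fold_sizes),
            "config": {
                "k_folds": self.config.k_folds,
                "group_size": self.config.group_size,
                "repetitions": self.config.repetitions,
                "horizon": self.config.horizon,
                "seed": self.config.seed,
                "fold_grouping": self.config.fold_grouping,
            },
        }


def _fold_assignment(
    dataset: SupervisedDataset, config: EvalConfig
) -> np.ndarray:
    """Fold index per entry; by default whole patients go to one fold."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7)))
    n = len(dataset)
    if config.fold_grouping == "by_entry":
        perm = rng.permutation(n)
        fold_of_entry = np.empty(n, dtype=int)
        fold_of_entry[perm] = np.arange(n) % config.k_folds
        return fold_of_entry
    patients = np.unique(dataset.patient_id)
    perm = rng.permutation(len(patients))
    fold_of_patient = np.empty(len(patients), dtype=int)
    fold_of_patient[perm] = np.arange(len(patients)) % config.k_folds
    lookup = dict(zip(patients.tolist(), fold_of_patient.tolist()))
    return np.array([lookup[p] for p in dataset.patient_id.tolist()])


def cross_validate(
    dataset: SupervisedDataset,
    method_factories: dict[str, Callable[[], object]],
    config: EvalConfig = EvalConfig(),
) -> EvaluationReport:
    """k-fold cross-validated E for each method, with pairwise rank-sum tests.

    Group sampling positions are shared across methods within a fold, so the
    per-fold comparison is paired on the sampled groups.
    """
    folds = _fold_assignment(dataset, config)
    fold_sizes = [int(np.sum(folds == i)) for i in range(config.k_folds)]
    if min(fold_sizes) < config.group_size:
        raise ValueError(
            f"smallest fold has {min(fold_sizes)} entries, smaller than "
            f"group_size={config.group_size}; reduce k_folds or group_size"
        )
    e_values: dict[str, list[float]] = {name: [] for name in method_factories}
    for i in range(config.k_folds):
        test_mask = folds == i
        train = dataset.subset(~test_mask)
        test = dataset.subset(test_mask)
        for name, factory in method_factories.items():
            e_values[name].append(
                error_measure_E(factory(), train, test, config, fold_id=i)
            )
    pairwise: dict[str, float] = {}
    names = list(method_factories)
    for a_i, a in enumerate(names):
        for b in names[a_i + 1 :]:
            res = sps.mannwhitneyu(
                e_values[a],
                e_values[b],
                use_continuity=True,
                alternative="two-sided",
                method="asymptotic",
            )
            pairwise[f"{a}_vs_{b}"] = float(res.pvalue)
    return EvaluationReport(
        e_values=e_values,
        pairwise_p=pairwise,
        config=config,
        fold_sizes=fold_sizes,
    )


def _rsf_tree_risk(model: SurvivalForestModel, b: int, X: np.ndarray) -> np.ndarray:
    grid = model.event_times
    leaf_sums = np.array([sf(grid).sum() for sf in model.leaf_chfs[b]])
    return leaf_sums[route(model.trees[b], X)]


def permutation_importance(
    model,
    dataset: SupervisedDataset,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Breiman-Cutler permutation variable importance of a fitted forest.

    For every tree and feature, the feature's values are permuted among the
    tree's out-of-bag cases and the increase of the tree-level OOB error is
    recorded; raw importance is the average increase over trees. Normalized
    scores clip negatives to zero and divide by the total (uniform when every
    raw importance is <= 0). Works for both forest types: the survival
    forest's error is 1 - Harrell concordance of the tree's OOB mortality,
    the regression forest's is OOB mean squared error.

    Returns a DataFrame with columns ``feature``, ``raw``, ``normalized``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    X = dataset.X
    y = dataset.remaining_los.astype(float)
    e = dataset.event
    p = X.shape[1]
    if isinstance(model, SurvivalForestModel):
        def tree_error(b: int, Xo, yo, eo) -> float:
            return 1.0 - harrell_concordance(yo, eo, _rsf_tree_risk(model, b, Xo))
    elif isinstance(model, RfModel):
        def tree_error(b: int, Xo, yo, eo) -> float:
            pred = model.leaf_values[b][route(model.trees[b], Xo)]
            return float(np.mean((pred - yo) ** 2))
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")

    raw = np.zeros(p)
    n_trees_used = 0
    for b in range(len(model.trees)):
        oob = model.oob_indices[b]
        if len(oob) < 2:
            continue
        Xo = X[oob].copy()
        yo = y[oob]
        eo = e[oob]
        try:
            base = tree_error(b, Xo, yo, eo)
        except ValueError:  # no comparable pairs in this OOB set
            continue
        for j in range(p):
            perm = rng.permutation(len(oob))
            col = Xo[:, j].copy()
            Xo[:, j] = col[perm]
            try:
                raw[j] += tree_error(b, Xo, yo, eo) - base
            finally:
                Xo[:, j] = col
        n_trees_used += 1
    if n_trees_used == 0:
        raise ValueError("no tree had a usable out-of-bag set")
    raw /= n_trees_used
    clipped = np.clip(raw, 0.0, None)
    total = clipped.sum()
    normalized = clipped / total if total > 0 else np.full(p, 1.0 / p)
    return pd.DataFrame(
        {"feature": dataset.feature_names, "raw": raw, "normalized": normalized}
    )
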