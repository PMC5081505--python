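"""Random Survival Forest: splits, terminal hazards, ensembles, OOB error."""

import numpy as np
import pytest

import icuforecast as icf
from icuforecast import (
    RsfParams,
    StepFunction,
    ensemble_chf,
    fit_rsf,
    nelson_aalen,
    oob_concordance_error,
    survival_function,
)
from icuforecast._tree import (
    BinnedFeatures,
    Tree,
    best_logrank_split,
    route,
)
from icuforecast.survival_forest import SurvivalForestModel
from conftest import random_survival_sample
from tests_helpers_forest import single_leaf_survival_model as _single_leaf_model


def test_unsplit_tree_reproduces_cohort_nelson_aalen():
    rng = np.random.default_rng(0)
    times, events = random_survival_sample(rng, 25)
    X = rng.integers(0, 5, size=(25, 3)).astype(float)
    model = fit_rsf(
        (X, times, events),
        RsfParams(n_trees=1, max_depth=0, bootstrap=False),
    )
    chf = ensemble_chf(model, X[0])
    expected = nelson_aalen(times, events)
    np.testing.assert_allclose(chf.x, expected.x)
    np.testing.assert_allclose(chf.y, expected.y)


def test_separated_strata_split_on_informative_predictor():
    """Two survival strata perfectly coded by predictor 0 dominate the root."""
    rng = np.random.default_rng(1)
    n = 200
    group = rng.random(n) < 0.5
    X = np.column_stack(
        [group.astype(float), rng.integers(0, 5, n).astype(float)]
    )
    # each stratum needs > d0 = 3 distinct event times or the split is barred
    times = np.where(group, rng.integers(1, 6, n), rng.integers(8, 14, n))
    events = np.ones(n, bool)
    model = fit_rsf(
        (X, times.astype(float), events),
        RsfParams(n_trees=25, mtry=2, seed=3, min_node_size=5),
    )
    roots = [t.feature[0] for t in model.trees]
    assert np.mean(np.asarray(roots) == 0) >= 0.9


def test_same_seed_identical_forests(small_dataset):
    params = RsfParams(n_trees=5, seed=77)
    a = fit_rsf(small_dataset, params)
    b = fit_rsf(small_dataset, params)
    assert a.to_dict() == b.to_dict()


def test_row_permutation_invariance():
    """With deterministic tie-breaks and no bootstrap, row order is irrelevant."""
    rng = np.random.default_rng(5)
    times, events = random_survival_sample(rng, 60)
    X = rng.integers(0, 5, size=(60, 4)).astype(float)
    params = RsfParams(n_trees=1, mtry=4, bootstrap=False, min_node_size=2,
                       min_unique_deaths=1, seed=0)
    a = fit_rsf((X, times, events), params)
    perm = rng.permutation(60)
    b = fit_rsf((X[perm], times[perm], events[perm]), params)
    assert a.trees[0].to_dict() == b.trees[0].to_dict()
    for fa, fb in zip(a.leaf_chfs[0], b.leaf_chfs[0]):
        np.testing.assert_allclose(fa.x, fb.x)
        np.testing.assert_allclose(fa.y, fb.y)


def test_noise_predictors_do_not_displace_signal():
    rng = np.random.default_rng(8)
    n = 300
    signal = rng.integers(0, 5, n).astype(float)
    X = np.column_stack([signal] + [rng.integers(0, 5, n) for _ in range(5)])
    times = np.clip(1 + signal * 2 + rng.integers(0, 2, n), 1, 13)
    events = np.ones(n, bool)
    model = fit_rsf(
        (X.astype(float), times.astype(float), events),
        RsfParams(n_trees=40, mtry=3, seed=2, min_node_size=10),
    )
    roots = np.asarray([t.feature[0] for t in model.trees])
    counts = np.bincount(roots[roots >= 0], minlength=6)
    assert counts[0] == counts.max()


def test_ensemble_chf_is_average_of_two_trees():
    n1 = StepFunction([1.0, 3.0], [0.2, 0.7])
    n2 = StepFunction([2.0, 3.0, 5.0], [0.1, 0.4, 1.1])
    model = _single_leaf_model([n1, n2])
    chf = ensemble_chf(model, [0.0])
    grid = np.array([0.5, 1, 2, 3, 4, 5, 9])
    np.testing.assert_allclose(chf(grid), (n1(grid) + n2(grid)) / 2)


def test_ensemble_chf_single_tree_identity():
    n1 = StepFunction([1.0, 4.0], [0.3, 0.9])
    model = _single_leaf_model([n1])
    chf = ensemble_chf(model, [0.0])
    np.testing.assert_allclose(chf.x, n1.x)
    np.testing.assert_allclose(chf.y, n1.y)


def test_ensemble_chf_nondecreasing(small_dataset):
    model = fit_rsf(small_dataset, RsfParams(n_trees=10, seed=1))
    for i in range(0, len(small_dataset), 37):
        chf = ensemble_chf(model, small_dataset.X[i])
        assert chf.is_nondecreasing


def test_survival_function_closed_forms():
    assert survival_function(StepFunction(np.empty(0), np.empty(0)))(5) == 1.0
    s = survival_function(StepFunction([2.0], [1.0]))
    assert s(2) == pytest.approx(np.exp(-1))
    assert s(0) == 1.0
    chf = nelson_aalen([1, 2, 2, 4], [True] * 4)
    assert survival_function(chf)(4) == pytest.approx(np.exp(-(0.25 + 2 / 3 + 1)))


def test_survival_function_rejects_invalid_chf():
    with pytest.raises(ValueError):
        survival_function(StepFunction([1.0, 2.0], [1.0, 0.5]))


def test_survival_curves_bounded_and_start_at_one(small_dataset):
    model = fit_rsf(small_dataset, RsfParams(n_trees=15, seed=4))
    S = model.predict_survival_matrix(small_dataset.X[:50], np.arange(11.0))
    assert np.all(S > 0) and np.all(S <= 1)
    assert np.allclose(S[:, 0], 1.0)  # no exits before the first morning
    assert np.all(np.diff(S, axis=1) <= 1e-12)


def test_oob_concordance_error_extremes():
    rng = np.random.default_rng(2)
    n = 80
    x = rng.permutation(n).astype(float)
    X = x.reshape(-1, 1)
    times = x + 1.0  # higher x, longer stay; uncensored
    events = np.ones(n, bool)
    model = fit_rsf(
        (X, times, events),
        RsfParams(n_trees=60, mtry=1, seed=6, min_node_size=5,
                  min_unique_deaths=1),
    )
    err = oob_concordance_error(model, (X, times, events))
    assert err < 0.1  # near-perfect ranking is learnable here


def test_oob_concordance_error_requires_oob_cases(small_dataset):
    model = fit_rsf(small_dataset, RsfParams(n_trees=1, bootstrap=False))
    with pytest.raises(ValueError, match="out of bag"):
        oob_concordance_error(model, small_dataset)


def test_fit_rejects_too_few_event_times():
    X = np.zeros((10, 1))
    times = np.full(10, 3.0)
    events = np.ones(10, bool)  # a single unique event time
    with pytest.raises(ValueError, match="unique event times"):
        fit_rsf((X, times, events), RsfParams(n_trees=1, min_unique_deaths=3))


def test_split_scan_agrees_with_bruteforce_logrank():
    """The fused node scan must pick the same cut as explicit enumeration."""
    rng = np.random.default_rng(12)
    for _ in range(30):
        n = int(rng.integers(12, 80))
        p = int(rng.integers(1, 5))
        X = rng.integers(0, 5, size=(n, p)).astype(float)
        times, events = random_survival_sample(rng, n)
        binned = BinnedFeatures(X)
        all_times = np.unique(times)
        t_idx = np.searchsorted(all_times, times)
        feats = np.arange(p)
        got = best_logrank_split(
            binned, t_idx, events, np.arange(n), feats, len(all_times), 1
        )
        # brute force over every feature and midpoint cut
        best = None
        for f in range(p):
            for cut in np.unique(X[:, f])[:-1]:
                uv = np.unique(X[:, f])
                thr = (cut + uv[uv > cut].min()) / 2
                left = X[:, f] <= thr
                d_left = len(np.unique(times[events & left]))
                d_right = len(np.unique(times[events & ~left]))
                if d_left <= 1 or d_right <= 1:
                    continue
                try:
                    s = abs(icf.log_rank_statistic(times, events, left))
                except ValueError:
                    continue
                if best is None or s > best[2] + 1e-12:
                    best = (f, thr, s)
        if best is None:
            assert got is None
        else:
            assert got is not None
            assert got[0] == best[0]
            assert got[1] == pytest.approx(best[1])
            assert got[2] == pytest.approx(best[2], rel=1e-9)


def test_numba_and_numpy_split_paths_agree():
    rng = np.random.default_rng(21)
    for _ in range(40):
        n = int(rng.integers(10, 100))
        p = int(rng.integers(2, 6))
        X = rng.integers(0, 6, size=(n, p)).astype(float)
        times, events = random_survival_sample(rng, n)
        binned = BinnedFeatures(X)
        all_times = np.unique(times)
        t_idx = np.searchsorted(all_times, times)
        feats = np.arange(p)
        args = (binned, t_idx, events, np.arange(n), feats, len(all_times), 1, 3)
        fast = best_logrank_split(*args)
        slow = best_logrank_split(*args, force_numpy=True)
        if fast is None or slow is None:
            assert fast is None and slow is None
        else:
            assert fast[0] == slow[0]
            assert fast[1] == pytest.approx(slow[1])
            assert fast[2] == pytest.approx(slow[2], rel=1e-9)


def test_json_roundtrip_preserves_predictions(small_dataset, tmp_path):
    model = fit_rsf(small_dataset, RsfParams(n_trees=5, seed=9))
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = SurvivalForestModel.from_json(path)
    grid = np.arange(11.0)
    np.testing.assert_allclose(
        model.predict_chf_matrix(small_dataset.X[:20], grid),
        loaded.predict_chf_matrix(small_dataset.X[:20], grid),
    )


def test_route_partitions_all_cases(small_dataset):
    model = fit_rsf(small_dataset, RsfParams(n_trees=3, seed=2))
    for tree, chfs in zip(model.trees, model.leaf_chfs):
        leaves = route(tree, small_dataset.X)
        assert leaves.min() >= 0
        assert leaves.max() < len(chfs)
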