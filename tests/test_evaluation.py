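"""Error measure E, cross-validation design, and permutation importance."""

import numpy as np
import pytest

import icuforecast as icf
from icuforecast import (
    EvalConfig,
    OracleMethod,
    RfParams,
    RsfParams,
    SamplingBaselineMethod,
    cross_validate,
    error_measure_E,
    fit_rf,
    fit_rsf,
    permutation_importance,
    simulate_signal_dataset,
)
from icuforecast.dataset import SupervisedDataset


class _ConstantFullHouse:
    """Stub method predicting every bed occupied on every day."""

    per_round = False
    uses_truth = False
    name = "constant"

    def fit(self, dataset):
        pass

    def entry_curves(self, X, horizon, rng=None):
        return np.ones((len(X), horizon + 1))


def _flat_dataset(remaining, event=None, patients=None):
    n = len(remaining)
    return SupervisedDataset.from_arrays(
        X=np.zeros((n, 19)),
        remaining_los=np.asarray(remaining),
        event=np.ones(n, bool) if event is None else np.asarray(event),
        patient_id=np.array(
            [f"q{i}" for i in range(n)] if patients is None else patients
        ),
    )


def test_oracle_attains_zero_error(small_dataset):
    cfg = EvalConfig(seed=1, repetitions=20)
    assert error_measure_E(OracleMethod(), small_dataset, small_dataset, cfg) == 0.0


def test_constant_full_house_mae_is_250_over_11():
    """25 beds predicted always-occupied vs everyone leaving after day 0."""
    test = _flat_dataset(np.ones(25, int))
    cfg = EvalConfig(seed=0, group_size=25, repetitions=5, horizon=10)
    e = error_measure_E(_ConstantFullHouse(), test, test, cfg)
    assert e == pytest.approx(250 / 11)


def test_error_measure_deterministic(small_dataset):
    cfg = EvalConfig(seed=5, repetitions=10)
    a = error_measure_E(SamplingBaselineMethod(), small_dataset, small_dataset, cfg)
    b = error_measure_E(SamplingBaselineMethod(), small_dataset, small_dataset, cfg)
    assert a == b


def test_error_measure_invariant_to_entry_order(small_dataset):
    cfg = EvalConfig(seed=2, repetitions=10)
    perm = np.random.default_rng(0).permutation(len(small_dataset))
    shuffled = small_dataset.subset(perm)
    a = error_measure_E(SamplingBaselineMethod(), small_dataset, small_dataset, cfg)
    b = error_measure_E(SamplingBaselineMethod(), small_dataset, shuffled, cfg)
    assert a == b


def test_error_measure_rejects_small_fold():
    cfg = EvalConfig(group_size=25)
    tiny = _flat_dataset(np.ones(10, int))
    with pytest.raises(ValueError, match="smaller than"):
        error_measure_E(OracleMethod(), tiny, tiny, cfg)


def test_cross_validate_fold_structure(small_dataset):
    cfg = EvalConfig(seed=3, k_folds=5, group_size=10, repetitions=5)
    report = cross_validate(
        small_dataset, {"baseline": SamplingBaselineMethod}, cfg
    )
    assert len(report.e_values["baseline"]) == 5
    assert all(v >= 0 for v in report.e_values["baseline"])
    assert sum(report.fold_sizes) == len(small_dataset)


def test_cross_validate_keeps_patients_within_one_fold(small_dataset):
    from icuforecast.evaluation import _fold_assignment

    cfg = EvalConfig(seed=3, k_folds=5, group_size=10)
    folds = _fold_assignment(small_dataset, cfg)
    for pid in np.unique(small_dataset.patient_id):
        assert len(np.unique(folds[small_dataset.patient_id == pid])) == 1


def test_identical_methods_not_significant(small_dataset):
    cfg = EvalConfig(seed=4, k_folds=5, group_size=10, repetitions=10)
    report = cross_validate(
        small_dataset,
        {"a": SamplingBaselineMethod, "b": SamplingBaselineMethod},
        cfg,
    )
    # same sampling distribution per fold: the rank-sum test must not reject
    assert report.pairwise_p["a_vs_b"] > 0.05


def test_cross_validate_rejects_infeasible_group_size(small_dataset):
    cfg = EvalConfig(seed=1, k_folds=10, group_size=10_000)
    with pytest.raises(ValueError, match="smaller than"):
        cross_validate(small_dataset, {"o": OracleMethod}, cfg)


def test_importance_normalized_and_signal_on_top(signal_dataset):
    model = fit_rsf(
        signal_dataset, RsfParams(n_trees=40, seed=2, min_node_size=20)
    )
    table = permutation_importance(
        model, signal_dataset, np.random.default_rng(0)
    )
    assert table["normalized"].sum() == pytest.approx(1.0)
    assert (table["normalized"] >= 0).all()
    top2 = set(table.nlargest(2, "normalized")["feature"])
    assert top2 == {"sofa_resp_d3", "sofa_cns_d3"}


def test_importance_noise_features_near_zero(signal_dataset):
    model = fit_rsf(
        signal_dataset, RsfParams(n_trees=40, seed=2, min_node_size=20)
    )
    table = permutation_importance(
        model, signal_dataset, np.random.default_rng(0)
    ).set_index("feature")
    noise = [f"sofa_coag_d{k}" for k in (1, 2, 3)]
    assert np.abs(table.loc[noise, "raw"]).max() < 0.01


def test_importance_works_for_regression_forest(signal_dataset):
    model = fit_rf(signal_dataset, RfParams(n_trees=30, seed=1))
    table = permutation_importance(
        model, signal_dataset, np.random.default_rng(1)
    )
    assert table["normalized"].sum() == pytest.approx(1.0)
    top2 = set(table.nlargest(2, "normalized")["feature"])
    assert top2 == {"sofa_resp_d3", "sofa_cns_d3"}


def test_report_serialization(small_dataset):
    cfg = EvalConfig(seed=6, k_folds=4, group_size=10, repetitions=5)
    report = cross_validate(
        small_dataset, {"baseline": SamplingBaselineMethod}, cfg
    )
    d = report.to_dict()
    assert set(d["e_values"]) == {"baseline"}
    assert d["config"]["k_folds"] == 4
    assert d["median_E"]["baseline"] == pytest.approx(report.median("baseline"))
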