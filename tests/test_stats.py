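"""Survival primitives against hand computation and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import NelsonAalenFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index

from icuforecast import (
    StepFunction,
    harrell_concordance,
    log_rank_statistic,
    nelson_aalen,
)


def test_nelson_aalen_hand_example():
    """times (1,2,2,4), all events: increments 1/4, 2/3, 1/1."""
    chf = nelson_aalen([1, 2, 2, 4], [True] * 4)
    assert chf(1) == pytest.approx(0.25)
    assert chf(2) == pytest.approx(0.25 + 2 / 3)
    assert chf(4) == pytest.approx(0.25 + 2 / 3 + 1.0)
    assert chf(0.5) == 0.0


def test_nelson_aalen_all_censored_is_zero():
    chf = nelson_aalen([3, 5, 7], [False, False, False])
    assert chf(10) == 0.0 and len(chf.x) == 0


def test_nelson_aalen_single_event():
    chf = nelson_aalen([3], [True])
    assert chf(3) == pytest.approx(1.0)


def test_nelson_aalen_censored_leave_risk_set():
    # censored at 2 is still at risk for the event at 2, gone by 3
    chf = nelson_aalen([2, 2, 3], [True, False, True])
    assert chf(2) == pytest.approx(1 / 3)
    assert chf(3) == pytest.approx(1 / 3 + 1.0)


@pytest.mark.parametrize("seed", range(10))
def test_nelson_aalen_matches_lifelines(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 40))
    times = rng.integers(1, 15, size=n).astype(float)
    events = rng.random(n) < 0.7
    chf = nelson_aalen(times, events)
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(times, event_observed=events)
    grid = np.unique(times)
    expected = naf.cumulative_hazard_at_times(grid).values
    np.testing.assert_allclose(chf(grid), expected, atol=1e-10)


def test_nelson_aalen_empty_rejected():
    with pytest.raises(ValueError):
        nelson_aalen([], [])


def test_logrank_identical_groups_zero():
    times = [1, 3, 4, 6, 6]
    events = [True, True, False, True, True]
    stat = log_rank_statistic(times * 2, events * 2, [True] * 5 + [False] * 5)
    assert stat == pytest.approx(0.0, abs=1e-12)


def test_logrank_separated_groups_large():
    times = [1] * 5 + [10] * 5
    events = [True] * 10
    left = [True] * 5 + [False] * 5
    assert abs(log_rank_statistic(times, events, left)) > 2


def test_logrank_antisymmetric():
    rng = np.random.default_rng(3)
    times = rng.integers(1, 10, 30).astype(float)
    events = rng.random(30) < 0.8
    left = rng.random(30) < 0.5
    if not left.any() or left.all():
        left[0] = ~left[0]
    a = log_rank_statistic(times, events, left)
    b = log_rank_statistic(times, events, ~left)
    assert a == pytest.approx(-b)


@pytest.mark.parametrize("seed", range(8))
def test_logrank_squared_matches_lifelines_chi2(seed):
    rng = np.random.default_rng(100 + seed)
    n = 40
    times = rng.integers(1, 12, n).astype(float)
    events = rng.random(n) < 0.75
    left = rng.random(n) < 0.5
    events[0] = True  # guarantee the statistic is defined
    left[0], left[1] = True, False
    stat = log_rank_statistic(times, events, left)
    res = logrank_test(
        times[left], times[~left], events[left], events[~left]
    )
    assert stat**2 == pytest.approx(res.test_statistic, rel=1e-8)


def test_logrank_requires_two_groups_and_events():
    with pytest.raises(ValueError):
        log_rank_statistic([1, 2], [True, True], [True, True])
    with pytest.raises(ValueError):
        log_rank_statistic([1, 2], [False, False], [True, False])


def test_concordance_perfect_and_reversed():
    times = np.array([1, 2, 3, 4, 5.0])
    events = np.ones(5, bool)
    risk = -times  # earlier exit = higher risk: perfect
    assert harrell_concordance(times, events, risk) == 1.0
    assert harrell_concordance(times, events, times) == 0.0


@pytest.mark.parametrize("seed", range(5))
def test_concordance_matches_lifelines(seed):
    rng = np.random.default_rng(seed)
    n = 60
    times = rng.exponential(5, n) + 0.01  # continuous: no ties in time
    events = rng.random(n) < 0.7
    risk = rng.normal(size=n)
    ours = harrell_concordance(times, events, risk)
    theirs = concordance_index(times, -risk, events)
    assert ours == pytest.approx(theirs, abs=1e-12)


def test_stepfunction_evaluation_rules():
    f = StepFunction([2.0, 5.0], [1.5, 3.0])
    np.testing.assert_allclose(f([0, 2, 3, 5, 9]), [0, 1.5, 1.5, 3, 3])
    g = StepFunction([2.0], [0.5], baseline=1.0)
    assert g(0) == 1.0 and g(2) == 0.5


def test_stepfunction_rejects_unsorted_knots():
    with pytest.raises(ValueError):
        StepFunction([3.0, 1.0], [1.0, 2.0])


@settings(derandomize=True, max_examples=100)
@given(
    st.lists(st.integers(1, 15), min_size=1, max_size=25),
    st.data(),
)
def test_nelson_aalen_nondecreasing_property(times, data):
    events = data.draw(
        st.lists(st.booleans(), min_size=len(times), max_size=len(times))
    )
    chf = nelson_aalen(np.array(times, float), np.array(events))
    assert chf.is_nondecreasing
    assert np.all(chf.y >= 0)
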