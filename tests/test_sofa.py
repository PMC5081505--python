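"""SOFA subscore branches, imputation, and monotonicity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from icuforecast import (
    DailyPhysiology,
    cardiovascular_subscore,
    cns_subscore,
    coagulation_subscore,
    liver_subscore,
    renal_subscore,
    respiratory_subscore,
    score_day,
)


@pytest.mark.parametrize(
    "value,expected",
    [(15, 4), (20, 4), (21, 3), (50, 3), (51, 2), (100, 2), (101, 1),
     (150, 1), (151, 0), (None, 0), (float("nan"), 0)],
)
def test_coagulation_branches(value, expected):
    assert coagulation_subscore(value) == expected


@pytest.mark.parametrize(
    "creat,urine,expected",
    [
        (5.0, 2000, 4),   # creatinine alone triggers the worst branch
        (1.0, 150, 4),    # anuria alone triggers it too
        (3.5, 1500, 3),
        (1.0, 450, 3),
        (2.5, 1500, 2),
        (1.5, 2000, 1),
        (0.8, 2000, 0),
        (None, None, 0),
        (None, 100, 4),   # absent creatinine never blocks the urine rule
        (2.0, None, 2),
    ],
)
def test_renal_branches(creat, urine, expected):
    assert renal_subscore(creat, urine) == expected


@pytest.mark.parametrize(
    "value,expected",
    [(13, 4), (12, 4), (6.5, 3), (2.0, 2), (1.2, 1), (0.8, 0), (None, 0)],
)
def test_liver_branches(value, expected):
    assert liver_subscore(value) == expected


@pytest.mark.parametrize(
    "value,expected",
    [(15, 0), (14, 1), (12, 2), (10, 2), (8, 3), (7, 3), (6, 4), (3, 4),
     (None, 0)],
)
def test_cns_branches(value, expected):
    assert cns_subscore(value) == expected


@pytest.mark.parametrize(
    "pf,vent,expected",
    [
        (150, True, 3),
        (150, False, 2),   # low PF without ventilation falls through to <=300
        (90, True, 4),
        (90, False, 2),
        (250, False, 2),
        (350, True, 1),
        (450, True, 0),
        (None, True, 0),
    ],
)
def test_respiratory_branches(pf, vent, expected):
    assert respiratory_subscore(pf, vent) == expected


@pytest.mark.parametrize(
    "kwargs,expected",
    [
        (dict(map_mean=80, dopamine_max=20), 4),
        (dict(map_mean=80, epinephrine_max=0.2), 4),
        (dict(map_mean=80, norepinephrine_max=0.11), 4),
        (dict(map_mean=80, dopamine_max=10), 3),
        (dict(map_mean=80, epinephrine_max=0.05), 3),
        (dict(map_mean=80, norepinephrine_max=0.1), 3),
        (dict(map_mean=80, dopamine_max=5), 2),
        (dict(map_mean=80, dobutamine_max=5), 2),
        (dict(map_mean=65), 1),
        (dict(map_mean=80), 0),
        (dict(map_mean=None), 0),
    ],
)
def test_cardiovascular_branches(kwargs, expected):
    assert cardiovascular_subscore(**kwargs) == expected


@pytest.mark.parametrize(
    "fn,args",
    [
        (coagulation_subscore, (-1,)),
        (renal_subscore, (-0.5, 100)),
        (liver_subscore, (-2,)),
        (cns_subscore, (2,)),
        (cns_subscore, (16,)),
        (respiratory_subscore, (0, True)),
        (cardiovascular_subscore, (80, -1, 0, 0, 0)),
    ],
)
def test_invalid_inputs_raise(fn, args):
    with pytest.raises(ValueError):
        fn(*args)


def test_score_day_all_absent_is_zero():
    row = DailyPhysiology(patient_id="p", day=1)
    sofa = score_day(row)
    assert sofa.as_tuple() == (0, 0, 0, 0, 0, 0)
    assert sofa.total == 0


def test_score_day_worst_case_totals_24():
    row = DailyPhysiology(
        patient_id="p", day=1, thrombocytes_min=10, creatinine_max=6,
        urine_sum=100, bilirubin_max=15, gcs_min=3, pf_ratio_min=50,
        ventilated=True, map_mean=40, dopamine_max=20,
    )
    assert score_day(row).total == 24


def test_score_day_all_healthy_totals_0():
    row = DailyPhysiology(
        patient_id="p", day=1, thrombocytes_min=151, creatinine_max=0.8,
        urine_sum=2000, bilirubin_max=0.8, gcs_min=15, pf_ratio_min=450,
        ventilated=False, map_mean=80,
    )
    assert score_day(row).total == 0


# --- properties -----------------------------------------------------------

physio = st.fixed_dictionaries(
    {
        "thrombocytes_min": st.one_of(st.none(), st.floats(0, 1000)),
        "creatinine_max": st.one_of(st.none(), st.floats(0, 20)),
        "urine_sum": st.one_of(st.none(), st.floats(0, 6000)),
        "bilirubin_max": st.one_of(st.none(), st.floats(0, 50)),
        "gcs_min": st.one_of(st.none(), st.integers(3, 15)),
        "sedated": st.booleans(),
        "pf_ratio_min": st.one_of(st.none(), st.floats(1, 700)),
        "ventilated": st.booleans(),
        "map_mean": st.one_of(st.none(), st.floats(20, 150)),
        "dopamine_max": st.one_of(st.none(), st.floats(0, 30)),
        "dobutamine_max": st.one_of(st.none(), st.floats(0, 30)),
        "epinephrine_max": st.one_of(st.none(), st.floats(0, 1)),
        "norepinephrine_max": st.one_of(st.none(), st.floats(0, 1)),
    }
)


@settings(derandomize=True, max_examples=300)
@given(physio)
def test_subscores_in_range_and_total_consistent(values):
    sofa = score_day(DailyPhysiology(patient_id="p", day=1, **values))
    assert all(0 <= s <= 4 for s in sofa.as_tuple())
    assert sofa.total == sum(sofa.as_tuple())
    assert 0 <= sofa.total <= 24


@settings(derandomize=True, max_examples=200)
@given(st.floats(0, 1000), st.floats(0, 1000))
def test_coagulation_monotone_nonincreasing(a, b):
    lo, hi = sorted((a, b))
    assert coagulation_subscore(lo) >= coagulation_subscore(hi)


@settings(derandomize=True, max_examples=200)
@given(st.floats(0, 50), st.floats(0, 50))
def test_liver_monotone_nondecreasing(a, b):
    lo, hi = sorted((a, b))
    assert liver_subscore(lo) <= liver_subscore(hi)


@settings(derandomize=True, max_examples=200)
@given(st.floats(0, 20), st.floats(0, 20), st.floats(0, 6000))
def test_renal_monotone_in_creatinine(a, b, urine):
    lo, hi = sorted((a, b))
    assert renal_subscore(lo, urine) <= renal_subscore(hi, urine)


@settings(derandomize=True, max_examples=200)
@given(st.floats(1, 700), st.floats(1, 700), st.booleans())
def test_respiratory_monotone_in_pf(a, b, vent):
    lo, hi = sorted((a, b))
    assert respiratory_subscore(lo, vent) >= respiratory_subscore(hi, vent)
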