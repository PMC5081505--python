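"""Daily SOFA (Sequential Organ Failure Assessment) scoring.

The SOFA score condenses one day of clinical measurements into six organ-system
subscores — coagulation, renal, liver, central nervous system, respiratory and
cardiovascular — each an integer from 0 (normal function) to 4 (severe organ
failure). The total score is their sum, 0 to 24.

Each subscore is a piecewise-constant map of the day's worst measurement(s).
The printed clinical cut-point tables have overlapping conditions when read
literally, so every subscore here is evaluated *most severe first* (4 down to
0), the standard convention, which makes the branches exhaustive and mutually
exclusive.

A measurement that is absent (``None`` or NaN) contributes a subscore of 0:
in routine ICU practice an organ that is judged healthy is simply not
monitored, so a missing channel is read as "no failure".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import DailyPhysiology

__all__ = [
    "SofaDay",
    "coagulation_subscore",
    "renal_subscore",
    "liver_subscore",
    "cns_subscore",
    "respiratory_subscore",
    "cardiovascular_subscore",
    "score_day",
]


@dataclass(frozen=True)
class SofaDay:
    """The six SOFA subscores for one patient-day.

    Attributes
    ----------
    coag, renal, liver, cns, resp, cardio
        Integer subscores in {0, 1, 2, 3, 4}.
    """

    coag: int
    renal: int
    liver: int
    cns: int
    resp: int
    cardio: int

    @property
    def total(self) -> int:
        """Total SOFA score: the sum of the six subscores (0-24)."""
        return self.coag + self.renal + self.liver + self.cns + self.resp + self.cardio

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        """Subscores in canonical order (coag, renal, liver, cns, resp, cardio)."""
        return (self.coag, self.renal, self.liver, self.cns, self.resp, self.cardio)


def _absent(value: Optional[float]) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def coagulation_subscore(thrombocytes_min: Optional[float]) -> int:
    """Coagulation subscore from the day's minimum thrombocyte count (x10^3/uL).

    Cut points: <=20 -> 4, <=50 -> 3, <=100 -> 2, <=150 -> 1, >150 -> 0.
    """
    if _absent(thrombocytes_min):
        return 0
    if thrombocytes_min < 0:
        raise ValueError(f"thrombocyte count must be >= 0, got {thrombocytes_min}")
    if thrombocytes_min <= 20:
        return 4
    if thrombocytes_min <= 50:
        return 3
    if thrombocytes_min <= 100:
        return 2
    if thrombocytes_min <= 150:
        return 1
    return 0


def renal_subscore(creatinine_max: Optional[float], urine_sum: Optional[float]) -> int:
    """Renal subscore from maximum serum creatinine (mg/dL) and 24h urine (mL).

    Most severe first: 4 if creatinine >= 4.9 or urine < 200; 3 if
    creatinine >= 3.4 or urine < 500; 2 if creatinine >= 1.9; 1 if
    creatinine >= 1.2; else 0. An absent channel never triggers a branch.
    """
    for name, v in (("creatinine_max", creatinine_max), ("urine_sum", urine_sum)):
        if not _absent(v) and v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    c_ok = not _absent(creatinine_max)
    u_ok = not _absent(urine_sum)
    if (c_ok and creatinine_max >= 4.9) or (u_ok and urine_sum < 200):
        return 4
    if (c_ok and creatinine_max >= 3.4) or (u_ok and urine_sum < 500):
        return 3
    if c_ok and creatinine_max >= 1.9:
        return 2
    if c_ok and creatinine_max >= 1.2:
        return 1
    return 0


def liver_subscore(bilirubin_max: Optional[float]) -> int:
    """Liver subscore from the day's maximum serum bilirubin (mg/dL).

    Cut points: >=12 -> 4, >=6 -> 3, >=2 -> 2, >=1.2 -> 1, <1.2 -> 0.
    """
    if _absent(bilirubin_max):
        return 0
    if bilirubin_max < 0:
        raise ValueError(f"bilirubin must be >= 0, got {bilirubin_max}")
    if bilirubin_max >= 12:
        return 4
    if bilirubin_max >= 6:
        return 3
    if bilirubin_max >= 2:
        return 2
    if bilirubin_max >= 1.2:
        return 1
    return 0


def cns_subscore(gcs_min: Optional[float]) -> int:
    """Central-nervous-system subscore from the minimum Glasgow coma score.

    Cut points: <=6 -> 4, <=9 -> 3, <=12 -> 2, <=14 -> 1, >14 -> 0.

    For a sedated patient the convention is to score the last known
    pre-sedation GCS; the caller is expected to supply that value.
    """
    if _absent(gcs_min):
        return 0
    if not (3 <= gcs_min <= 15):
        raise ValueError(f"Glasgow coma score must be in [3, 15], got {gcs_min}")
    if gcs_min <= 6:
        return 4
    if gcs_min <= 9:
        return 3
    if gcs_min <= 12:
        return 2
    if gcs_min <= 14:
        return 1
    return 0


def respiratory_subscore(pf_ratio_min: Optional[float], ventilated: bool) -> int:
    """Respiratory subscore from the minimum PaO2/FiO2 ratio (mm Hg).

    Most severe first: 4 if PF <= 100 and ventilated; 3 if PF <= 200 and
    ventilated; 2 if PF <= 300; 1 if PF <= 400; else 0. A low PF ratio
    without mechanical ventilation falls through to the <=300 branch.
    """
    if _absent(pf_ratio_min):
        return 0
    if pf_ratio_min <= 0:
        raise ValueError(f"PF ratio must be > 0, got {pf_ratio_min}")
    if pf_ratio_min <= 100 and ventilated:
        return 4
    if pf_ratio_min <= 200 and ventilated:
        return 3
    if pf_ratio_min <= 300:
        return 2
    if pf_ratio_min <= 400:
        return 1
    return 0


def cardiovascular_subscore(
    map_mean: Optional[float],
    dopamine_max: Optional[float] = None,
    dobutamine_max: Optional[float] = None,
    epinephrine_max: Optional[float] = None,
    norepinephrine_max: Optional[float] = None,
) -> int:
    """Cardiovascular subscore from mean arterial pressure and vasopressor doses.

    Drug doses in ug/kg/min, MAP in mm Hg.  Most severe first:

    * 4 if dopamine > 15 or epinephrine > 0.1 or norepinephrine > 0.1
    * 3 if dopamine in (5, 15] or epinephrine in (0, 0.1] or
      norepinephrine in (0, 0.1]
    * 2 if dopamine in (0, 5] or dobutamine > 0
    * 1 if MAP < 70
    * 0 otherwise

    Drug intervals are half-open (a, b]; an absent channel never triggers.
    """
    doses = {
        "dopamine_max": dopamine_max,
        "dobutamine_max": dobutamine_max,
        "epinephrine_max": epinephrine_max,
        "norepinephrine_max": norepinephrine_max,
    }
    for name, v in doses.items():
        if not _absent(v) and v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    dop = 0.0 if _absent(dopamine_max) else dopamine_max
    dobu = 0.0 if _absent(dobutamine_max) else dobutamine_max
    epi = 0.0 if _absent(epinephrine_max) else epinephrine_max
    nor = 0.0 if _absent(norepinephrine_max) else norepinephrine_max
    if dop > 15 or epi > 0.1 or nor > 0.1:
        return 4
    if dop > 5 or epi > 0 or nor > 0:
        return 3
    if dop > 0 or dobu > 0:
        return 2
    if not _absent(map_mean) and map_mean < 70:
        return 1
    return 0


def score_day(row: "DailyPhysiology") -> SofaDay:
    """Score one patient-day of raw physiology into a :class:`SofaDay`.

    For sedated patients ``row.gcs_min`` is taken to already hold the last
    pre-sedation Glasgow coma score, so the CNS subscore uses it directly.
    """
    return SofaDay(
        coag=coagulation_subscore(row.thrombocytes_min),
        renal=renal_subscore(row.creatinine_max, row.urine_sum),
        liver=liver_subscore(row.bilirubin_max),
        cns=cns_subscore(row.gcs_min),
        resp=respiratory_subscore(row.pf_ratio_min, bool(row.ventilated)),
        cardio=cardiovascular_subscore(
            row.map_mean,
            row.dopamine_max,
            row.dobutamine_max,
            row.epinephrine_max,
            row.norepinephrine_max,
        ),
    )
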