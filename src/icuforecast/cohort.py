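"""Core containers for ICU stays: daily raw physiology and whole stays.

An ICU stay is represented as an ordered sequence of :class:`DailyPhysiology`
rows (days 1..los) plus how the stay ended: ``discharge`` (the event of
interest for remaining-length-of-stay modelling) or in-ICU ``death`` (treated
downstream as right censoring of discharge). The patient physically occupies a
bed on days 1..los and leaves on the morning of day los+1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np

__all__ = ["ExitType", "DailyPhysiology", "PatientStay", "cohort_summary"]


class ExitType(str, enum.Enum):
    DISCHARGE = "discharge"
    DEATH = "death"


#: Measurement channels, in the canonical CSV column order.
PHYSIOLOGY_CHANNELS = (
    "thrombocytes_min",
    "creatinine_max",
    "urine_sum",
    "bilirubin_max",
    "gcs_min",
    "sedated",
    "pf_ratio_min",
    "ventilated",
    "map_mean",
    "dopamine_max",
    "dobutamine_max",
    "epinephrine_max",
    "norepinephrine_max",
)


@dataclass
class DailyPhysiology:
    """One day of raw measurements for one patient.

    Any channel may be ``None`` ("not monitored"); at scoring time an absent
    channel maps to a subscore of 0. Units: thrombocytes x10^3/uL, creatinine
    and bilirubin mg/dL, urine mL/24h, PF ratio and MAP mm Hg, drug doses
    ug/kg/min. ``gcs_min`` holds the last pre-sedation value when ``sedated``.
    """

    patient_id: str
    day: int
    thrombocytes_min: Optional[float] = None
    creatinine_max: Optional[float] = None
    urine_sum: Optional[float] = None
    bilirubin_max: Optional[float] = None
    gcs_min: Optional[int] = None
    sedated: bool = False
    pf_ratio_min: Optional[float] = None
    ventilated: bool = False
    map_mean: Optional[float] = None
    dopamine_max: Optional[float] = None
    dobutamine_max: Optional[float] = None
    epinephrine_max: Optional[float] = None
    norepinephrine_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError(f"day must be >= 1, got {self.day}")


@dataclass
class PatientStay:
    """One ICU stay: consecutive daily physiology rows plus the exit label."""

    patient_id: str
    physiology: list[DailyPhysiology] = field(default_factory=list)
    exit_type: ExitType = ExitType.DISCHARGE

    def __post_init__(self) -> None:
        self.exit_type = ExitType(self.exit_type)
        days = [row.day for row in self.physiology]
        if days != list(range(1, len(days) + 1)):
            raise ValueError(
                f"stay {self.patient_id}: physiology days must be consecutive "
                f"from 1, got {days}"
            )
        for row in self.physiology:
            if row.patient_id != self.patient_id:
                raise ValueError(
                    f"stay {self.patient_id}: row with foreign patient_id "
                    f"{row.patient_id!r}"
                )

    @property
    def los(self) -> int:
        """Length of stay in days (number of physiology days)."""
        return len(self.physiology)


def cohort_summary(stays: Sequence[PatientStay]) -> dict:
    """Summarise a cohort: exit-type counts, LOS quantiles, fraction in [3, 16].

    Returns a plain dict so it serialises directly to JSON/YAML.
    """
    if not stays:
        raise ValueError("cohort_summary requires a non-empty cohort")
    los = np.array([s.los for s in stays], dtype=float)
    n = len(stays)
    n_death = sum(1 for s in stays if s.exit_type is ExitType.DEATH)
    q = np.quantile(los, [0.0, 0.25, 0.5, 0.75, 1.0])
    return {
        "n_patients": n,
        "n_discharge": n - n_death,
        "n_death": n_death,
        "death_fraction": n_death / n,
        "los_min": float(q[0]),
        "los_q25": float(q[1]),
        "los_median": float(q[2]),
        "los_q75": float(q[3]),
        "los_max": float(q[4]),
        "fraction_los_3_to_16": float(np.mean((los >= 3) & (los <= 16))),
    }


def _physiology_field_names() -> list[str]:
    return [f.name for f in fields(DailyPhysiology)]
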