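"""Cohort filtering and sliding-window construction of the supervised dataset.

Stays shorter than 3 days are dropped (too little history for a 3-day
window and clinically easy to plan for), and stays over 16 days are dropped
(the province of prolonged-stay models). For each kept stay, one dataset
entry is created at the morning of day 4 and each following morning up to
and including the last occupied day: the entry at ``index_day`` carries the
six SOFA subscores of the previous three days (18 predictors) plus the
number of days already admitted (1 predictor, = index_day - 1), for 19
predictors in total. The target is the remaining length of stay measured in
whole days from the index morning to the exit morning (the patient leaves on
the morning of day los + 1, so remaining_los = los - index_day + 1 >= 1; an
entry with a zero-day remaining stay would be degenerate and is not
created). A stay of exactly 3 days passes the filter but yields no entries.

Discharge is the event of interest; an in-ICU death right-censors the
discharge time, so entries from stays ending in death carry ``event=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import ExitType, PatientStay
from .sofa import SofaDay

__all__ = [
    "FEATURE_NAMES",
    "DatasetEntry",
    "SupervisedDataset",
    "filter_cohort",
    "build_entries",
    "assemble_dataset",
]

_SYSTEMS = ("coag", "renal", "liver", "cns", "resp", "cardio")

#: Canonical predictor order: for each organ system, lags d1 (three days
#: before the index morning) through d3 (the most recent day), then the
#: days-admitted count. 19 names in total.
FEATURE_NAMES: list[str] = [
    f"sofa_{sys}_d{k}" for sys in _SYSTEMS for k in (1, 2, 3)
] + ["days_admitted"]

MIN_LOS = 3
MAX_LOS = 16


@dataclass(frozen=True)
class DatasetEntry:
    """One sliding-window row: 19 predictors, target and censoring flag."""

    patient_id: str
    index_day: int
    predictors: tuple[float, ...]
    remaining_los: int
    event: bool

    def __post_init__(self) -> None:
        if len(self.predictors) != len(FEATURE_NAMES):
            raise ValueError(
                f"expected {len(FEATURE_NAMES)} predictors, got {len(self.predictors)}"
            )
        if self.index_day < 4:
            raise ValueError("index_day must be >= 4 (needs a 3-day history)")
        if self.remaining_los < 0:
            raise ValueError("remaining_los must be >= 0")


@dataclass
class SupervisedDataset:
    """Column-major supervised dataset with provenance of the filtering step.

    ``X`` is (n, p) float, ``remaining_los`` (n,) int, ``event`` (n,) bool
    (True = discharge observed, False = right-censored by death).
    """

    X: np.ndarray
    remaining_los: np.ndarray
    event: np.ndarray
    patient_id: np.ndarray
    index_day: np.ndarray
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.remaining_los = np.asarray(self.remaining_los, dtype=int)
        self.event = np.asarray(self.event, dtype=bool)
        self.patient_id = np.asarray(self.patient_id)
        self.index_day = np.asarray(self.index_day, dtype=int)
        n, p = self.X.shape if self.X.ndim == 2 else (len(self.X), 0)
        if p != len(self.feature_names):
            raise ValueError(
                f"X has {p} columns but {len(self.feature_names)} feature names"
            )
        for name, arr in (
            ("remaining_los", self.remaining_los),
            ("event", self.event),
            ("patient_id", self.patient_id),
            ("index_day", self.index_day),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")

    def __len__(self) -> int:
        return len(self.X)

    @classmethod
    def from_arrays(
        cls,
        X,
        remaining_los,
        event,
        patient_id=None,
        index_day=None,
        feature_names: Optional[Sequence[str]] = None,
    ) -> "SupervisedDataset":
        """Assemble a dataset from plain arrays (generic feature count allowed)."""
        X = np.asarray(X, dtype=float)
        n = len(X)
        if patient_id is None:
            patient_id = np.array([f"x{i:06d}" for i in range(n)])
        if index_day is None:
            index_day = np.full(n, 4, dtype=int)
        if feature_names is None:
            p = X.shape[1]
            feature_names = (
                list(FEATURE_NAMES) if p == len(FEATURE_NAMES)
                else [f"f{j}" for j in range(p)]
            )
        return cls(
            X=X,
            remaining_los=remaining_los,
            event=event,
            patient_id=patient_id,
            index_day=index_day,
            feature_names=list(feature_names),
        )

    @classmethod
    def from_entries(
        cls, entries: Sequence[DatasetEntry], provenance: Optional[dict] = None
    ) -> "SupervisedDataset":
        X = np.array([e.predictors for e in entries], dtype=float).reshape(
            len(entries), len(FEATURE_NAMES)
        )
        return cls(
            X=X,
            remaining_los=np.array([e.remaining_los for e in entries], dtype=int),
            event=np.array([e.event for e in entries], dtype=bool),
            patient_id=np.array([e.patient_id for e in entries]),
            index_day=np.array([e.index_day for e in entries], dtype=int),
            provenance=provenance or {},
        )

    def subset(self, idx) -> "SupervisedDataset":
        """Row subset (indices or boolean mask); provenance is not propagated."""
        idx = np.asarray(idx)
        return SupervisedDataset(
            X=self.X[idx],
            remaining_los=self.remaining_los[idx],
            event=self.event[idx],
            patient_id=self.patient_id[idx],
            index_day=self.index_day[idx],
            feature_names=list(self.feature_names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "patient_id", self.patient_id)
        df.insert(1, "index_day", self.index_day)
        df["remaining_los"] = self.remaining_los
        df["event"] = self.event
        return df


def filter_cohort(
    stays: Sequence[PatientStay],
) -> tuple[list[PatientStay], dict[str, int]]:
    """Keep stays with 3 <= LOS <= 16; log how many each rule removed."""
    kept: list[PatientStay] = []
    log = {"input": len(stays), "removed_los_lt_3": 0, "removed_los_gt_16": 0}
    for stay in stays:
        if stay.los < MIN_LOS:
            log["removed_los_lt_3"] += 1
        elif stay.los > MAX_LOS:
            log["removed_los_gt_16"] += 1
        else:
            kept.append(stay)
    log["kept"] = len(kept)
    return kept, log


def build_entries(
    stay: PatientStay, scored: Sequence[SofaDay]
) -> list[DatasetEntry]:
    """Sliding-window entries for one filtered, scored stay.

    One entry per index morning in {4, ..., los}; the entry at ``index_day``
    reads the subscores of days index_day-3 .. index_day-1 (lags d1..d3).
    """
    if not (MIN_LOS <= stay.los <= MAX_LOS):
        raise ValueError(
            f"stay {stay.patient_id} has LOS {stay.los}; filter the cohort first"
        )
    if len(scored) != stay.los:
        raise ValueError(
            f"stay {stay.patient_id}: {len(scored)} scored days for LOS {stay.los}"
        )
    event = stay.exit_type is ExitType.DISCHARGE
    entries = []
    for index_day in range(4, stay.los + 1):
        window = scored[index_day - 4 : index_day - 1]  # days index_day-3..-1
        predictors = tuple(
            float(getattr(day, sys)) for sys in _SYSTEMS for day in window
        ) + (float(index_day - 1),)
        entries.append(
            DatasetEntry(
                patient_id=stay.patient_id,
                index_day=index_day,
                predictors=predictors,
                remaining_los=stay.los - index_day + 1,
                event=event,
            )
        )
    return entries


def assemble_dataset(
    stays: Sequence[PatientStay],
    scored_days: dict[str, Sequence[SofaDay]],
    filter_log: Optional[dict] = None,
) -> SupervisedDataset:
    """Concatenate the sliding-window entries of all filtered, scored stays."""
    all_entries: list[DatasetEntry] = []
    seen: set[tuple[str, int]] = set()
    per_patient: dict[str, int] = {}
    for stay in stays:
        entries = build_entries(stay, scored_days[stay.patient_id])
        for e in entries:
            key = (e.patient_id, e.index_day)
            if key in seen:
                raise ValueError(f"duplicate entry for {key}")
            seen.add(key)
        all_entries.extend(entries)
        per_patient[stay.patient_id] = len(entries)
    provenance = {
        "filter": dict(filter_log) if filter_log else {},
        "n_entries": len(all_entries),
        "n_patients_with_entries": sum(1 for c in per_patient.values() if c > 0),
        "entries_per_patient": per_patient,
    }
    return SupervisedDataset.from_entries(all_entries, provenance=provenance)
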