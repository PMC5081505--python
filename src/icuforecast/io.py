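"""CSV readers/writers and provenance sidecars for the pipeline artifacts.

All tabular artifacts are plain CSV: one physiology row per patient-day
(empty cell = channel not monitored), a stays sidecar (patient_id, los,
exit_type), a SOFA table (one row per patient-day with the six subscores and
the total), and the supervised dataset (19 predictor columns in canonical
order plus target and censoring flag). Models and evaluation reports are
JSON. Readers validate schemas and report offending row numbers; writers can
drop a ``<path>.meta.json`` sidecar embedding a hash of the generating
configuration for provenance.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import DailyPhysiology, ExitType, PatientStay, PHYSIOLOGY_CHANNELS
from .dataset import FEATURE_NAMES, SupervisedDataset
from .sofa import SofaDay

__all__ = [
    "write_cohort_csv",
    "read_physiology_csv",
    "read_stays_csv",
    "read_cohort_csv",
    "write_sofa_csv",
    "read_sofa_csv",
    "write_dataset_csv",
    "read_dataset_csv",
    "write_meta_sidecar",
    "config_hash",
]

_PHYSIO_COLUMNS = ["patient_id", "day", *PHYSIOLOGY_CHANNELS]
_BOOL_CHANNELS = {"sedated", "ventilated"}
_NONNEG_CHANNELS = {
    "thrombocytes_min",
    "creatinine_max",
    "urine_sum",
    "bilirubin_max",
    "map_mean",
    "dopamine_max",
    "dobutamine_max",
    "epinephrine_max",
    "norepinephrine_max",
    "pf_ratio_min",
}
_SOFA_COLUMNS = ["patient_id", "day", "coag", "renal", "liver", "cns", "resp",
                 "cardio", "total"]
_DATASET_META = ["patient_id", "index_day"]
_DATASET_TAIL = ["remaining_los", "event"]


def config_hash(config) -> str:
    """Stable sha256 of a configuration (dataclass or plain mapping)."""
    payload = asdict(config) if is_dataclass(config) else dict(config)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_meta_sidecar(path, config) -> Path:
    """Write ``<path>.meta.json`` with the config and its hash."""
    payload = asdict(config) if is_dataclass(config) else dict(config)
    meta_path = Path(str(path) + ".meta.json")
    with open(meta_path, "w") as fh:
        json.dump({"config_hash": config_hash(config), "config": payload}, fh,
                  indent=2, default=str)
    return meta_path


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, (bool, np.bool_)):
        return "1" if value else "0"
    return repr(float(value)) if isinstance(value, float) else str(value)


def write_cohort_csv(
    stays: Sequence[PatientStay], physiology_path, stays_path, config=None
) -> None:
    """Write daily physiology rows and the stays sidecar for a cohort."""
    with open(physiology_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PHYSIO_COLUMNS)
        for stay in stays:
            for row in stay.physiology:
                writer.writerow(
                    [row.patient_id, row.day]
                    + [_fmt(getattr(row, ch)) for ch in PHYSIOLOGY_CHANNELS]
                )
    with open(stays_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "los", "exit_type"])
        for stay in stays:
            writer.writerow([stay.patient_id, stay.los, stay.exit_type.value])
    if config is not None:
        write_meta_sidecar(physiology_path, config)


class SchemaError(ValueError):
    """A CSV file violates the documented schema."""


def _read_rows(path, required_columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required_columns if c not in df.columns]
    extra = [c for c in df.columns if c not in required_columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if extra:
        raise SchemaError(f"{path}: unknown columns {extra}")
    return df


def _cell_float(raw: str, path, row_no: int, col: str) -> Optional[float]:
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise SchemaError(
            f"{path}: row {row_no}, column {col!r}: non-numeric value {raw!r}"
        ) from None


def read_physiology_csv(path) -> list[DailyPhysiology]:
    """Read daily physiology rows; empty cells become 'not monitored'."""
    df = _read_rows(path, _PHYSIO_COLUMNS)
    rows: list[DailyPhysiology] = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        rec = rec._asdict()
        values: dict = {}
        for ch in PHYSIOLOGY_CHANNELS:
            raw = rec[ch]
            if ch in _BOOL_CHANNELS:
                if raw in ("", "0"):
                    values[ch] = False
                elif raw == "1":
                    values[ch] = True
                else:
                    raise SchemaError(
                        f"{path}: row {i}, column {ch!r}: expected 0/1, got {raw!r}"
                    )
                continue
            v = _cell_float(raw, path, i, ch)
            if v is not None and ch in _NONNEG_CHANNELS and v < 0:
                raise SchemaError(
                    f"{path}: row {i}, column {ch!r}: negative value {v}"
                )
            if ch == "gcs_min" and v is not None:
                if not (3 <= v <= 15):
                    raise SchemaError(
                        f"{path}: row {i}, column 'gcs_min': out of [3, 15]: {v}"
                    )
                v = int(v)
            values[ch] = v
        day = _cell_float(rec["day"], path, i, "day")
        if day is None or day != int(day) or day < 1:
            raise SchemaError(f"{path}: row {i}: invalid day {rec['day']!r}")
        rows.append(
            DailyPhysiology(patient_id=rec["patient_id"], day=int(day), **values)
        )
    return rows


def read_stays_csv(path) -> list[tuple[str, int, ExitType]]:
    df = _read_rows(path, ["patient_id", "los", "exit_type"])
    out = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        los = _cell_float(rec.los, path, i, "los")
        if los is None or los != int(los) or los < 1:
            raise SchemaError(f"{path}: row {i}: invalid los {rec.los!r}")
        try:
            exit_type = ExitType(rec.exit_type)
        except ValueError:
            raise SchemaError(
                f"{path}: row {i}: unknown exit_type {rec.exit_type!r}"
            ) from None
        out.append((rec.patient_id, int(los), exit_type))
    return out


def read_cohort_csv(physiology_path, stays_path) -> list[PatientStay]:
    """Assemble typed stays from the physiology table and the stays sidecar.

    Validates that each stay's physiology days are consecutive from 1 and
    that the recorded LOS matches the number of physiology rows.
    """
    rows = read_physiology_csv(physiology_path)
    by_patient: dict[str, list[DailyPhysiology]] = {}
    for row in rows:
        by_patient.setdefault(row.patient_id, []).append(row)
    stays = []
    for patient_id, los, exit_type in read_stays_csv(stays_path):
        physio = sorted(by_patient.pop(patient_id, []), key=lambda r: r.day)
        if len(physio) != los:
            raise SchemaError(
                f"{stays_path}: stay {patient_id}: los={los} but "
                f"{len(physio)} physiology rows"
            )
        try:
            stays.append(
                PatientStay(
                    patient_id=patient_id, physiology=physio, exit_type=exit_type
                )
            )
        except ValueError as err:
            raise SchemaError(f"{physiology_path}: {err}") from None
    if by_patient:
        raise SchemaError(
            f"{physiology_path}: physiology rows for patients missing from the "
            f"stays file: {sorted(by_patient)[:5]}"
        )
    return stays


def write_sofa_csv(scored: dict[str, Sequence[SofaDay]], path, config=None) -> None:
    """Write one row per patient-day with the six subscores and the total."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SOFA_COLUMNS)
        for patient_id in scored:
            for day, sofa in enumerate(scored[patient_id], start=1):
                writer.writerow(
                    [patient_id, day, *sofa.as_tuple(), sofa.total]
                )
    if config is not None:
        write_meta_sidecar(path, config)


def read_sofa_csv(path) -> dict[str, list[SofaDay]]:
    df = _read_rows(path, _SOFA_COLUMNS)
    scored: dict[str, list[SofaDay]] = {}
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        rec = rec._asdict()
        parts = {}
        for col in ("coag", "renal", "liver", "cns", "resp", "cardio"):
            v = _cell_float(rec[col], path, i, col)
            if v is None or v != int(v) or not 0 <= v <= 4:
                raise SchemaError(
                    f"{path}: row {i}, column {col!r}: invalid subscore {rec[col]!r}"
                )
            parts[col] = int(v)
        sofa = SofaDay(**parts)
        total = _cell_float(rec["total"], path, i, "total")
        if total != sofa.total:
            raise SchemaError(
                f"{path}: row {i}: total {total} != sum of subscores {sofa.total}"
            )
        day_list = scored.setdefault(rec["patient_id"], [])
        day = _cell_float(rec["day"], path, i, "day")
        if day != len(day_list) + 1:
            raise SchemaError(
                f"{path}: row {i}: day {rec['day']!r} out of order for "
                f"patient {rec['patient_id']}"
            )
        day_list.append(sofa)
    return scored


def write_dataset_csv(dataset: SupervisedDataset, path, config=None) -> None:
    dataset.to_frame().to_csv(path, index=False)
    if config is not None:
        write_meta_sidecar(path, config)


def read_dataset_csv(path) -> SupervisedDataset:
    """Read the supervised dataset; enforces the 19 canonical predictors."""
    expected = _DATASET_META + FEATURE_NAMES + _DATASET_TAIL
    df = _read_rows(path, expected)
    n = len(df)
    X = np.empty((n, len(FEATURE_NAMES)))
    for j, col in enumerate(FEATURE_NAMES):
        for i, raw in enumerate(df[col], start=2):
            v = _cell_float(raw, path, i, col)
            if v is None:
                raise SchemaError(
                    f"{path}: row {i}, column {col!r}: blank predictor cell"
                )
            X[i - 2, j] = v
    remaining = np.array(
        [_cell_float(v, path, i, "remaining_los")
         for i, v in enumerate(df["remaining_los"], start=2)]
    )
    event_raw = df["event"].str.lower()
    bad = ~event_raw.isin(["true", "false", "0", "1"])
    if bad.any():
        row = int(np.argmax(bad.values)) + 2
        raise SchemaError(f"{path}: row {row}: invalid event flag")
    event = event_raw.isin(["true", "1"]).values
    index_day = np.array(
        [int(_cell_float(v, path, i, "index_day"))
         for i, v in enumerate(df["index_day"], start=2)]
    )
    return SupervisedDataset(
        X=X,
        remaining_los=remaining.astype(int),
        event=event,
        patient_id=df["patient_id"].values,
        index_day=index_day,
    )
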