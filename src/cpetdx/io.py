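"""Reading, writing, validating and stage-segmenting CPET tables.

CSV only; vendor formats (MGC, Cosmed, Vyaire) are out of scope.  Stage
boundaries are recovered from the treadmill speed channel because exports
carry no explicit phase markers.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .schema import (
    COLUMNS,
    CSV_HEADER,
    BreathSeries,
    PatientRecord,
    SchemaError,
    StageAnnotation,
    ValidationError,
    normalize_column_name,
)

__all__ = [
    "read_patient_table",
    "write_patient_table",
    "segment_stages",
    "validate_series",
    "SegmentationError",
    "read_manifest",
    "write_manifest",
    "load_cohort",
]

#: mph below which the treadmill is considered stationary (sensor jitter)
SPEED_EPSILON = 0.1

#: tolerated |RER - VCO2/VO2| before the validation report flags a row
RER_TOLERANCE = 0.05


class SegmentationError(ValueError):
    """The series cannot be split into rest/test/recovery (no test phase)."""


def read_patient_table(
    path: Union[str, os.PathLike],
    patient_id: Optional[str] = None,
    label: Optional[str] = None,
    mass: Optional[float] = None,
    age: Optional[float] = None,
    sex: Optional[str] = None,
) -> PatientRecord:
    """Read one patient's CSV into a validated :class:`PatientRecord`.

    Header names are matched case/whitespace-insensitively against known
    aliases (real CPET exports vary, e.g. ``VO2/kg((ml/min)/kg)``).

    Raises
    ------
    SchemaError
        if a required column is absent (named in the message).
    ValidationError
        if time is not strictly increasing or fewer than 3 rows parse.
    """
    path = Path(path)
    raw = pd.read_csv(path)
    rename: dict[str, str] = {}
    for col in raw.columns:
        canon = normalize_column_name(str(col))
        if canon is not None and canon not in rename.values():
            rename[col] = canon
    missing = [COLUMNS[c] for c in COLUMNS if c not in rename.values()]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s): {missing}")
    df = raw.rename(columns=rename).loc[:, list(COLUMNS)]

    bad = df.apply(pd.to_numeric, errors="coerce").isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
        raise ValidationError(f"{path.name}: unparseable rows at line(s) {lines}")
    series = BreathSeries(df)
    return PatientRecord(
        patient_id=patient_id or path.stem,
        series=series,
        label=label,
        mass=mass,
        age=age,
        sex=sex,
    )


def write_patient_table(record: PatientRecord, path: Union[str, os.PathLike]) -> Path:
    """Write the record's series as CSV in the canonical column order.

    Floats are formatted at 6 significant digits, so write -> read round-trips
    are value-identical at that precision and bytes are deterministic.
    """
    path = Path(path)
    df = record.series.data.copy()
    df.columns = list(CSV_HEADER)
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
    return path


def segment_stages(
    series: BreathSeries, speed_epsilon: float = SPEED_EPSILON
) -> StageAnnotation:
    """Partition a series into rest / test / recovery from the speed channel.

    Rest is the maximal all-stationary prefix; test runs from the first moving
    row through the last moving row; recovery is the remainder.  A row is
    "moving" when speed exceeds ``speed_epsilon`` (elevation is the tiebreak
    for grade-only ramp protocols).
    """
    moving = (series.speed > speed_epsilon) | (series.elevation > speed_epsilon)
    idx = np.flatnonzero(moving)
    if idx.size == 0:
        raise SegmentationError(
            f"speed never exceeds {speed_epsilon} mph: no test phase found"
        )
    first, last = int(idx[0]), int(idx[-1])
    n = len(series)
    return StageAnnotation(
        rest=(0, first), test=(first, last + 1), recovery=(last + 1, n)
    )


def validate_series(series: BreathSeries, rer_tol: float = RER_TOLERANCE) -> list[str]:
    """Return a report of violated invariants (empty list = clean); never raises.

    Checks: strictly increasing time; positivity of VO2, VCO2, VE; internal
    consistency |RER - VCO2/VO2| <= ``rer_tol``; RER inside the [0.5, 1.5]
    physiologic warning band.
    """
    report: list[str] = []
    t = series.time
    if not np.all(np.diff(t) > 0):
        report.append("time is not strictly increasing")
    for chan in ("vo2", "vco2", "ve"):
        vals = getattr(series, chan)
        if np.any(vals <= 0):
            report.append(f"{chan} has non-positive values")
    with np.errstate(divide="ignore", invalid="ignore"):
        implied = series.vco2 / series.vo2
    dev = np.abs(series.rer - implied)
    if np.any(dev > rer_tol):
        report.append(
            f"RER inconsistent with VCO2/VO2 (max deviation {np.nanmax(dev):.3g} "
            f"> {rer_tol})"
        )
    if np.any((series.rer < 0.5) | (series.rer > 1.5)):
        report.append("RER outside [0.5, 1.5] warning band")
    return report


# ---------------------------------------------------------------------------
# cohort manifest helpers

def write_manifest(records: list[PatientRecord], path: Union[str, os.PathLike]) -> Path:
    path = Path(path)
    cols = {"patient_id": [r.patient_id for r in records],
            "label": [r.label for r in records]}
    # demographics ride along when any record carries them (flowchart norms)
    for key in ("mass", "age", "sex"):
        vals = [getattr(r, key) for r in records]
        if any(v is not None for v in vals):
            cols[key] = vals
    pd.DataFrame(cols).to_csv(path, index=False, lineterminator="\n")
    return path


def read_manifest(path: Union[str, os.PathLike]) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"patient_id", "label"} <= set(df.columns):
        raise SchemaError("manifest must have columns patient_id,label")
    return df


def load_cohort(
    directory: Union[str, os.PathLike], manifest: Union[str, os.PathLike]
) -> list[PatientRecord]:
    """Load every patient listed in a manifest from ``directory``/<id>.csv."""
    directory = Path(directory)
    df = read_manifest(manifest)
    out = []
    for _, row in df.iterrows():
        extra = {}
        for key in ("mass", "age", "sex"):  # optional demographic columns
            if key in df.columns and not pd.isna(row[key]):
                extra[key] = row[key] if key == "sex" else float(row[key])
        rec = read_patient_table(
            directory / f"{row.patient_id}.csv",
            patient_id=str(row.patient_id),
            label=None if pd.isna(row.label) else str(row.label),
            **extra,
        )
        out.append(rec)
    return out
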