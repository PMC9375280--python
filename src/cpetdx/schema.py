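"""Canonical breath-by-breath CPET table schema and in-memory containers.

A CPET export is one row per averaged breath interval (commonly 30 s) with
gas-exchange, ventilatory and treadmill channels.  Everything downstream
(stage segmentation, feature extraction, the classifiers) speaks this schema.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "CSV_HEADER",
    "MODEL_CHANNELS",
    "SchemaError",
    "ValidationError",
    "BreathSeries",
    "PatientRecord",
    "StageAnnotation",
    "STAGES",
]

#: canonical column order (internal name -> CSV header name)
COLUMNS: dict[str, str] = {
    "time": "Time",
    "mets": "METS",
    "hr": "HR",
    "vo2": "VO2",
    "vo2_per_kg": "VO2_per_kg",
    "vco2": "VCO2",
    "rer": "RER",
    "ve": "VE",
    "ve_vo2": "VE_VO2",
    "ve_vco2": "VE_VCO2",
    "rr": "RR",
    "vt_ex": "VTex",
    "vt_in": "VTin",
    "speed": "Speed",
    "elevation": "Elevation",
}

CSV_HEADER: tuple[str, ...] = tuple(COLUMNS.values())

#: the 8 channels used by the statistical / neural models (demographics and
#: redundant ratio channels excluded)
MODEL_CHANNELS: tuple[str, ...] = (
    "mets", "hr", "vo2", "vco2", "rer", "ve", "vt_ex", "vt_in",
)

STAGES: tuple[str, ...] = ("rest", "test", "recovery")

# Aliases seen in real CPET exports, matched after lowercasing and stripping
# everything that is not alphanumeric.  Keys are the normalized forms.
_ALIASES: dict[str, str] = {
    "time": "time", "timemin": "time", "t": "time",
    "mets": "mets", "met": "mets",
    "hr": "hr", "heartrate": "hr", "hrbeatsmin": "hr",
    "vo2": "vo2", "vo2lmin": "vo2", "vo2l": "vo2",
    "vo2perkg": "vo2_per_kg", "vo2kg": "vo2_per_kg",
    "vo2kgmlminkg": "vo2_per_kg", "vo2mlminkg": "vo2_per_kg",
    "vco2": "vco2", "vco2lmin": "vco2",
    "rer": "rer",
    "ve": "ve", "velmin": "ve", "ventilation": "ve",
    "vevo2": "ve_vo2", "veo2": "ve_vo2",
    "vevco2": "ve_vco2", "veco2": "ve_vco2",
    "rr": "rr", "rrlmin": "rr", "respiratoryrate": "rr", "rrbreathsmin": "rr",
    "vtex": "vt_ex", "vtexl": "vt_ex", "vte": "vt_ex",
    "vtin": "vt_in", "vtinl": "vt_in", "vti": "vt_in",
    "speed": "speed", "speedmph": "speed",
    "elevation": "elevation", "grade": "elevation", "elevationpct": "elevation",
}


def normalize_column_name(name: str) -> Optional[str]:
    """Map an exported header to its canonical name, or ``None`` if unknown."""
    key = re.sub(r"[^a-z0-9]", "", name.lower())
    return _ALIASES.get(key)


class SchemaError(ValueError):
    """A table does not conform to the CPET column schema."""


class ValidationError(ValueError):
    """A table parses but violates a structural invariant (e.g. time order)."""


@dataclass
class BreathSeries:
    """One patient's multichannel breath-by-breath series.

    ``data`` holds the canonical columns (keys of :data:`COLUMNS`) as floats.
    Channel arrays are exposed as attributes, e.g. ``series.vo2``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        self.data = self.data.loc[:, list(COLUMNS)].astype(float).reset_index(drop=True)
        if len(self.data) < 3:
            raise ValidationError("a breath series needs at least 3 rows")
        t = self.data["time"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise ValidationError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.data)

    def __getattr__(self, name: str) -> np.ndarray:
        if name in COLUMNS:
            return self.data[name].to_numpy()
        raise AttributeError(name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BreathSeries):
            return NotImplemented
        return self.data.equals(other.data)

    def channel_matrix(self, channels: tuple[str, ...] = MODEL_CHANNELS) -> np.ndarray:
        """Return an observations x len(channels) matrix."""
        return self.data.loc[:, list(channels)].to_numpy()

    @property
    def sampling_interval(self) -> float:
        """Median spacing of the time grid, in minutes."""
        return float(np.median(np.diff(self.data["time"].to_numpy())))


@dataclass
class PatientRecord:
    """A breath series plus identity, clinical label and optional demographics."""

    patient_id: str
    series: BreathSeries
    label: Optional[str] = None
    mass: Optional[float] = None  # kg, used only by the flowchart norms
    age: Optional[float] = None
    sex: Optional[str] = None  # 'M' | 'F'

    _LABELS = ("heart_failure", "metabolic_syndrome")

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in self._LABELS:
            raise ValueError(
                f"label must be one of {self._LABELS} or None, got {self.label!r}"
            )
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")


@dataclass(frozen=True)
class StageAnnotation:
    """Contiguous rest / test / recovery index ranges, 0-based half-open.

    The three ranges partition ``range(n)``; rest and recovery may be empty.
    """

    rest: tuple[int, int]
    test: tuple[int, int]
    recovery: tuple[int, int]

    def __post_init__(self) -> None:
        r, t, v = self.rest, self.test, self.recovery
        if not (r[0] == 0 and r[1] == t[0] and t[1] == v[0]):
            raise ValueError("stage ranges must be contiguous starting at 0")
        if t[1] <= t[0]:
            raise ValueError("test stage must be non-empty")

    @property
    def n(self) -> int:
        return self.recovery[1]

    def indices(self, stage: str) -> np.ndarray:
        lo, hi = getattr(self, stage)
        return np.arange(lo, hi)

    def slices(self) -> dict[str, slice]:
        return {s: slice(*getattr(self, s)) for s in STAGES}
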