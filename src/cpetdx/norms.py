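"""Normal-value references for peak V̇O2 and the anaerobic threshold.

Two styles are provided, mirroring the two sources used in clinical practice:

* **Hansen-style**: predicted peak V̇O2 from linear equations in age and body
  mass (per sex), with lower limits expressed as fractions of predicted
  (default 0.84 for peak, 0.40 of predicted peak for the AT).
* **FRIEND-style**: a sex x age-decade percentile lookup of peak V̇O2 per kg
  (50th percentile as predicted, 20th as the lower limit).

The embedded constants are defaults approximating the published sources, not
reproductions of them; every number can be overridden from a YAML/JSON
mapping via :func:`load_norms`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

__all__ = ["ReferenceNorms", "HansenNorms", "FriendNorms",
           "hansen_norms", "friend_norms", "load_norms", "percent_predicted"]


@dataclass
class ReferenceNorms:
    """Base interface: predicted peak V̇O2 (mL/min) plus lower-limit rules."""

    source: str = "base"
    peak_vo2_lower_limit_fraction: float = 0.84
    at_lower_limit_fraction: float = 0.40

    def __post_init__(self) -> None:
        for f in (self.peak_vo2_lower_limit_fraction, self.at_lower_limit_fraction):
            if not 0 < f < 1:
                raise ValueError("lower-limit fractions must be in (0, 1)")

    def predicted_peak_vo2(self, age: float, sex: str, mass: float) -> float:
        raise NotImplementedError

    def peak_vo2_lower_limit(self, age: float, sex: str, mass: float) -> float:
        """mL/min below which measured peak V̇O2 is abnormal."""
        return self.peak_vo2_lower_limit_fraction * self.predicted_peak_vo2(age, sex, mass)

    def at_lower_limit(self, age: float, sex: str, mass: float) -> float:
        """mL/min below which the AT is abnormal (fraction of predicted peak)."""
        return self.at_lower_limit_fraction * self.predicted_peak_vo2(age, sex, mass)


def _check_demographics(age, sex, mass) -> None:
    if age is None or sex is None or mass is None:
        raise ValueError(
            "percent-predicted needs age, sex and body mass; attach them to the "
            "PatientRecord (or manifest) before running the flowchart"
        )
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")


@dataclass
class HansenNorms(ReferenceNorms):
    """Linear predicted-peak-V̇O2 equations in age and mass, per sex.

    predicted (mL/min) = (mass + mass_offset) x (intercept + slope x age)
    """

    source: str = "Hansen"
    male: dict = field(default_factory=lambda: {
        "intercept": 50.72, "age_slope": -0.372, "mass_offset": 0.0})
    female: dict = field(default_factory=lambda: {
        "intercept": 22.78, "age_slope": -0.17, "mass_offset": 43.0})

    def predicted_peak_vo2(self, age: float, sex: str, mass: float) -> float:
        _check_demographics(age, sex, mass)
        c = self.male if sex == "M" else self.female
        value = (mass + c["mass_offset"]) * (c["intercept"] + c["age_slope"] * age)
        if value <= 0:
            raise ValueError(f"predicted peak V̇O2 non-positive for age={age}")
        return value


# default sex x age-decade peak V̇O2/kg percentiles (mL/min/kg); decades are
# keyed by their lower bound, clamped at both ends of the table
_FRIEND_P50 = {
    "M": {20: 48.0, 30: 42.4, 40: 37.8, 50: 32.6, 60: 28.2, 70: 24.4},
    "F": {20: 37.6, 30: 30.2, 40: 26.7, 50: 23.4, 60: 20.0, 70: 18.3},
}
_FRIEND_P20 = {
    "M": {20: 38.1, 30: 32.7, 40: 28.8, 50: 24.5, 60: 20.9, 70: 17.9},
    "F": {20: 28.6, 30: 23.5, 40: 20.6, 50: 17.6, 60: 15.2, 70: 13.6},
}


@dataclass
class FriendNorms(ReferenceNorms):
    """Registry-style percentile lookup of peak V̇O2 per kg by sex and decade."""

    source: str = "FRIEND"
    p50: dict = field(default_factory=lambda: {s: dict(d) for s, d in _FRIEND_P50.items()})
    p20: dict = field(default_factory=lambda: {s: dict(d) for s, d in _FRIEND_P20.items()})

    def _decade(self, age: float) -> int:
        decades = sorted(self.p50["M"])
        return max(decades[0], min(decades[-1], int(age // 10) * 10))

    def predicted_peak_vo2(self, age: float, sex: str, mass: float) -> float:
        _check_demographics(age, sex, mass)
        return self.p50[sex][self._decade(age)] * mass

    def peak_vo2_lower_limit(self, age: float, sex: str, mass: float) -> float:
        # the registry's 20th percentile stands in for a fraction-of-predicted rule
        _check_demographics(age, sex, mass)
        return self.p20[sex][self._decade(age)] * mass


def hansen_norms() -> HansenNorms:
    return HansenNorms()


def friend_norms() -> FriendNorms:
    return FriendNorms()


def load_norms(spec: Union[str, Path, dict, ReferenceNorms]) -> ReferenceNorms:
    """Resolve a norms spec: 'hansen' | 'friend' | YAML/JSON path | mapping."""
    if isinstance(spec, ReferenceNorms):
        return spec
    if isinstance(spec, (str, Path)):
        name = str(spec).lower()
        if name == "hansen":
            return hansen_norms()
        if name == "friend":
            return friend_norms()
        with open(spec) as fh:
            spec = yaml.safe_load(fh)
    if not isinstance(spec, dict):
        raise TypeError(f"cannot interpret norms spec {spec!r}")
    source = spec.get("source", "hansen").lower()
    kwargs = {k: v for k, v in spec.items() if k != "source"}
    if source == "hansen":
        return HansenNorms(**kwargs)
    if source == "friend":
        # allow string age keys from YAML
        for tbl in ("p50", "p20"):
            if tbl in kwargs:
                kwargs[tbl] = {s: {int(a): float(v) for a, v in d.items()}
                               for s, d in kwargs[tbl].items()}
        return FriendNorms(**kwargs)
    raise ValueError(f"unknown norms source {source!r}")


def percent_predicted(
    measured_ml_min: float, norms: ReferenceNorms,
    age: float, sex: str, mass: float,
) -> float:
    """100 x measured / predicted peak V̇O2 (both in mL/min)."""
    if measured_ml_min < 0:
        raise ValueError("measured value must be >= 0")
    return 100.0 * measured_ml_min / norms.predicted_peak_vo2(age, sex, mass)
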