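"""Synthetic breath-by-breath CPET cohort generator.

The generator emulates a treadmill ramp protocol with three phases (rest,
incremental test, recovery) and the physiological coupling that drives CPET
interpretation:

* V̇O2 follows a first-order lag toward a work-rate-proportional target that
  saturates at the archetype's peak (external-to-cellular respiration
  coupling; time constant ~0.5 min).
* V̇CO2 is a two-segment piecewise-linear function of V̇O2 with the slope
  break at the anaerobic threshold (the V-slope signature), so RER = V̇CO2/V̇O2
  starts near 0.8 and crosses 1.0 beyond the AT.
* VE is linearly coupled to V̇CO2 (VE/V̇CO2 slope; elevated in heart failure).
* HR lags toward rest + (max − rest)·work fraction.

Condition contrasts are parameterized by :class:`ConditionArchetype`:
heart failure = low peak V̇O2, early AT, steep VE/V̇CO2 slope, low HR reserve;
metabolic syndrome = near-normal gas exchange at higher body mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .schema import BreathSeries, PatientRecord

__all__ = [
    "Protocol",
    "ConditionArchetype",
    "ProtocolError",
    "ParameterError",
    "HEART_FAILURE",
    "METABOLIC_SYNDROME",
    "simulate_patient",
    "simulate_cohort",
]


class ProtocolError(ValueError):
    """The protocol is internally inconsistent (e.g. non-integer row count)."""


class ParameterError(ValueError):
    """An archetype parameter is out of its physiologic domain."""


@dataclass(frozen=True)
class Protocol:
    """Treadmill three-phase protocol on a uniform averaging grid.

    Durations are minutes; ``sampling_interval`` is the breath-averaging
    window (default 30 s).  Speed/elevation are 0 at rest, ramp linearly and
    non-decreasingly from the start values to the peaks during the test, and
    drop back to 0 in recovery.
    """

    rest_duration: float = 3.0
    ramp_duration: float = 10.0
    recovery_duration: float = 3.0
    sampling_interval: float = 0.5
    speed_start: float = 1.0
    speed_peak: float = 4.0
    elevation_start: float = 0.0
    elevation_peak: float = 12.0

    def __post_init__(self) -> None:
        for name in ("rest_duration", "ramp_duration", "recovery_duration",
                     "sampling_interval"):
            if getattr(self, name) <= 0:
                raise ProtocolError(f"{name} must be > 0")
        if self.speed_peak < self.speed_start or self.elevation_peak < self.elevation_start:
            raise ProtocolError("ramp schedules must be non-decreasing")
        total = self.rest_duration + self.ramp_duration + self.recovery_duration
        rows = total / self.sampling_interval
        if abs(rows - round(rows)) > 1e-9:
            raise ProtocolError(
                f"total duration {total} min is not an integer number of "
                f"{self.sampling_interval}-min rows"
            )

    @property
    def n_rows(self) -> int:
        total = self.rest_duration + self.ramp_duration + self.recovery_duration
        return round(total / self.sampling_interval)

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_rows) * self.sampling_interval

    def work_fraction(self, t: np.ndarray) -> np.ndarray:
        """Fraction of peak work rate at each time (0 at rest and recovery)."""
        frac = (t - self.rest_duration) / self.ramp_duration
        w = np.clip(frac, 0.0, 1.0)
        w[t >= self.rest_duration + self.ramp_duration] = 0.0
        return w

    def speed_profile(self, t: np.ndarray) -> np.ndarray:
        in_test = (t >= self.rest_duration) & (t < self.rest_duration + self.ramp_duration)
        frac = np.clip((t - self.rest_duration) / self.ramp_duration, 0.0, 1.0)
        return np.where(in_test, self.speed_start + (self.speed_peak - self.speed_start) * frac, 0.0)

    def elevation_profile(self, t: np.ndarray) -> np.ndarray:
        in_test = (t >= self.rest_duration) & (t < self.rest_duration + self.ramp_duration)
        frac = np.clip((t - self.rest_duration) / self.ramp_duration, 0.0, 1.0)
        return np.where(in_test, self.elevation_start + (self.elevation_peak - self.elevation_start) * frac, 0.0)


@dataclass(frozen=True)
class ConditionArchetype:
    """Condition-level physiological parameters for one diagnostic group."""

    label: str
    peak_vo2_per_kg: float        # mL/min/kg
    at_fraction_of_peak: float    # AT as a fraction of peak V̇O2, in (0,1)
    ve_vco2_slope: float          # ventilatory efficiency slope
    hr_max: float                 # beats/min
    body_mass: float              # kg
    noise_sd_per_channel: float = 0.02  # fraction of channel dynamic range
    age: float = 50.0
    sex: str = "M"
    hr_rest: float = 75.0
    rr_rest: float = 14.0
    rr_max: float = 40.0
    vslope_lower: float = 0.82    # V̇CO2/V̇O2 slope below the AT
    vslope_upper: float = 1.35    # slope above the AT
    ve_intercept: float = 3.0     # L/min
    vo2_tau: float = 0.5          # first-order V̇O2 kinetics, minutes
    hr_tau: float = 0.75

    def __post_init__(self) -> None:
        if self.peak_vo2_per_kg <= 0:
            raise ParameterError("peak_vo2_per_kg must be > 0")
        if not 0 < self.at_fraction_of_peak < 1:
            raise ParameterError("at_fraction_of_peak must be in (0, 1)")
        if self.ve_vco2_slope <= 0:
            raise ParameterError("ve_vco2_slope must be > 0")
        if self.noise_sd_per_channel < 0:
            raise ParameterError("noise_sd_per_channel must be >= 0")

    @property
    def peak_vo2(self) -> float:
        """Peak V̇O2 in L/min."""
        return self.peak_vo2_per_kg * self.body_mass / 1000.0

    @property
    def at_vo2(self) -> float:
        """Anaerobic-threshold V̇O2 in L/min."""
        return self.at_fraction_of_peak * self.peak_vo2


#: default heart-failure archetype: low peak V̇O2, early AT, steep VE/V̇CO2
HEART_FAILURE = ConditionArchetype(
    label="heart_failure",
    peak_vo2_per_kg=14.0,
    at_fraction_of_peak=0.45,
    ve_vco2_slope=38.0,
    hr_max=130.0,
    body_mass=85.0,
    age=60.0,
    sex="M",
)

#: default metabolic-syndrome archetype: near-normal gas exchange, higher mass
METABOLIC_SYNDROME = ConditionArchetype(
    label="metabolic_syndrome",
    peak_vo2_per_kg=28.0,
    at_fraction_of_peak=0.60,
    ve_vco2_slope=27.0,
    hr_max=165.0,
    body_mass=98.0,
    age=45.0,
    sex="M",
)

# physiologic floors applied after additive noise
_FLOORS = {"vo2": 0.15, "vco2": 0.10, "ve": 3.0, "hr": 40.0, "rr": 6.0}


def _first_order_lag(target: np.ndarray, x0: float, dt: float, tau: float) -> np.ndarray:
    """Discrete first-order relaxation of x toward target with time constant tau."""
    alpha = 1.0 - math.exp(-dt / tau)
    out = np.empty_like(target)
    x = x0
    for i, tgt in enumerate(target):
        x = x + (tgt - x) * alpha
        out[i] = x
    return out


def _vco2_from_vo2(vo2: np.ndarray, arch: ConditionArchetype) -> np.ndarray:
    """Two-segment V-slope relation with the break at the AT."""
    at = arch.at_vo2
    below = arch.vslope_lower * vo2
    above = arch.vslope_lower * at + arch.vslope_upper * (vo2 - at)
    return np.where(vo2 <= at, below, above)


def simulate_patient(
    archetype: ConditionArchetype,
    protocol: Protocol = Protocol(),
    seed: int = 0,
    patient_id: Optional[str] = None,
) -> PatientRecord:
    """Simulate one patient's breath-by-breath table; deterministic given seed.

    Noise is additive Gaussian on the primary channels (V̇O2, V̇CO2, VE, HR,
    RR) with SD = ``noise_sd_per_channel`` x that channel's noiseless dynamic
    range, clipped at physiologic floors.  Derived channels (RER, VE/V̇O2,
    VE/V̇CO2, METS, V̇O2/kg, tidal volumes) are recomputed from the noisy
    primaries, so definitional identities hold at any noise level.
    """
    rng = np.random.default_rng(seed)
    t = protocol.time_grid()
    dt = protocol.sampling_interval
    w = protocol.work_fraction(t)

    vo2_rest = 3.5 * archetype.body_mass / 1000.0  # 1 MET baseline, L/min
    peak = archetype.peak_vo2
    target = np.minimum(vo2_rest + (peak - vo2_rest) * w, peak)
    vo2 = _first_order_lag(target, vo2_rest, dt, archetype.vo2_tau)
    vco2 = _vco2_from_vo2(vo2, archetype)
    ve = archetype.ve_vco2_slope * vco2 + archetype.ve_intercept
    hr_target = archetype.hr_rest + (archetype.hr_max - archetype.hr_rest) * w
    hr = _first_order_lag(hr_target, archetype.hr_rest, dt, archetype.hr_tau)
    ve_span = max(ve.max() - ve.min(), 1e-9)
    rr = archetype.rr_rest + (archetype.rr_max - archetype.rr_rest) * (ve - ve.min()) / ve_span

    primaries = {"vo2": vo2, "vco2": vco2, "ve": ve, "hr": hr, "rr": rr}
    if archetype.noise_sd_per_channel > 0:
        for name, clean in primaries.items():
            span = max(clean.max() - clean.min(), 0.05 * abs(clean.mean()))
            noisy = clean + rng.normal(0.0, archetype.noise_sd_per_channel * span, clean.shape)
            primaries[name] = np.maximum(noisy, _FLOORS[name])
    vo2, vco2, ve, hr, rr = (primaries[k] for k in ("vo2", "vco2", "ve", "hr", "rr"))

    vt_ex = ve / rr
    vt_in = 1.05 * vt_ex  # inspiratory volumes run slightly above expiratory
    vo2_per_kg = vo2 * 1000.0 / archetype.body_mass
    df = pd.DataFrame({
        "time": t,
        "mets": vo2_per_kg / 3.5,
        "hr": hr,
        "vo2": vo2,
        "vo2_per_kg": vo2_per_kg,
        "vco2": vco2,
        "rer": vco2 / vo2,
        "ve": ve,
        "ve_vo2": ve / vo2,
        "ve_vco2": ve / vco2,
        "rr": rr,
        "vt_ex": vt_ex,
        "vt_in": vt_in,
        "speed": protocol.speed_profile(t),
        "elevation": protocol.elevation_profile(t),
    })
    return PatientRecord(
        patient_id=patient_id or f"{archetype.label[:2].upper()}-{seed}",
        series=BreathSeries(df),
        label=archetype.label,
        mass=archetype.body_mass,
        age=archetype.age,
        sex=archetype.sex,
    )


def simulate_cohort(
    n_per_condition: int,
    hf_archetype: ConditionArchetype = HEART_FAILURE,
    ms_archetype: ConditionArchetype = METABOLIC_SYNDROME,
    protocol: Protocol = Protocol(),
    seed: int = 0,
    mass_jitter: float = 0.10,
    hr_max_jitter: float = 8.0,
) -> list[PatientRecord]:
    """Simulate a balanced two-condition cohort (2·n records).

    Per-patient seeds derive deterministically from the master seed.  Each
    patient gets demographic jitter: body mass uniform within ±``mass_jitter``
    (fractional) and HR max uniform within ±``hr_max_jitter`` beats/min of the
    archetype values.
    """
    if n_per_condition < 1:
        raise ParameterError("n_per_condition must be >= 1")
    master = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    for arch, prefix in ((hf_archetype, "HF"), (ms_archetype, "MS")):
        for i in range(n_per_condition):
            jitter_rng = np.random.default_rng(master.integers(0, 2**31 - 1))
            mass = arch.body_mass * (1.0 + jitter_rng.uniform(-mass_jitter, mass_jitter))
            hr_max = arch.hr_max + jitter_rng.uniform(-hr_max_jitter, hr_max_jitter)
            patient_arch = replace(arch, body_mass=mass, hr_max=hr_max)
            rec = simulate_patient(
                patient_arch,
                protocol,
                seed=int(master.integers(0, 2**31 - 1)),
                patient_id=f"{prefix}{i + 1:02d}",
            )
            records.append(rec)
    return records
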