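"""Study-design dataclasses: fish ground truth, chamber protocol, scenarios.

These describe both real intermittent-flow experiments (protocol, treatment
labels) and the simulator's ground truth for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "FishTruth",
    "ProtocolConfig",
    "BackgroundModel",
    "ScenarioConfig",
    "TEMPERATURE_LEVELS_C",
    "ACCLIMATION_LEVELS_DAYS",
    "OXYGEN_TREATMENTS",
]

#: Factorial treatment levels used in the study design.
TEMPERATURE_LEVELS_C = (20.0, 24.0, 28.0)
ACCLIMATION_LEVELS_DAYS = (7, 14, 30)
#: Treatment name -> nominal bath dissolved O2 in mg/L (midpoint of the
#: maintained band: normoxia 6-8 mg/L, low oxygen 3-4 mg/L).
OXYGEN_TREATMENTS = {"normoxia": 7.0, "hypoxia": 3.5}


@dataclass(frozen=True)
class FishTruth:
    """Ground-truth physiology of one simulated fish.

    Rates are mass-specific in mg O2 kg^-1 h^-1; oxygen tensions in kPa.
    `recovery_halflife_h` governs the exponential return from maximum to
    standard metabolic rate after the exhaustive chase.
    """

    body_mass_kg: float = 0.0015
    body_length_cm: float = 5.5
    smr: float = 250.0
    mmr: float = 700.0
    pcrit_kpa: float = 6.0
    loe_po2_kpa: float = 2.5
    recovery_halflife_h: float = 2.0
    background_slope: float = 0.0  # blank-chamber depletion, mg O2 L^-1 h^-1

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0:
            raise ValueError("body_mass_kg must be > 0")
        if not self.mmr > self.smr > 0:
            raise ValueError("require MMR > SMR > 0")
        if not 0 < self.loe_po2_kpa < self.pcrit_kpa:
            raise ValueError("require 0 < loss-of-equilibrium PO2 < Pcrit")
        if self.recovery_halflife_h <= 0:
            raise ValueError("recovery_halflife_h must be > 0")


@dataclass(frozen=True)
class ProtocolConfig:
    """Chamber and cycle protocol for intermittent-flow respirometry.

    Defaults: 300 mL chambers, 20 min sealed determinations alternating with
    2 min flushes, ~24 h in the chamber, preceded by a 2 min exhaustive
    chase plus 40 s air exposure (the maximum-metabolic-rate protocol).
    """

    chamber_volume_l: float = 0.300
    determination_minutes: float = 20.0
    flush_minutes: float = 2.0
    sample_interval_s: float = 1.0
    total_hours: float = 24.0
    chase_minutes: float = 2.0
    air_exposure_seconds: float = 40.0

    def __post_init__(self) -> None:
        for name in (
            "chamber_volume_l",
            "determination_minutes",
            "flush_minutes",
            "sample_interval_s",
            "total_hours",
            "chase_minutes",
            "air_exposure_seconds",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sample_interval_s > 60.0:
            raise ValueError("sample_interval_s must be <= 60 s")

    @property
    def cycle_seconds(self) -> float:
        return (self.determination_minutes + self.flush_minutes) * 60.0

    def effective_volume_l(self, body_mass_kg: float) -> float:
        """Chamber volume minus animal volume (neutral buoyancy, 1 g/mL)."""
        v = self.chamber_volume_l - body_mass_kg / 1.0
        if v <= 0:
            raise ValueError("animal volume exceeds chamber volume")
        return v


@dataclass(frozen=True)
class BackgroundModel:
    """Microbial (blank-chamber) respiration over the run.

    `daily_blank_slopes` holds one blank-chamber O2 depletion slope per day
    (mg O2 L^-1 h^-1, non-negative); `drift` is an optional fractional
    increase per day applied multiplicatively on top.
    """

    daily_blank_slopes: tuple = (0.0,)
    drift: float = 0.0

    def __post_init__(self) -> None:
        if len(self.daily_blank_slopes) == 0:
            raise ValueError("need at least one daily blank slope")
        if any(s < 0 for s in self.daily_blank_slopes):
            raise ValueError("blank slopes must be >= 0")

    def slope_at(self, t_hours: float) -> float:
        """Blank slope at a time point, linearly interpolated between days."""
        import numpy as np

        days = np.arange(len(self.daily_blank_slopes), dtype=float)
        s = float(np.interp(t_hours / 24.0, days, self.daily_blank_slopes))
        return s * (1.0 + self.drift * t_hours / 24.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the factorial design plus simulator noise settings.

    Temperature levels 20/24/28 degC crossed with bath oxygen treatment
    (normoxia 6-8 mg/L vs low oxygen 3-4 mg/L) and acclimation duration
    (7/14/30 days). `noise_sd` is i.i.d. Gaussian sensor noise on
    concentration per sample.
    """

    temperature_c: float = 24.0
    oxygen_treatment: str = "normoxia"
    acclimation_days: int = 30
    n_fish: int = 12
    noise_sd: float = 0.02
    seed: int = 0
    barometric_pressure_kpa: float = 101.325

    def __post_init__(self) -> None:
        if self.oxygen_treatment not in OXYGEN_TREATMENTS:
            raise ValueError(
                f"oxygen_treatment must be one of {sorted(OXYGEN_TREATMENTS)}"
            )
        if self.n_fish < 0:
            raise ValueError("n_fish must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def bath_o2_mgl(self) -> float:
        return OXYGEN_TREATMENTS[self.oxygen_treatment]
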