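"""Synthetic chamber-oxygen traces from fish with known physiology.

Generates the two trace kinds the analysis pipeline consumes:

* an intermittent-flow run — alternating sealed 20-min determinations and
  2-min flushes over ~24 h, beginning immediately after an exhaustive chase
  so the first determination reflects maximum metabolic rate, with the
  fish's oxygen uptake decaying exponentially back to its standard rate;
* a closed-respirometry run — flushing off, oxygen falling until the fish
  loses equilibrium, with uptake independent of PO2 above the critical
  tension (oxy-regulation) and proportional to PO2 below it
  (oxy-conformity, a line through the origin).

Every trace is paired with the ``FishTruth`` that generated it, so each
downstream estimator has an exact parameter-recovery target. All randomness
flows from the scenario seed; per-fish substreams are spawned
deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BackgroundModel, FishTruth, ProtocolConfig, ScenarioConfig
from .trace_io import (
    PHASE_CLOSED,
    PHASE_DETERMINATION,
    PHASE_FLUSH,
    OxygenTrace,
)
from .units import WaterConditions, mgL_to_kPa, o2_saturation_concentration, po2_air_kpa

__all__ = [
    "simulate_intermittent_trace",
    "simulate_closed_phase",
    "simulate_cohort",
    "draw_fish_truth",
    "Cohort",
    "CohortFish",
]

#: Oxygen floor honoured during determinations (protocol clamp).
O2_FLOOR_MGL = 1.0


def _conditions(scenario: ScenarioConfig) -> WaterConditions:
    return WaterConditions(
        temperature=scenario.temperature_c,
        barometric_pressure=scenario.barometric_pressure_kpa,
    )


def _base_meta(truth: FishTruth, protocol: ProtocolConfig, scenario: ScenarioConfig) -> dict:
    return {
        "body_mass_kg": truth.body_mass_kg,
        "body_length_cm": truth.body_length_cm,
        "chamber_volume_l": protocol.chamber_volume_l,
        "temperature_c": scenario.temperature_c,
        "barometric_pressure_kpa": scenario.barometric_pressure_kpa,
        "oxygen_treatment": scenario.oxygen_treatment,
        "acclimation_days": scenario.acclimation_days,
    }


def simulate_intermittent_trace(
    truth: FishTruth,
    protocol: ProtocolConfig,
    background: BackgroundModel | None = None,
    scenario: ScenarioConfig | None = None,
    rng: np.random.Generator | None = None,
) -> OxygenTrace:
    """Simulate one intermittent-flow run for a single fish.

    The fish enters the chamber at t=0 straight after the chase protocol, so
    its oxygen uptake starts at ``truth.mmr`` and decays exponentially toward
    ``truth.smr`` with half-life ``truth.recovery_halflife_h``. Uptake is held
    constant within each determination at its cycle-start value (a 20-min
    cycle integrates the probe signal anyway), giving noiseless runs exact
    slope-recovery identities. During a determination the chamber O2 falls
    linearly at (uptake x mass + background x chamber volume) / effective
    volume; flushes ramp O2 back to the bath value. Determinations that would
    drop below 1 mg/L are clamped there and flagged in
    ``meta['clamped_cycles']``.
    """
    scenario = scenario or ScenarioConfig()
    background = background or BackgroundModel()
    if rng is None:
        rng = np.random.default_rng(scenario.seed)

    dt = protocol.sample_interval_s
    det_s = protocol.determination_minutes * 60.0
    flush_s = protocol.flush_minutes * 60.0
    cycle_s = det_s + flush_s
    times = np.arange(0.0, protocol.total_hours * 3600.0, dt)
    v_eff = protocol.effective_volume_l(truth.body_mass_kg)
    bath = scenario.bath_o2_mgl

    o2 = np.empty_like(times)
    phase = np.empty(times.size, dtype=object)
    cycle_index = np.full(times.size, -1, dtype=int)

    n_cycles = int(np.ceil(times[-1] / cycle_s)) + 1
    clamped: list[int] = []
    true_mo2: list[float] = []
    ln2 = np.log(2.0)

    for ci in range(n_cycles):
        t0 = ci * cycle_s
        in_cycle = (times >= t0) & (times < t0 + cycle_s)
        if not in_cycle.any():
            continue
        tau = times[in_cycle] - t0
        det = tau < det_s

        mo2 = truth.smr + (truth.mmr - truth.smr) * np.exp(
            -ln2 * (t0 / 3600.0) / truth.recovery_halflife_h
        )
        true_mo2.append(float(mo2))
        bg = background.slope_at(t0 / 3600.0)
        rate = (mo2 * truth.body_mass_kg + bg * protocol.chamber_volume_l) / v_eff

        seg = np.empty(tau.size)
        seg[det] = bath - rate * tau[det] / 3600.0
        o2_end = bath - rate * det_s / 3600.0
        if (seg[det] < O2_FLOOR_MGL).any() or o2_end < O2_FLOOR_MGL:
            seg[det] = np.maximum(seg[det], O2_FLOOR_MGL)
            o2_end = max(o2_end, O2_FLOOR_MGL)
            clamped.append(ci)
        seg[~det] = o2_end + (bath - o2_end) * (tau[~det] - det_s) / flush_s

        o2[in_cycle] = seg
        phase[in_cycle] = np.where(det, PHASE_DETERMINATION, PHASE_FLUSH)
        cycle_index[in_cycle] = ci

    if scenario.noise_sd > 0:
        o2 = o2 + rng.normal(0.0, scenario.noise_sd, size=o2.size)
    o2 = np.maximum(o2, 0.0)

    meta = _base_meta(truth, protocol, scenario)
    meta["trace_kind"] = "intermittent"
    meta["clamped_cycles"] = ",".join(map(str, clamped))
    df = pd.DataFrame(
        {
            "time_s": times,
            "o2_mgL": o2,
            "temp_C": scenario.temperature_c,
            "phase": phase,
            "cycle_index": cycle_index,
        }
    )
    trace = OxygenTrace(data=df, meta=meta)
    trace.meta["true_cycle_mo2"] = true_mo2  # not serialised; for tests
    return trace


def simulate_closed_phase(
    truth: FishTruth,
    protocol: ProtocolConfig,
    scenario: ScenarioConfig | None = None,
    rng: np.random.Generator | None = None,
    max_hours: float = 48.0,
) -> OxygenTrace:
    """Simulate the closed-respirometry phase ending in loss of equilibrium.

    The chamber starts at the bath O2 of the scenario with flushing off.
    Oxygen uptake equals SMR while PO2 >= Pcrit and SMR x PO2/Pcrit below it,
    which makes the concentration decline linear above the critical tension
    and exponential beneath it (both in closed form). The trace terminates
    at the first sample whose (noiseless) PO2 is at or below the fish's
    loss-of-equilibrium tension; that sample index is stored in
    ``meta['loe_index']``.
    """
    scenario = scenario or ScenarioConfig()
    if rng is None:
        rng = np.random.default_rng(scenario.seed)

    cond = _conditions(scenario)
    kpa_per_mgl = po2_air_kpa(cond) / o2_saturation_concentration(cond)
    c0 = scenario.bath_o2_mgl
    c_crit = truth.pcrit_kpa / kpa_per_mgl
    c_loe = truth.loe_po2_kpa / kpa_per_mgl
    if c_loe >= c0:
        raise ValueError(
            "loss-of-equilibrium PO2 is at or above the starting bath PO2"
        )

    v_eff = protocol.effective_volume_l(truth.body_mass_kg)
    a = truth.smr * truth.body_mass_kg / v_eff  # mg L^-1 h^-1 while regulating

    dt_h = protocol.sample_interval_s / 3600.0
    times_h = np.arange(0.0, max_hours, dt_h)

    # closed-form piecewise trajectory: linear to the critical tension,
    # then exponential decay (uptake proportional to PO2)
    if c0 > c_crit:
        t_reg = (c0 - c_crit) / a
        conc = np.where(
            times_h <= t_reg,
            c0 - a * times_h,
            c_crit * np.exp(-(a / c_crit) * (times_h - t_reg)),
        )
    else:
        conc = c0 * np.exp(-(a / c_crit) * times_h)

    below = np.nonzero(conc * kpa_per_mgl <= truth.loe_po2_kpa)[0]
    if below.size == 0:
        raise ValueError("trace did not reach the loss-of-equilibrium tension")
    loe_idx = int(below[0])
    times_h = times_h[: loe_idx + 1]
    conc = conc[: loe_idx + 1]

    o2 = conc.copy()
    if scenario.noise_sd > 0:
        o2 = o2 + rng.normal(0.0, scenario.noise_sd, size=o2.size)
    o2 = np.maximum(o2, 0.0)

    meta = _base_meta(truth, protocol, scenario)
    meta["trace_kind"] = "closed"
    meta["loe_index"] = loe_idx
    meta["loe_time_s"] = float(times_h[loe_idx] * 3600.0)
    df = pd.DataFrame(
        {
            "time_s": times_h * 3600.0,
            "o2_mgL": o2,
            "temp_C": scenario.temperature_c,
            "phase": PHASE_CLOSED,
            "cycle_index": -1,
        }
    )
    return OxygenTrace(data=df, meta=meta)


def draw_fish_truth(
    rng: np.random.Generator, background: BackgroundModel | None = None
) -> FishTruth:
    """Draw one fish's ground truth from the cohort distributions.

    Juvenile fish of ~1.5 g and ~55 mm (condition factor near 1), standard
    metabolic rate around 250 mg O2 kg^-1 h^-1 with maximum rate a factor
    ~2.8 above it, critical tension around 6 kPa and loss of equilibrium at
    35-55% of the critical tension.
    """
    mass_g = 1.5 * np.exp(rng.normal(0.0, 0.10))
    k = np.clip(rng.normal(0.90, 0.05), 0.7, 1.1)
    length_cm = (100.0 * mass_g / k) ** (1.0 / 3.0)
    smr = float(np.clip(rng.normal(250.0, 30.0), 150.0, 400.0))
    mmr = smr * float(np.clip(rng.normal(2.8, 0.3), 1.5, 4.0))
    pcrit = float(np.clip(rng.normal(6.0, 0.8), 3.5, 9.5))
    loe = pcrit * rng.uniform(0.35, 0.55)
    halflife = float(np.clip(rng.normal(2.0, 0.3), 1.0, 3.5))
    bg = background.daily_blank_slopes[0] if background else 0.0
    return FishTruth(
        body_mass_kg=mass_g / 1000.0,
        body_length_cm=float(length_cm),
        smr=smr,
        mmr=mmr,
        pcrit_kpa=pcrit,
        loe_po2_kpa=float(loe),
        recovery_halflife_h=halflife,
        background_slope=float(bg),
    )


@dataclass
class CohortFish:
    fish_id: str
    truth: FishTruth
    intermittent: OxygenTrace
    closed: OxygenTrace


@dataclass
class Cohort:
    scenario: ScenarioConfig
    protocol: ProtocolConfig
    background: BackgroundModel
    fish: list = field(default_factory=list)

    @property
    def manifest(self) -> dict:
        from dataclasses import asdict

        return {
            "scenario": asdict(self.scenario),
            "protocol": asdict(self.protocol),
            "background": {
                "daily_blank_slopes": list(self.background.daily_blank_slopes),
                "drift": self.background.drift,
            },
            "fish": [
                {"fish_id": f.fish_id, "truth": asdict(f.truth)} for f in self.fish
            ],
        }


def simulate_cohort(
    scenario: ScenarioConfig,
    protocol: ProtocolConfig | None = None,
    background: BackgroundModel | None = None,
    include_closed: bool = True,
) -> Cohort:
    """Simulate ``scenario.n_fish`` fish: truths, traces and a manifest.

    Per-fish random substreams are spawned deterministically from the
    scenario seed, so a fixed seed reproduces the cohort exactly.
    """
    protocol = protocol or ProtocolConfig()
    background = background or BackgroundModel()
    cohort = Cohort(scenario=scenario, protocol=protocol, background=background)

    streams = np.random.SeedSequence(scenario.seed).spawn(max(scenario.n_fish, 1))
    for i in range(scenario.n_fish):
        sub = streams[i].spawn(3)
        truth = draw_fish_truth(np.random.default_rng(sub[0]), background)
        inter = simulate_intermittent_trace(
            truth, protocol, background, scenario, rng=np.random.default_rng(sub[1])
        )
        closed = (
            simulate_closed_phase(
                truth, protocol, scenario, rng=np.random.default_rng(sub[2])
            )
            if include_closed
            else None
        )
        cohort.fish.append(
            CohortFish(fish_id=f"fish{i:03d}", truth=truth, intermittent=inter, closed=closed)
        )
    return cohort
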