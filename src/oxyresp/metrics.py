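"""Per-fish metabolic summaries: SMR, MMR, aerobic scope, condition factor.

SMR is the mean of the lowest 10% of QC-passing determination cycles
(excluding the post-chase cycle); MMR is the uptake of the first
determination after the exhaustive chase; absolute aerobic scope is their
difference. Fulton's condition factor K = 100 W / L^3 (W in g, L in cm)
summarises body condition, scaled so typical fish sit near 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mo2 import Mo2Record

__all__ = [
    "MetabolicSummary",
    "estimate_smr",
    "estimate_mmr",
    "aerobic_scope",
    "fulton_k",
    "summarize_fish",
]


@dataclass
class MetabolicSummary:
    smr: float
    mmr: float
    aas: float
    n_cycles_used: int
    n_smr_cycles: int
    fulton_k: float | None = None
    body_mass_g: float | None = None
    body_length_cm: float | None = None
    flags: set = field(default_factory=set)


def smr_pool_size(n: int) -> int:
    """Number of cycles entering the lowest-10% mean: ceil(0.10 n), min 1."""
    return max(1, math.ceil(0.10 * n))


def estimate_smr(values) -> float:
    """Standard metabolic rate: mean of the lowest 10% of measurements.

    `values` are corrected, QC-passing, non-MMR cycle uptakes in
    determination order. Exactly ceil(0.10 n) order statistics are averaged
    (at least one); ties at the cutoff are resolved by stable cycle order.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no eligible cycles")
    k = smr_pool_size(values.size)
    order = np.argsort(values, kind="stable")
    return float(values[order[:k]].mean())


def estimate_mmr(records: list[Mo2Record]) -> tuple[float, set]:
    """Maximum metabolic rate: the post-chase first-determination uptake.

    Returns (MMR, flags); if the MMR cycle itself failed QC its value is
    still reported, flagged ``mmr_qc``.
    """
    mmr_records = [r for r in records if r.is_mmr_cycle]
    if not mmr_records:
        raise ValueError("no post-chase (MMR) cycle present")
    rec = mmr_records[0]
    flags = {"mmr_qc"} if rec.qc_flags else set()
    return rec.value, flags


def aerobic_scope(smr: float, mmr: float) -> tuple[float, set]:
    """Absolute aerobic scope MMR - SMR; negative values are flagged."""
    if not (math.isfinite(smr) and math.isfinite(mmr)):
        raise ValueError("SMR and MMR must be finite")
    aas = mmr - smr
    return aas, ({"negative_scope"} if aas < 0 else set())


def fulton_k(weight_g: float, length_cm: float) -> float:
    """Fulton's condition factor K = 100 W / L^3 (W in g, L in cm)."""
    if weight_g <= 0 or length_cm <= 0:
        raise ValueError("weight and length must be > 0")
    return 100.0 * weight_g / length_cm**3


def summarize_fish(
    records: list[Mo2Record],
    body_mass_g: float | None = None,
    body_length_cm: float | None = None,
    settle_exclude_h: float = 0.0,
) -> MetabolicSummary:
    """Full per-fish summary from a corrected, QC-flagged cycle table.

    `settle_exclude_h` optionally removes an initial settling window from
    the SMR pool (default: no exclusion beyond the post-chase cycle).
    """
    eligible = [
        r
        for r in records
        if r.passes_qc and not r.is_mmr_cycle and r.start_h >= settle_exclude_h
    ]
    if not eligible:
        raise ValueError("no eligible cycles")
    smr = estimate_smr([r.value for r in eligible])
    mmr, flags = estimate_mmr(records)
    aas, aas_flags = aerobic_scope(smr, mmr)
    flags = flags | aas_flags

    k = None
    if body_mass_g is not None and body_length_cm is not None:
        k = fulton_k(body_mass_g, body_length_cm)

    return MetabolicSummary(
        smr=smr,
        mmr=mmr,
        aas=aas,
        n_cycles_used=len(eligible),
        n_smr_cycles=smr_pool_size(len(eligible)),
        fulton_k=k,
        body_mass_g=body_mass_g,
        body_length_cm=body_length_cm,
        flags=flags,
    )
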