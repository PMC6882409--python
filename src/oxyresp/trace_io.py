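"""Oxygen-trace containers, delimited-text I/O and cycle segmentation.

A trace is the time series logged by one chamber's fibre-optic oxygen probe:
time, dissolved O2, temperature, plus phase annotations (determination /
flush / closed). Traces round-trip through a plain CSV dialect with a
``# key=value`` metadata header, one file per fish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ProtocolConfig

__all__ = [
    "OxygenTrace",
    "DeterminationCycle",
    "TraceParseError",
    "read_trace",
    "write_trace",
    "segment_cycles",
]

PHASE_DETERMINATION = "determination"
PHASE_FLUSH = "flush"
PHASE_CLOSED = "closed"

_DEFAULT_COLUMNS = {
    "time": "time_s",
    "o2": "o2_mgL",
    "temperature": "temp_C",
    "phase": "phase",
    "cycle": "cycle_index",
}


class TraceParseError(ValueError):
    """Raised when a trace file fails validation; message carries line numbers."""


@dataclass
class OxygenTrace:
    """One chamber's logged oxygen time series plus fish/chamber metadata.

    `data` columns: time_s (strictly increasing, seconds from trace start),
    o2_mgL (>= 0), temp_C, phase, cycle_index. `meta` carries chamber id,
    fish body mass (kg) and length (cm), chamber volume (L), barometric
    pressure (kPa) and event annotations such as ``loe_time_s``.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"time_s", "o2_mgL", "temp_C", "phase"}
        missing = required - set(self.data.columns)
        if missing:
            raise TraceParseError(f"missing columns: {sorted(missing)}")
        if len(self.data) == 0:
            raise TraceParseError("no samples")
        t = self.data["time_s"].to_numpy(float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise TraceParseError(
                f"time not strictly increasing at sample {bad[0] + 2}"
            )
        if np.any(self.data["o2_mgL"].to_numpy(float) < 0):
            i = int(np.argmax(self.data["o2_mgL"].to_numpy(float) < 0))
            raise TraceParseError(f"negative O2 at sample {i + 1}")

    @property
    def time_s(self) -> np.ndarray:
        return self.data["time_s"].to_numpy(float)

    @property
    def o2_mgl(self) -> np.ndarray:
        return self.data["o2_mgL"].to_numpy(float)

    @property
    def temperature_c(self) -> float:
        return float(self.data["temp_C"].iloc[0])

    def phases(self) -> np.ndarray:
        return self.data["phase"].to_numpy()


@dataclass(frozen=True)
class DeterminationCycle:
    """One sealed measurement window within an intermittent-flow trace."""

    index: int
    start_s: float
    end_s: float
    start_idx: int
    end_idx: int  # half-open [start_idx, end_idx)
    is_mmr_cycle: bool = False
    is_background_blank: bool = False

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def samples(self, trace: OxygenTrace) -> pd.DataFrame:
        return trace.data.iloc[self.start_idx : self.end_idx]


def write_trace(trace: OxygenTrace, path) -> None:
    """Write a trace as CSV with a ``# key=value`` metadata header."""
    with open(path, "w") as fh:
        for key, value in sorted(trace.meta.items()):
            fh.write(f"# {key}={value}\n")
        trace.data.to_csv(fh, index=False)


def read_trace(path, columns: dict | None = None) -> OxygenTrace:
    """Read a delimited trace file, validating time order and O2 sign.

    `columns` optionally maps the logical names time/o2/temperature/phase/
    cycle to the file's header names (default: the simulator dialect
    time_s, o2_mgL, temp_C, phase, cycle_index).
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)

    meta: dict = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = _coerce(value.strip())

    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise TraceParseError(f"{path}: no samples") from None
    if len(df) == 0:
        raise TraceParseError(f"{path}: no samples")

    missing = [v for k, v in colmap.items() if k in ("time", "o2", "temperature") and v not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing columns: {missing}")

    out = pd.DataFrame(
        {
            "time_s": df[colmap["time"]].astype(float),
            "o2_mgL": df[colmap["o2"]].astype(float),
            "temp_C": df[colmap["temperature"]].astype(float),
        }
    )
    out["phase"] = df[colmap["phase"]] if colmap["phase"] in df.columns else PHASE_CLOSED
    if colmap["cycle"] in df.columns:
        out["cycle_index"] = df[colmap["cycle"]].astype(int)

    # data rows start after metadata header + the CSV header line
    first_data_line = header_lines + 2
    t = out["time_s"].to_numpy()
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise TraceParseError(
            f"{path}: time not increasing at line {first_data_line + int(bad[0]) + 1}"
        )
    neg = np.nonzero(out["o2_mgL"].to_numpy() < 0)[0]
    if neg.size:
        raise TraceParseError(
            f"{path}: negative O2 at line {first_data_line + int(neg[0])}"
        )
    return OxygenTrace(data=out, meta=meta)


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def segment_cycles(
    trace: OxygenTrace,
    protocol: ProtocolConfig,
    use_labels: bool | None = None,
    duration_tolerance: float = 0.25,
) -> list[DeterminationCycle]:
    """Split an intermittent-flow trace into ordered determination cycles.

    With phase labels present (the normal case) contiguous runs labelled
    'determination' become cycles; otherwise flush onsets are detected as
    sustained O2 increases exceeding 3x the local noise level. Cycles whose
    duration deviates from the nominal determination length by more than
    `duration_tolerance` (fraction) are dropped (truncated tail cycles).
    The first determination is flagged as the post-chase MMR cycle.
    """
    phases = trace.phases()
    if use_labels is None:
        use_labels = bool(np.isin(phases, [PHASE_DETERMINATION, PHASE_FLUSH]).any())

    if use_labels:
        runs = _runs_of(phases == PHASE_DETERMINATION)
    else:
        runs = _detect_determinations(trace, protocol)

    nominal = protocol.determination_minutes * 60.0
    t = trace.time_s
    cycles: list[DeterminationCycle] = []
    for start_idx, end_idx in runs:
        start_s = float(t[start_idx])
        end_s = float(t[end_idx - 1]) + protocol.sample_interval_s
        if abs((end_s - start_s) - nominal) > duration_tolerance * nominal:
            continue
        cycles.append(
            DeterminationCycle(
                index=len(cycles),
                start_s=start_s,
                end_s=end_s,
                start_idx=int(start_idx),
                end_idx=int(end_idx),
                is_mmr_cycle=False,
                is_background_blank=bool(trace.meta.get("is_blank", False)),
            )
        )
    if cycles:
        cycles[0] = DeterminationCycle(
            **{**cycles[0].__dict__, "is_mmr_cycle": not cycles[0].is_background_blank}
        )
    return cycles


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs where mask is True."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def _detect_determinations(
    trace: OxygenTrace, protocol: ProtocolConfig
) -> list[tuple[int, int]]:
    """Label-free segmentation: flushes show as sustained O2 upticks.

    The rise over a ~60 s window is compared with 3x the sample noise sd
    (robustly estimated from first differences); windows exceeding the
    threshold are flush phases, the gaps between them determinations.
    """
    o2 = trace.o2_mgl
    dt = float(np.median(np.diff(trace.time_s)))
    w = max(3, int(round(60.0 / dt)))
    if o2.size <= w:
        return []

    d = np.diff(o2)
    noise_sd = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
    rise = o2[w:] - o2[:-w]
    threshold = max(3.0 * noise_sd * np.sqrt(2.0), 1e-9)
    flushing = np.zeros(o2.size, dtype=bool)
    for start, end in _runs_of(rise > threshold):
        flushing[start : end + w] = True

    if not flushing.any():
        return []
    return _runs_of(~flushing)
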