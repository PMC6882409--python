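"""Critical oxygen tension by two-segment regression; loss of equilibrium.

The closed-respirometry trace is reduced to (PO2, Mo2) points by fitting
depletion slopes in consecutive fixed-duration bins (default 2 min) and
converting each through the chamber scaling. A continuous two-segment
piecewise-linear model is then fitted by least squares:

    Mo2 = b0 + b1 * PO2 + b2 * (PO2 - psi)_+

so the two lines meet at the breakpoint psi. The breakpoint minimising the
sum of squared errors — searched over a grid at the data's PO2 resolution
and refined by bounded scalar minimisation — is the critical tension
P_crit: the intersection of the oxy-conforming line (below) with the
oxy-regulating line (above). An alternative estimator reports where the
conforming line crosses the fish's standard metabolic rate. Uncertainty
comes from a case-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .trace_io import OxygenTrace
from .units import WaterConditions, mgL_to_kPa

__all__ = [
    "PcritFit",
    "LoeRecord",
    "closed_phase_mo2",
    "fit_segmented",
    "pcrit_smr_crossing",
    "bootstrap_ci",
    "detect_loe",
]

#: Breakpoint search window as percentiles of observed PO2 (edge guard).
SEARCH_PERCENTILES = (5.0, 95.0)


@dataclass
class PcritFit:
    """Two-segment regression result; `breakpoint_kpa` is the P_crit."""

    breakpoint_kpa: float | None
    conforming_slope: float | None
    conforming_intercept: float | None
    regulating_slope: float | None
    regulating_intercept: float | None
    sse_segmented: float
    sse_single_line: float
    n_points: int
    method: str = "grid"
    degenerate: bool = False
    ci_low: float | None = None
    ci_high: float | None = None
    flags: set = field(default_factory=set)


@dataclass(frozen=True)
class LoeRecord:
    """Loss-of-equilibrium endpoint: recorded O2, its tension, elapsed time."""

    loe_o2_mgl: float
    loe_po2_kpa: float
    time_to_loe_min: float


def _conditions_from_meta(meta: dict) -> WaterConditions:
    return WaterConditions(
        temperature=float(meta["temperature_c"]),
        barometric_pressure=float(meta.get("barometric_pressure_kpa", 101.325)),
    )


def closed_phase_mo2(
    trace: OxygenTrace,
    bin_minutes: float = 2.0,
    cond: WaterConditions | None = None,
    min_bin_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce a closed-phase trace to (PO2 kPa, Mo2 mg kg^-1 h^-1) points.

    Consecutive `bin_minutes` windows each get an OLS depletion slope; the
    slope converts to uptake via effective volume and body mass, and the
    bin's PO2 is the fitted line's midpoint concentration converted through
    the solubility model. Requires at least 30 samples. Bins holding fewer
    than `min_bin_fraction` of a full bin's samples (the truncated tail at
    loss of equilibrium) are dropped — a near-empty bin's slope has a far
    larger sampling variance than the rest and would dominate the fit.
    """
    t = trace.time_s
    o2 = trace.o2_mgl
    if t.size < 30:
        raise ValueError("closed-phase trace too short (< 30 samples)")
    if cond is None:
        cond = _conditions_from_meta(trace.meta)

    body_mass = float(trace.meta["body_mass_kg"])
    v_eff = float(trace.meta["chamber_volume_l"]) - body_mass

    bin_s = bin_minutes * 60.0
    dt = float(np.median(np.diff(t))) if t.size > 1 else bin_s
    min_samples = max(3, min(int(np.ceil(min_bin_fraction * bin_s / dt)), t.size))
    edges = np.arange(t[0], t[-1] + bin_s, bin_s)
    po2_pts, mo2_pts = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (t >= lo) & (t < hi)
        if mask.sum() < min_samples:
            continue
        tb = (t[mask] - lo) / 3600.0
        fit = stats.linregress(tb, o2[mask]) if np.ptp(o2[mask]) > 0 else None
        if fit is None:
            slope, mid_conc = 0.0, float(o2[mask][0])
        else:
            slope = float(fit.slope)
            mid_conc = float(fit.intercept + slope * tb.mean())
        if mid_conc < 0:
            continue
        mo2_pts.append(-slope * v_eff / body_mass)
        po2_pts.append(mgL_to_kPa(mid_conc, cond))
    return np.asarray(po2_pts), np.asarray(mo2_pts)


def _segmented_sse(x: np.ndarray, y: np.ndarray, psis: np.ndarray):
    """SSE and coefficients of the hinge model for each candidate breakpoint.

    Solves the 3x3 normal equations of y ~ 1 + x + (x - psi)_+ for a whole
    vector of candidates at once (y is mean-centred for conditioning).
    """
    psis = np.atleast_1d(np.asarray(psis, dtype=float))
    n = x.size
    ybar = y.mean()
    yc = y - ybar
    u = np.clip(x[None, :] - psis[:, None], 0.0, None)

    sx, sxx = x.sum(), x @ x
    sy, sxy, syy = yc.sum(), x @ yc, yc @ yc
    su = u.sum(axis=1)
    sxu = u @ x
    suu = np.einsum("ij,ij->i", u, u)
    suy = u @ yc

    m = psis.size
    a = np.empty((m, 3, 3))
    a[:, 0, 0] = n
    a[:, 0, 1] = a[:, 1, 0] = sx
    a[:, 0, 2] = a[:, 2, 0] = su
    a[:, 1, 1] = sxx
    a[:, 1, 2] = a[:, 2, 1] = sxu
    a[:, 2, 2] = suu
    b = np.stack([np.full(m, sy), np.full(m, sxy), suy], axis=1)

    try:
        beta = np.linalg.solve(a, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.linalg.pinv(a) @ b[..., None]
        beta = beta[..., 0]
    sse = np.clip(syy - np.einsum("ij,ij->i", beta, b), 0.0, None)
    beta = beta.copy()
    beta[:, 0] += ybar  # undo the centring
    return sse, beta


def _single_line_sse(x: np.ndarray, y: np.ndarray) -> float:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return float(resid @ resid)


def fit_segmented(
    po2: np.ndarray,
    mo2: np.ndarray,
    search_bounds: tuple[float, float] | None = None,
    n_grid: int = 101,
    refine: bool = True,
) -> PcritFit:
    """Continuous two-segment least-squares fit of Mo2 against PO2.

    Candidate breakpoints are the observed PO2 values inside the search
    window (default the 5th-95th percentile of the data) augmented with a
    uniform grid; the best candidates are refined by bounded scalar
    minimisation. Ties go to the smallest breakpoint. Collinear data yield
    a degenerate single-line fit with no breakpoint.
    """
    x = np.asarray(po2, dtype=float)
    y = np.asarray(mo2, dtype=float)
    if x.size != y.size:
        raise ValueError("po2 and mo2 must have equal length")
    if x.size < 6:
        raise ValueError("need at least 6 points for a segmented fit")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]

    sse_single = _single_line_sse(x, y)
    total_ss = float(((y - y.mean()) ** 2).sum())
    if total_ss == 0.0 or sse_single <= 1e-10 * total_ss:
        slope, intercept = np.polyfit(x, y, 1)
        return PcritFit(
            breakpoint_kpa=None,
            conforming_slope=float(slope),
            conforming_intercept=float(intercept),
            regulating_slope=float(slope),
            regulating_intercept=float(intercept),
            sse_segmented=sse_single,
            sse_single_line=sse_single,
            n_points=x.size,
            degenerate=True,
            flags={"collinear"},
        )

    if search_bounds is None:
        lo, hi = np.percentile(x, SEARCH_PERCENTILES)
    else:
        lo, hi = search_bounds
    # keep at least two points on each side of any candidate
    lo = max(lo, x[1])
    hi = min(hi, x[-2])
    if not lo < hi:
        lo, hi = x[1], x[-2]

    candidates = np.unique(
        np.concatenate([x[(x >= lo) & (x <= hi)], np.linspace(lo, hi, n_grid)])
    )
    sse, _ = _segmented_sse(x, y, candidates)

    best_psi = float(candidates[int(np.argmin(sse))])
    best_sse = float(sse.min())

    if refine:
        # refine around the few best local candidates; the SSE profile has
        # kinks at the data points, so each bracket is searched separately
        top = np.argsort(sse, kind="stable")[:3]
        for j in sorted(set(int(i) for i in top)):
            blo = candidates[max(j - 1, 0)]
            bhi = candidates[min(j + 1, candidates.size - 1)]
            if bhi - blo <= 0:
                continue
            res = optimize.minimize_scalar(
                lambda p: float(_segmented_sse(x, y, np.array([p]))[0][0]),
                bounds=(float(blo), float(bhi)),
                method="bounded",
                options={"xatol": 1e-7},
            )
            if res.fun < best_sse - 1e-12 or (
                abs(res.fun - best_sse) <= 1e-12 and res.x < best_psi
            ):
                best_sse, best_psi = float(res.fun), float(res.x)

    _, beta = _segmented_sse(x, y, np.array([best_psi]))
    b0, b1, b2 = beta[0]
    return PcritFit(
        breakpoint_kpa=best_psi,
        conforming_slope=float(b1),
        conforming_intercept=float(b0),
        regulating_slope=float(b1 + b2),
        regulating_intercept=float(b0 - b2 * best_psi),
        sse_segmented=best_sse,
        sse_single_line=sse_single,
        n_points=x.size,
        method="grid",
    )


def pcrit_smr_crossing(fit: PcritFit, smr: float) -> tuple[float | None, set]:
    """PO2 where the fitted conforming segment reaches the SMR level.

    Alternative P_crit estimator, reported alongside the breakpoint. Returns
    (PO2 kPa or None, flags); undefined when the conforming slope is not
    positive, flagged when SMR exceeds the regulating plateau.
    """
    flags: set = set()
    if fit.degenerate or fit.breakpoint_kpa is None:
        return None, {"degenerate_fit"}
    if fit.conforming_slope is None or fit.conforming_slope <= 0:
        return None, {"nonpositive_conforming_slope"}
    plateau = fit.conforming_intercept + fit.conforming_slope * fit.breakpoint_kpa
    if smr > plateau + 1e-3 * max(abs(plateau), 1.0):
        flags.add("smr_above_plateau")
    crossing = (smr - fit.conforming_intercept) / fit.conforming_slope
    return float(crossing), flags


def bootstrap_ci(
    po2: np.ndarray,
    mo2: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
    confidence: float = 0.95,
    **fit_kwargs,
) -> tuple[float, float, int]:
    """Percentile bootstrap CI for the breakpoint via case resampling.

    Returns (ci_low, ci_high, n_degenerate); degenerate refits (collinear
    resamples) are counted and excluded from the percentiles. Refits use
    the grid stage only by default — sub-grid refinement is far below the
    resampling spread of the breakpoint and would triple the cost.
    """
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    fit_kwargs.setdefault("refine", False)
    x = np.asarray(po2, dtype=float)
    y = np.asarray(mo2, dtype=float)
    rng = np.random.default_rng(seed)
    estimates = []
    n_degenerate = 0
    for _ in range(n_boot):
        idx = rng.integers(0, x.size, size=x.size)
        try:
            refit = fit_segmented(x[idx], y[idx], **fit_kwargs)
        except ValueError:
            n_degenerate += 1
            continue
        if refit.degenerate or refit.breakpoint_kpa is None:
            n_degenerate += 1
            continue
        estimates.append(refit.breakpoint_kpa)
    if not estimates:
        raise ValueError("all bootstrap refits were degenerate")
    alpha = (1.0 - confidence) / 2.0
    lo, hi = np.percentile(estimates, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi), n_degenerate


def detect_loe(
    trace: OxygenTrace,
    cond: WaterConditions | None = None,
    loe_time_s: float | None = None,
) -> LoeRecord:
    """Extract the loss-of-equilibrium record from an annotated closed trace.

    The event sample comes from ``meta['loe_index']`` (set by the simulator
    or a manual annotation) or from a supplied event time; the recorded O2
    concentration at that sample is converted to a tension at the trace
    temperature.
    """
    t = trace.time_s
    if loe_time_s is not None:
        idx = int(np.argmin(np.abs(t - loe_time_s)))
    elif "loe_index" in trace.meta:
        idx = int(trace.meta["loe_index"])
    else:
        raise ValueError("no loss-of-equilibrium event annotated or supplied")
    if cond is None:
        cond = _conditions_from_meta(trace.meta)
    loe_o2 = float(trace.o2_mgl[idx])
    return LoeRecord(
        loe_o2_mgl=loe_o2,
        loe_po2_kpa=mgL_to_kPa(loe_o2, cond),
        time_to_loe_min=float((t[idx] - t[0]) / 60.0),
    )
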