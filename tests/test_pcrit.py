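"""Segmented-regression P_crit, SMR-crossing estimator, bootstrap, LOE."""

import numpy as np
import pytest

import oxyresp as ox
from oxyresp.pcrit import PcritFit, _segmented_sse


def _piecewise(x, bp=5.0, conf_slope=10.0, plateau=None):
    plateau = conf_slope * bp if plateau is None else plateau
    return np.where(x < bp, conf_slope * x, plateau)


class TestFitSegmented:
    def test_exact_piecewise_data_recovers_breakpoint_and_slopes(self):
        x = np.linspace(1.0, 10.0, 40)
        y = _piecewise(x, bp=5.0, conf_slope=10.0)
        fit = ox.fit_segmented(x, y, search_bounds=(2.0, 9.0))
        assert fit.breakpoint_kpa == pytest.approx(5.0, abs=1e-5)
        assert fit.conforming_slope == pytest.approx(10.0, abs=1e-6)
        assert fit.regulating_slope == pytest.approx(0.0, abs=1e-6)
        assert fit.sse_segmented <= fit.sse_single_line + 1e-9

    def test_straight_line_is_degenerate(self):
        x = np.linspace(1.0, 10.0, 30)
        fit = ox.fit_segmented(x, 2.0 * x + 1.0)
        assert fit.degenerate
        assert fit.breakpoint_kpa is None
        assert "collinear" in fit.flags

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="6 points"):
            ox.fit_segmented(np.arange(5.0), np.arange(5.0) ** 2)

    def test_segmented_sse_never_exceeds_single_line(self, rng):
        for _ in range(25):
            x = np.sort(rng.uniform(1.0, 15.0, 30))
            y = _piecewise(x, bp=6.0, conf_slope=40.0) + rng.normal(0, 15.0, 30)
            fit = ox.fit_segmented(x, y)
            assert fit.sse_segmented <= fit.sse_single_line + 1e-9

    def test_breakpoint_shift_equivariance(self, rng):
        x = np.sort(rng.uniform(1.0, 12.0, 50))
        y = _piecewise(x, bp=6.0, conf_slope=40.0) + rng.normal(0, 10.0, 50)
        base = ox.fit_segmented(x, y)
        shifted = ox.fit_segmented(x + 3.0, y)
        assert shifted.breakpoint_kpa == pytest.approx(
            base.breakpoint_kpa + 3.0, abs=1e-6
        )

    def test_breakpoint_response_scale_invariance(self, rng):
        x = np.sort(rng.uniform(1.0, 12.0, 50))
        y = _piecewise(x, bp=6.0, conf_slope=40.0) + rng.normal(0, 10.0, 50)
        base = ox.fit_segmented(x, y)
        scaled = ox.fit_segmented(x, 3.5 * y)
        assert scaled.breakpoint_kpa == pytest.approx(base.breakpoint_kpa, abs=1e-6)

    def test_tie_break_prefers_smallest_breakpoint(self):
        # symmetric V shape: psi anywhere in the flat centre fits equally
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        y = np.abs(x - 4.5)
        fit = ox.fit_segmented(x, y, search_bounds=(2.0, 7.0), refine=False)
        assert fit.breakpoint_kpa <= 4.5 + 1e-9

    def test_matches_exhaustive_search_on_noisy_data(self, rng):
        """Grid + refinement equals brute force at 1e-3 resolution."""
        for seed in range(1, 11):
            r = np.random.default_rng(seed)
            x = np.sort(r.uniform(2.0, 16.0, 40))
            y = _piecewise(x, bp=6.0, conf_slope=40.0) + r.normal(0, 10.0, 40)
            fit = ox.fit_segmented(x, y)
            lo, hi = np.percentile(x, [5, 95])
            best_sse, best_psi = np.inf, None
            for psi in np.arange(lo, hi, 0.001):
                design = np.column_stack(
                    [np.ones_like(x), x, np.clip(x - psi, 0.0, None)]
                )
                beta, *_ = np.linalg.lstsq(design, y, rcond=None)
                resid = y - design @ beta
                sse = float(resid @ resid)
                if sse < best_sse:
                    best_sse, best_psi = sse, psi
            assert fit.breakpoint_kpa == pytest.approx(best_psi, abs=0.01)


class TestClosedPhasePoints:
    def test_noiseless_points_lie_on_the_two_regime_lines(self, protocol_5s):
        truth = ox.FishTruth(pcrit_kpa=6.0, loe_po2_kpa=1.5, smr=250.0)
        scen = ox.ScenarioConfig(noise_sd=0.0, seed=3)
        trace = ox.simulate_closed_phase(truth, protocol_5s, scen)
        po2, mo2 = ox.closed_phase_mo2(trace)
        margin = 0.3  # skip the bin straddling the breakpoint
        above = po2 > truth.pcrit_kpa + margin
        below = po2 < truth.pcrit_kpa - margin
        assert np.allclose(mo2[above], truth.smr, rtol=1e-6)
        assert np.allclose(
            mo2[below], truth.smr * po2[below] / truth.pcrit_kpa, rtol=5e-3
        )

    def test_full_trace_bin_gives_single_point(self, protocol_5s):
        truth = ox.FishTruth()
        scen = ox.ScenarioConfig(noise_sd=0.0, seed=3)
        trace = ox.simulate_closed_phase(truth, protocol_5s, scen)
        hours = trace.time_s[-1] / 3600.0
        po2, mo2 = ox.closed_phase_mo2(trace, bin_minutes=2 * 60.0 * hours)
        assert po2.size == 1

    def test_short_trace_rejected(self, protocol_5s):
        truth = ox.FishTruth()
        scen = ox.ScenarioConfig(noise_sd=0.0, seed=3)
        trace = ox.simulate_closed_phase(truth, protocol_5s, scen)
        trace.data = trace.data.iloc[:10]
        with pytest.raises(ValueError, match="short"):
            ox.closed_phase_mo2(trace)

    def test_end_to_end_breakpoint_recovers_truth(self, protocol_5s):
        truth = ox.FishTruth(pcrit_kpa=6.0, loe_po2_kpa=1.5)
        scen = ox.ScenarioConfig(noise_sd=0.0, seed=3)
        trace = ox.simulate_closed_phase(truth, protocol_5s, scen)
        po2, mo2 = ox.closed_phase_mo2(trace)
        fit = ox.fit_segmented(po2, mo2)
        assert fit.breakpoint_kpa == pytest.approx(truth.pcrit_kpa, abs=0.05)


class TestSmrCrossing:
    def _fit(self, bp=5.0, conf_slope=10.0):
        x = np.linspace(1.0, 10.0, 60)
        y = _piecewise(x, bp=bp, conf_slope=conf_slope)
        return ox.fit_segmented(x, y, search_bounds=(2.0, 9.0))

    def test_simple_crossing(self):
        fit = self._fit(bp=5.0, conf_slope=10.0)
        crossing, flags = ox.pcrit_smr_crossing(fit, smr=50.0)
        assert crossing == pytest.approx(5.0, abs=1e-4)
        assert flags == set()

    def test_smr_above_plateau_flagged(self):
        fit = self._fit(bp=5.0, conf_slope=10.0)
        crossing, flags = ox.pcrit_smr_crossing(fit, smr=80.0)
        assert "smr_above_plateau" in flags

    def test_estimators_agree_when_plateau_equals_smr(self, protocol_5s):
        truth = ox.FishTruth(pcrit_kpa=6.0, loe_po2_kpa=1.5)
        scen = ox.ScenarioConfig(noise_sd=0.0, seed=3)
        trace = ox.simulate_closed_phase(truth, protocol_5s, scen)
        po2, mo2 = ox.closed_phase_mo2(trace)
        fit = ox.fit_segmented(po2, mo2)
        crossing, _ = ox.pcrit_smr_crossing(fit, smr=truth.smr)
        assert crossing == pytest.approx(fit.breakpoint_kpa, abs=0.05)

    def test_degenerate_fit_propagates(self):
        x = np.linspace(1.0, 10.0, 30)
        fit = ox.fit_segmented(x, 2.0 * x)
        crossing, flags = ox.pcrit_smr_crossing(fit, smr=10.0)
        assert crossing is None and "degenerate_fit" in flags


class TestBootstrapCi:
    def test_exact_piecewise_data_has_zero_width(self):
        x = np.linspace(1.0, 10.0, 60)
        y = _piecewise(x, bp=5.0, conf_slope=10.0)
        lo, hi, _ = ox.bootstrap_ci(x, y, n_boot=100, seed=1, refine=True)
        assert hi - lo == pytest.approx(0.0, abs=1e-4)

    def test_reproducible_for_fixed_seed(self, rng):
        x = np.sort(rng.uniform(1.0, 12.0, 60))
        y = _piecewise(x, bp=6.0, conf_slope=40.0) + rng.normal(0, 10.0, 60)
        a = ox.bootstrap_ci(x, y, n_boot=100, seed=7)
        b = ox.bootstrap_ci(x, y, n_boot=100, seed=7)
        assert a == b

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="100"):
            ox.bootstrap_ci(np.arange(10.0), np.arange(10.0), n_boot=50)


class TestDetectLoe:
    def test_recorded_concentration_passes_through(self, noiseless_fish):
        truth, _, closed = noiseless_fish
        loe = ox.detect_loe(closed)
        idx = int(closed.meta["loe_index"])
        assert loe.loe_o2_mgl == closed.o2_mgl[idx]
        assert loe.loe_po2_kpa == pytest.approx(truth.loe_po2_kpa, rel=0.01)

    def test_po2_consistent_with_unit_conversion(self, noiseless_fish):
        _, _, closed = noiseless_fish
        loe = ox.detect_loe(closed)
        cond = ox.WaterConditions(
            temperature=closed.temperature_c,
            barometric_pressure=float(closed.meta["barometric_pressure_kpa"]),
        )
        assert loe.loe_po2_kpa == pytest.approx(
            ox.mgL_to_kPa(loe.loe_o2_mgl, cond), rel=1e-12
        )

    def test_event_at_first_sample_has_zero_elapsed_time(self, noiseless_fish):
        _, _, closed = noiseless_fish
        loe = ox.detect_loe(closed, loe_time_s=0.0)
        assert loe.time_to_loe_min == 0.0

    def test_missing_event_rejected(self, noiseless_fish):
        _, inter, _ = noiseless_fish
        with pytest.raises(ValueError, match="equilibrium"):
            ox.detect_loe(inter)

    def test_loe_below_fitted_breakpoint(self, protocol_5s):
        truth = ox.FishTruth(pcrit_kpa=6.0, loe_po2_kpa=2.0)
        scen = ox.ScenarioConfig(noise_sd=0.0, seed=5)
        trace = ox.simulate_closed_phase(truth, protocol_5s, scen)
        po2, mo2 = ox.closed_phase_mo2(trace)
        fit = ox.fit_segmented(po2, mo2)
        loe = ox.detect_loe(trace)
        assert loe.loe_po2_kpa < fit.breakpoint_kpa
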