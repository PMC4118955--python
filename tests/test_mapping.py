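"""Saddle-node curves, the switch-to-two-process map, and calibration."""

from dataclasses import replace

import numpy as np
import pytest

from sleepdyn.mapping import (
    calibrate_switch_from_pr,
    fold_points,
    pr_switch_to_two_process,
    saddle_node_curve,
)
from sleepdyn.params import ParameterError
from sleepdyn.pr import firing_rate, firing_rate_slope, slow_manifold_solve


class TestSaddleNodeCurve:
    def test_fold_conditions_hold(self, pr_params):
        """Equilibrium and tangency both satisfied at each returned fold."""
        p = pr_params
        folds = fold_points(p)
        assert len(folds) == 2
        for f in folds:
            # equilibrium residuals
            assert f.V_m == pytest.approx(p.A - p.nu_mv * firing_rate(f.V_v, p), abs=1e-9)
            assert f.D_v == pytest.approx(f.V_v + p.nu_vm * firing_rate(f.V_m, p), abs=1e-9)
            # tangency: derivative condition of the reduced scalar equation
            tang = p.nu_vm * p.nu_mv * firing_rate_slope(f.V_m, p) * firing_rate_slope(f.V_v, p)
            assert tang == pytest.approx(1.0, abs=1e-9)

    def test_folds_bracket_hysteresis_and_match_brute_count_scan(self, pr_params):
        p = pr_params
        folds = fold_points(p)
        d_plus, d_minus = folds[0].D_v, folds[-1].D_v
        assert d_minus < d_plus
        # brute-force: find the 1<->3 solution-count changes on a fine grid
        grid = np.linspace(d_minus - 0.2, d_plus + 0.2, 4001)
        counts = np.array([len(slow_manifold_solve(d, p.A, p, step=0.05)) for d in grid])
        changes = np.nonzero(np.diff(counts))[0]
        assert len(changes) == 2
        lo_est = 0.5 * (grid[changes[0]] + grid[changes[0] + 1])
        hi_est = 0.5 * (grid[changes[1]] + grid[changes[1] + 1])
        half_step = 0.5 * (grid[1] - grid[0])
        assert abs(lo_est - d_minus) <= half_step + 1e-6
        assert abs(hi_est - d_plus) <= half_step + 1e-6

    def test_refined_fold_matches_bisected_count_change(self, pr_params):
        """Fold location agrees with a bisection on the solution count to 1e-6 mV."""
        p = pr_params
        d_plus = fold_points(p)[0].D_v

        def n_sols(d):
            return len(slow_manifold_solve(d, p.A, p, step=0.02))

        lo, hi = d_plus - 0.05, d_plus + 0.05
        assert n_sols(lo) == 3 and n_sols(hi) == 1
        while hi - lo > 1e-9:
            mid = 0.5 * (lo + hi)
            if n_sols(mid) == 3:
                lo = mid
            else:
                hi = mid
        assert abs(0.5 * (lo + hi) - d_plus) < 1e-6

    def test_hard_switch_has_no_folds(self, sp_human):
        assert fold_points(sp_human) == []
        curve = saddle_node_curve(sp_human, np.linspace(1.0, 3.0, 5))
        assert np.isnan(curve.D_v_plus).all() and np.isnan(curve.D_v_minus).all()

    def test_wake_fold_saturates_at_a_corner(self, pr_params):
        """The reachable VLPO drive saturates once the MA firing saturates.

        Along the wake fold, raising the MA drive initially buys several mV
        of VLPO-drive headroom per mV, but as the firing rate approaches
        its maximum the ratio collapses: far beyond the corner a very large
        MA-drive increase is needed for any further headroom.
        """
        p = pr_params
        curve = saddle_node_curve(p, np.linspace(p.A, 60.0, 120))
        ok = ~np.isnan(curve.D_v_plus)
        dvp, dm = curve.D_v_plus[ok], curve.D_m[ok]
        assert np.all(np.diff(dvp) > 0)
        # headroom is bounded by full MA inhibition of the VLPO
        assert dvp.max() < p.nu_vm * p.Q_max + 20.0
        slopes = np.gradient(dm, dvp)
        assert slopes[-1] > 5.0 * slopes[0]


class TestSwitchToTwoProcess:
    def test_drive_shift_moves_both_thresholds_equally(self, sp_human):
        tp0 = pr_switch_to_two_process(sp_human)
        tp1 = pr_switch_to_two_process(replace(sp_human, D0_v=sp_human.D0_v + 1.0))
        shift_plus = tp1.H0_plus - tp0.H0_plus
        shift_minus = tp1.H0_minus - tp0.H0_minus
        assert shift_plus == pytest.approx(-1.0 / sp_human.nu_vh, rel=1e-12)
        assert shift_minus == pytest.approx(shift_plus, rel=1e-12)
        assert tp1.threshold_gap() == pytest.approx(tp0.threshold_gap(), rel=1e-12)

    def test_gap_is_ma_inhibition_of_vlpo(self, sp_human):
        """Threshold gap equals the extra VLPO drive needed while the MA fires."""
        tp = pr_switch_to_two_process(sp_human)
        # drive needed for the VLPO to reach V_th with the MA active vs quiescent
        drive_wake = sp_human.V_th + sp_human.nu_vm * sp_human.Q_bar
        drive_sleep = sp_human.V_th
        assert tp.threshold_gap() == pytest.approx(
            (drive_wake - drive_sleep) / sp_human.nu_vh, rel=1e-12)

    def test_no_inhibition_collapses_gap(self, sp_human):
        with pytest.raises(ParameterError, match="nu_vm"):
            pr_switch_to_two_process(replace(sp_human, nu_vm=0.0))

    def test_switch_and_mapped_two_process_transitions_coincide(self, calibration):
        """Cross-simulation: the exact map reproduces transition times."""
        _, report = calibration
        diffs = np.abs(report.transition_diff_switch_vs_2p)
        assert len(diffs) >= 15
        assert diffs.max() < 2.0 / 60.0  # within the fast-relaxation timescale


class TestCalibration:
    def test_switch_rate_is_mean_wake_firing(self, calibration, pr_params):
        sp, _ = calibration
        assert sp.Q_bar < 0.1 * pr_params.Q_max
        # mean MA firing over the wake phase of the source cycle
        from sleepdyn.pr import simulate_pr

        ts, pat = simulate_pr(pr_params, t_span=(0.0, 24.0 * 10), sample_dt=0.05)
        wake = (ts.state == "wake") & (ts.t > 24.0 * 5)
        q_mean = float(ts.Q_m[wake].mean())
        assert sp.Q_bar == pytest.approx(q_mean, rel=0.15)

    def test_extrema_timing_retained(self, calibration):
        _, report = calibration
        assert len(report.extrema_time_diff) >= 10
        assert np.abs(report.extrema_time_diff).max() < 1.0 / 60.0

    def test_three_way_equivalence_within_ten_minutes(self, calibration):
        _, report = calibration
        assert report.max_transition_diff() < 10.0 / 60.0

    def test_calibration_idempotent_on_switch_model(self, sp_human):
        sp2, _ = calibrate_switch_from_pr(sp_human, discard_days=10.0, full_report=False)
        assert sp2.Q_bar == pytest.approx(sp_human.Q_bar, rel=2e-2)
        assert sp2.V_th == pytest.approx(sp_human.V_th, abs=5e-2)
        assert sp2.nu_vm == pytest.approx(sp_human.nu_vm, rel=5e-2)

    def test_shipped_defaults_match_recalibration(self, calibration, sp_human, tp_human):
        """The frozen human parameter files are reproduced by the pipeline."""
        sp, report = calibration
        assert sp.Q_bar == pytest.approx(sp_human.Q_bar, rel=1e-6)
        assert sp.V_th == pytest.approx(sp_human.V_th, abs=1e-6)
        assert sp.nu_vm == pytest.approx(sp_human.nu_vm, rel=1e-6)
        assert report.two_process.mu == pytest.approx(tp_human.mu, rel=1e-6)
        assert report.two_process.H0_plus == pytest.approx(tp_human.H0_plus, abs=1e-6)
        assert report.two_process.H0_minus == pytest.approx(tp_human.H0_minus, abs=1e-6)

    def test_monotone_wake_response_to_drive(self, sp_human):
        """More VLPO drive lowers both thresholds: strictly less daily wake."""
        from sleepdyn.bifurcation import classify_pattern
        from sleepdyn.twoprocess import simulate_two_process

        wakes = []
        for d0 in (sp_human.D0_v - 1.0, sp_human.D0_v, sp_human.D0_v + 1.0):
            tp = pr_switch_to_two_process(replace(sp_human, D0_v=d0))
            _, pat = simulate_two_process(tp, H_init=0.5 * (tp.H0_plus + tp.H0_minus),
                                          state_init="wake", t_span=(0.0, 24.0 * 45),
                                          sample_dt=None)
            s = classify_pattern(pat.after(24.0 * 25))
            assert s.converged and s.period_days == 1
            wakes.append(24.0 - s.daily_sleep_h)
        assert wakes[0] > wakes[1] > wakes[2]
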