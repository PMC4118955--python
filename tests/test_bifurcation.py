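"""Pattern classification, parameter scans and grazing bifurcations."""

from dataclasses import replace

import numpy as np
import pytest

from sleepdyn.bifurcation import (
    ScanSpec,
    classify_pattern,
    find_period2_window,
    locate_grazing,
    scan_parameter,
)
from sleepdyn.containers import SLEEP, WAKE
from sleepdyn.params import CircadianWaveform
from sleepdyn.twoprocess import simulate_two_process


def _converged_pattern(p, days=60, discard=30, H0=None):
    H0 = 0.5 * (p.H0_plus + p.H0_minus) if H0 is None else H0
    _, pat = simulate_two_process(p, H_init=H0, state_init=WAKE,
                                  t_span=(0.0, 24.0 * days), sample_dt=None)
    return pat.after(24.0 * discard)


class TestClassifyPattern:
    def test_monophasic_human_defaults(self, tp_human):
        s = classify_pattern(_converged_pattern(tp_human))
        assert s.converged and s.period_days == 1 and s.episodes_per_day == 1.0
        assert 6.0 < s.daily_sleep_h < 11.0

    def test_biphasic_at_reduced_chi(self, tp_human):
        """Reduced homeostatic time constant: two sleeps a day, one long one short."""
        p = replace(tp_human, chi_w=17.0, chi_s=17.0)
        pat = _converged_pattern(p)
        s = classify_pattern(pat)
        assert s.converged and s.period_days == 1 and s.episodes_per_day == 2.0
        durs = sorted(b - a for a, b in pat.sleep_intervals()[-2:])
        assert durs[0] < 0.6 * durs[1]

    def test_non_repeating_reported_unconverged(self, tp_human):
        # far too short a window to certify any period
        pat = _converged_pattern(tp_human, days=31, discard=30)
        s = classify_pattern(pat)
        assert not s.converged

    def test_sub_minute_chatter_merged(self, tp_human):
        from sleepdyn.containers import SleepWakePattern

        times = np.array([10.0, 10.005, 10.01, 20.0])
        dirs = [SLEEP, WAKE, SLEEP, WAKE]
        pat = SleepWakePattern(times, dirs, WAKE, (0.0, 48.0))
        merged = pat.merged()
        assert len(merged.times) == 2  # the 18-second wake blip is absorbed


class TestScans:
    def test_decreasing_chi_adds_episodes(self, tp_human):
        spec = ScanSpec("chi", np.linspace(45.0, 7.0, 13),
                        discard_days=30.0, classify_days=32.0)
        scan = scan_parameter(tp_human, spec)
        eps = [s.episodes_per_day for s in scan.summaries if s.converged]
        assert eps[0] == 1.0
        assert max(eps) >= 3.0
        # non-decreasing outside period-2 (and deeper adding) windows
        integer = [e for s, e in zip(scan.summaries, eps) if float(e).is_integer()]
        assert all(b >= a for a, b in zip(integer, integer[1:]))
        assert any(kind == "episode-adding" for _, _, kind in scan.critical)

    def test_drive_scan_ends_in_no_wake_and_no_sleep(self, tp_human):
        spec = ScanSpec("threshold_shift", np.linspace(-18.0, 9.0, 10),
                        discard_days=20.0, classify_days=32.0)
        with pytest.warns(UserWarning):
            scan = scan_parameter(tp_human, spec)
        assert scan.summaries[0].truncated_state == SLEEP  # no wake at low drive end
        assert scan.summaries[-1].truncated_state == WAKE  # no sleep at high drive end
        mids = [s.daily_sleep_h for s in scan.summaries if s.converged
                and s.episodes_per_day == 1.0]
        assert all(b < a for a, b in zip(mids, mids[1:]))  # monotone daily sleep
        kinds = {k for _, _, k in scan.critical}
        assert {"no-wake boundary", "no-sleep boundary"} <= kinds

    def test_boundary_cycles_exceed_a_day(self, tp_human):
        """Near the no-sleep boundary, wake episodes last more than 24 hours."""
        with pytest.warns(UserWarning, match="mu"):
            p = replace(tp_human, H0_plus=tp_human.H0_plus + 7.5,
                        H0_minus=tp_human.H0_minus + 7.5)
        pat = _converged_pattern(p, days=70, discard=30)
        s = classify_pattern(pat)
        assert s.converged and s.episodes_per_day == 0.5
        wake_durs = [b - a for a, b, st in pat.episodes() if st == WAKE]
        assert max(wake_durs) > 24.0

    def test_raster_uses_day_fold_convention(self, tp_human):
        spec = ScanSpec("chi", np.array([45.0, 30.0]), discard_days=20.0,
                        classify_days=16.0)
        scan = scan_parameter(tp_human, spec)
        for raster in scan.rasters:
            assert len(raster) > 0
            for day, onset, dur in raster:
                assert 0 <= onset < 24.0 and dur > 0 and day >= 0


class TestGrazing:
    def test_monophasic_biphasic_grazing_certified(self, tp_human):
        res = locate_grazing(tp_human, "chi", (19.0, 17.0))
        assert 17.0 < res.critical_value < 19.0
        assert res.episodes_low_side == 1.0 < res.episodes_high_side
        # certificate: trajectory comes within 1e-4 of the grazed threshold,
        # tangentially (time-derivatives of trajectory and threshold agree)
        assert res.certificate_distance < 1e-4
        assert res.certificate_slope < 1e-3
        assert res.map_discontinuity is not None  # jump crosses the diagonal

    def test_equal_episode_brackets_rejected(self, tp_human):
        with pytest.raises(ValueError, match="same episode count"):
            locate_grazing(tp_human, "chi", (45.0, 40.0),
                           discard_days=20.0, classify_days=16.0)

    def test_no_grazing_without_circadian_modulation(self, tp_human):
        """a = 0: the free-running cycle deforms smoothly under threshold shifts.

        Without circadian gating there are no tangencies: every sleep
        episode within a run has the same duration, and durations change
        continuously (no episode-adding jumps) as both thresholds move.
        """
        p0 = replace(tp_human, circadian=CircadianWaveform(amplitude=0.0))
        sleep_durs, wake_durs = [], []
        for shift in (-2.0, -1.0, 0.0, 1.0, 2.0):
            ps = replace(p0, H0_plus=p0.H0_plus + shift, H0_minus=p0.H0_minus + shift)
            pat = _converged_pattern(ps, days=50, discard=25)
            # interior episodes only (window edges truncate the first/last)
            s_d = [b - a for a, b in pat.sleep_intervals()[1:-1]]
            w_d = [b - a for a, b, st in pat.episodes()[1:-1] if st == WAKE]
            assert np.std(s_d) < 1e-9 and np.std(w_d) < 1e-9
            sleep_durs.append(s_d[0])
            wake_durs.append(w_d[0])
        # smooth, monotone deformation: higher thresholds -> longer wake,
        # shorter sleep, with no jumps of hours anywhere
        assert all(b > a for a, b in zip(wake_durs, wake_durs[1:]))
        assert all(b < a for a, b in zip(sleep_durs, sleep_durs[1:]))
        # increments change gradually: no episode-adding discontinuity
        for durs in (wake_durs, sleep_durs):
            inc = np.abs(np.diff(durs))
            assert np.all(inc[1:] < 2.0 * inc[:-1])

    def test_period_two_window_between_regimes(self, tp_human):
        """A two-day-period window separates monophasic from biphasic sleep."""
        win = find_period2_window(tp_human, (19.0, 17.0))
        assert win is not None
        lo, hi, grazing = win
        assert lo < hi
        assert hi == pytest.approx(grazing.critical_value, abs=1e-3)
        from sleepdyn.bifurcation import _episodes_at

        s = _episodes_at(tp_human, "chi", 0.5 * (lo + hi), 40.0, 16.0)
        assert s.converged and s.period_days == 2 and s.episodes_per_period == 3

    def test_two_process_and_neuronal_critical_chi_agree(self, pr_params, tp_human):
        """The monophasic-biphasic chi shift between models stays bounded.

        The mapped model holds the asymptote fixed while the neuronal model's
        effective asymptote varies with chi, shifting the bifurcation; the
        two locations agree within 15% of their mean.
        """
        res_tp = locate_grazing(tp_human, "chi", (19.0, 17.0), xtol=1e-3,
                                discard_days=30.0, classify_days=16.0, certify=False)
        res_pr = locate_grazing(pr_params, "chi", (17.0, 15.0), xtol=5e-3,
                                discard_days=20.0, classify_days=10.0, certify=False)
        a, b = res_tp.critical_value, res_pr.critical_value
        assert abs(a - b) / (0.5 * (a + b)) < 0.15
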