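"""Deprivation protocols and the two wake-effort formulations."""

from dataclasses import replace

import numpy as np
import pytest

from sleepdyn.containers import WAKE
from sleepdyn.deprivation import (
    DeprivationProtocol,
    _SlowBranches,
    deprivation_comparison,
    effort_asymmetry,
    fit_effort_relation,
    simulate_deprived,
    wake_effort_two_process,
)
from sleepdyn.twoprocess import simulate_two_process


@pytest.fixture(scope="module")
def branches(pr_params):
    return _SlowBranches(pr_params)


@pytest.fixture(scope="module")
def relation(branches, pr_params):
    return fit_effort_relation(branches.curve, pr_params)


@pytest.fixture(scope="module")
def comparison_sat(pr_params, tp_human):
    return deprivation_comparison(replace(pr_params, asymptote_form="saturating"),
                                  tp_human, days=4.0)


class TestProtocols:
    def test_interval_validation(self):
        with pytest.raises(ValueError):
            DeprivationProtocol(((10.0, 5.0),), (0.0, 24.0))
        with pytest.raises(ValueError):
            DeprivationProtocol(((0.0, 10.0), (5.0, 15.0)), (0.0, 24.0))

    def test_empty_protocol_matches_normal_simulation(self, tp_human):
        proto = DeprivationProtocol((), (0.0, 24.0 * 10))
        ts_d, pat_d = simulate_deprived(tp_human, proto, H_init=14.8, state_init=WAKE)
        ts_n, pat_n = simulate_two_process(tp_human, H_init=14.8, state_init=WAKE,
                                           t_span=(0.0, 24.0 * 10), sample_dt=0.05)
        assert np.allclose(pat_d.times, pat_n.times, atol=1e-9)
        assert np.allclose(ts_d.H, ts_n.H, atol=1e-9)

    def test_pressure_never_exceeds_asymptote(self, tp_human):
        proto = DeprivationProtocol(((24.0, 24.0 * 5),), (0.0, 24.0 * 6))
        ts, _ = simulate_deprived(tp_human, proto, H_init=14.8, state_init=WAKE)
        assert np.all(ts.H <= tp_human.mu + 1e-9)

    def test_four_day_deprivation_near_sleep_dips(self, comparison_sat):
        """Pressure rises toward the asymptote with circadian-gated near-sleep dips."""
        res = comparison_sat
        # overall envelope rises
        day_means = [res.H[(res.t - res.t[0]) // 24 == d].mean() for d in range(4)]
        assert all(b > a for a, b in zip(day_means, day_means[1:]))
        # effort returns to zero during the first day's circadian dip ...
        first_day = res.effort_pr[(res.t - res.t[0]) < 24.0]
        assert first_day.min() == 0.0
        # ... but stays clear of zero by the final day
        last_day = res.effort_pr[(res.t - res.t[0]) > 72.0]
        assert last_day.min() > 0.0

    def test_recovery_sleep_far_shorter_than_deprivation(self, tp_human):
        """Lost sleep is repaid exponentially, not hour-for-hour."""
        t_on = 23.33  # converged onset of the default cycle
        proto = DeprivationProtocol(((t_on, t_on + 96.0),), (t_on, t_on + 24.0 * 7))
        ts, pat = simulate_deprived(tp_human, proto,
                                    H_init=float(tp_human.upper_threshold(t_on)),
                                    state_init=WAKE)
        sleeps = [(a, b) for a, b in pat.sleep_intervals() if a >= t_on + 96.0]
        first = sleeps[0][1] - sleeps[0][0]
        assert 8.65 < first < 24.0  # longer than the 8.6-h baseline night
        assert first < 48.0  # nowhere near the 96 lost hours


class TestEffort:
    def test_zero_below_threshold(self, tp_human, relation, comparison_sat):
        t = np.array([1.0, 5.0])
        H = np.asarray(tp_human.upper_threshold(t)) - 0.5
        assert np.all(wake_effort_two_process(tp_human, relation, H, t) == 0.0)
        assert comparison_sat.effort_pr[0] == pytest.approx(0.0, abs=1e-6)

    def test_efforts_nonnegative_and_continuous(self, comparison_sat):
        res = comparison_sat
        for series in (res.effort_pr, res.effort_2p):
            assert np.nanmin(series) >= 0.0
            steps = np.abs(np.diff(series))
            assert np.nanmax(steps) < 0.05  # no jumps at the clamping boundary

    def test_effort_envelope_levels_off(self, comparison_sat):
        """Daily effort maxima rise with decreasing increments (leveling off)."""
        res = comparison_sat
        t = res.t - res.t[0]
        maxima = [res.effort_pr[(t >= 24 * d) & (t < 24 * (d + 1))].max() for d in range(4)]
        increments = np.diff(maxima)
        assert all(m > 0 for m in maxima)
        assert all(b < a for a, b in zip(increments, increments[1:]))

    def test_effort_unavailable_beyond_fold_range(self, branches):
        """Past the tabulated fold curve wake cannot be maintained at all."""
        dvp, _, _ = branches.curve._plus_branch()
        assert np.isnan(branches.effort(dvp[-1] + 50.0))
        assert branches.effort(dvp[0] - 1.0) == 0.0  # below threshold: no effort

    def test_sleep_extension_more_restricted_than_wake(self, pr_params):
        wake_ext, sleep_ext = effort_asymmetry(pr_params, dm_span=1.0)
        assert wake_ext > sleep_ext > 0.0


class TestEffortRelation:
    def test_fit_quality(self, relation):
        assert relation.rms_residual < 0.02

    def test_relation_close_to_linear_with_small_quadratic(self, relation, branches):
        """The effort-pressure relation is near-linear; the quadratic term
        is a small correction (a pure-line refit already fits to a few %)."""
        x = np.linspace(0.0, relation.delta_max, 400)[1:]
        y = branches.effort(branches.D_v_plus + x)
        c_lin = float(np.sum(x * y) / np.sum(x * x))
        rng = float(np.ptp(y))
        assert relation.rms_residual < 0.02
        assert np.sqrt(np.mean((y - c_lin * x) ** 2)) / rng < 0.08
        # the quadratic term stays subdominant across the whole fit window
        assert abs(relation.quadratic) * relation.delta_max < abs(relation.linear)

    def test_coefficients_independent_of_grid_density(self, branches, pr_params):
        from sleepdyn.mapping import saddle_node_curve

        r1 = fit_effort_relation(branches.curve, pr_params, delta_max=8.0, n=300)
        dense = saddle_node_curve(pr_params, np.linspace(pr_params.A, pr_params.A + 25.0, 1200))
        r2 = fit_effort_relation(dense, pr_params, delta_max=8.0, n=300)
        assert r2.linear == pytest.approx(r1.linear, rel=1e-3)
        assert r2.quadratic == pytest.approx(r1.quadratic, rel=1e-3)

    def test_insufficient_span_refused(self, pr_params):
        from sleepdyn.mapping import saddle_node_curve

        tiny = saddle_node_curve(pr_params, np.linspace(pr_params.A, pr_params.A + 0.1, 20))
        with pytest.raises(ValueError, match="span"):
            fit_effort_relation(tiny, pr_params, delta_max=10.0)


class TestFormulationAgreement:
    def test_saturating_form_tracks_two_process(self, comparison_sat):
        """Firing-rate-limited production: both formulations agree closely.

        Compared on the daily effort maxima (the envelope): pointwise
        ratios are ill-conditioned inside the circadian dips where both
        efforts pass near zero.
        """
        res = comparison_sat
        t = res.t - res.t[0]
        for d in range(4):
            day = (t >= 24 * d) & (t < 24 * (d + 1))
            peak_pr = np.nanmax(res.effort_pr[day])
            peak_2p = np.nanmax(res.effort_2p[day])
            assert abs(peak_pr - peak_2p) / peak_2p < 0.15
        assert abs(res.rel_diff[-1]) < 0.15
        # absolute agreement holds everywhere, dips included
        assert np.nanmax(np.abs(res.effort_pr - res.effort_2p)) < 0.4

    def test_linear_form_production_runs_away(self, pr_params, tp_human):
        """Unbounded linear production makes the ghost effort diverge."""
        res_lin = deprivation_comparison(pr_params, tp_human, days=4.0)
        assert res_lin.effort_pr[-1] > 2.0 * res_lin.effort_2p[-1]
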