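"""Equivalence machinery between the neuronal model and the two-process model.

Three pieces:

* saddle-node (fold) curves of the slow manifold, which bound the bistable
  band of VLPO drives and play the role of the two-process thresholds;
* the exact translation of hard-switch parameters into two-process
  parameters (asymptote, thresholds, circadian amplitude);
* calibration of the hard-switch parameters (``Q_bar``, ``V_th`` and the
  rescaled VLPO<-MA weight) from a converged cycle of the full sigmoid
  model, so that the mapped two-process trajectory retains the timings and
  values of the homeostat's extrema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .bifurcation import classify_pattern
from .containers import SLEEP
from .params import (
    CircadianWaveform,
    ParameterError,
    PRParams,
    PRSwitchParams,
    TwoProcessParams,
)
from .pr import firing_rate, firing_rate_slope, simulate_pr
from .twoprocess import simulate_two_process

__all__ = [
    "FoldPoint",
    "SaddleNodeCurve",
    "EquivalenceReport",
    "fold_points",
    "saddle_node_curve",
    "pr_switch_to_two_process",
    "calibrate_switch_from_pr",
    "equivalence_report",
]


# ---------------------------------------------------------------------------
# Saddle-node curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPoint:
    """One saddle-node of the frozen-drive fast subsystem."""

    D_v: float  # fold drive to the VLPO, mV
    V_v: float  # VLPO potential at the fold, mV
    V_m: float  # MA potential at the fold, mV


def _dv_of_vv(V_v, D_m, p: PRParams):
    """VLPO drive on the equilibrium branch parametrised by ``V_v``."""
    V_m = D_m - p.nu_mv * firing_rate(V_v, p)
    return V_v + p.nu_vm * firing_rate(V_m, p)


def _dv_slope(V_v, D_m, p: PRParams):
    V_m = D_m - p.nu_mv * firing_rate(V_v, p)
    return 1.0 - p.nu_vm * p.nu_mv * firing_rate_slope(V_m, p) * firing_rate_slope(V_v, p)


def fold_points(p: PRParams, D_m: Optional[float] = None,
                v_range: tuple = (-40.0, 40.0), step: float = 0.02):
    """Saddle-node points at fixed MA drive ``D_m`` (default: ``p.A``).

    Returns a list of :class:`FoldPoint`, sorted by ``V_v``: the first is
    the wake fold (``D_v_plus``, the drive at which the wake state
    vanishes), the second the sleep fold (``D_v_minus``).  The hard-switch
    firing function has no smooth folds, so an empty list is returned for
    :class:`PRSwitchParams`.
    """
    if isinstance(p, PRSwitchParams):
        return []
    if D_m is None:
        D_m = p.A
    grid = np.arange(v_range[0], v_range[1] + step, step)
    slope = _dv_slope(grid, D_m, p)
    out = []
    for k in np.nonzero(np.diff(np.signbit(slope)))[0]:
        V_v = brentq(_dv_slope, grid[k], grid[k + 1], args=(D_m, p),
                     xtol=1e-12, rtol=8.9e-16)
        V_m = D_m - p.nu_mv * float(firing_rate(V_v, p))
        out.append(FoldPoint(D_v=float(_dv_of_vv(V_v, D_m, p)), V_v=float(V_v), V_m=V_m))
    return out


@dataclass
class SaddleNodeCurve:
    """Fold drives as a function of the MA drive ``D_m``.

    ``D_v_minus``/``D_v_plus`` are NaN where the corresponding fold does
    not exist; ``validity`` is the sub-range of ``D_m`` on which both
    folds were found.
    """

    D_m: np.ndarray
    D_v_minus: np.ndarray
    D_v_plus: np.ndarray
    V_minus: np.ndarray  # VLPO potential at the sleep fold
    V_plus: np.ndarray  # VLPO potential at the wake fold
    V_m_plus: np.ndarray  # MA potential at the wake fold (ghost-state firing)
    params: PRParams = field(repr=False, default=None)

    @property
    def validity(self):
        ok = ~np.isnan(self.D_v_minus) & ~np.isnan(self.D_v_plus)
        if not ok.any():
            return None
        return float(self.D_m[ok].min()), float(self.D_m[ok].max())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "D_m": self.D_m,
            "D_v_minus": self.D_v_minus,
            "D_v_plus": self.D_v_plus,
            "V_minus": self.V_minus,
            "V_plus": self.V_plus,
        })

    # -- wake-ghost geometry -------------------------------------------------

    def _plus_branch(self):
        ok = ~np.isnan(self.D_v_plus)
        order = np.argsort(self.D_v_plus[ok])
        return self.D_v_plus[ok][order], self.D_m[ok][order], self.V_m_plus[ok][order]

    def ghost_drive(self, D_v):
        """MA drive needed on the wake fold at VLPO drive ``D_v``.

        NaN outside the tabulated fold range ("impossible to maintain
        wake").  Below the natural fold drive the nominal ``A`` suffices.
        """
        dvp, dm, _ = self._plus_branch()
        D_v = np.asarray(D_v, dtype=float)
        out = np.interp(D_v, dvp, dm, left=self.params.A, right=np.nan)
        return out

    def ghost_V_m(self, D_v):
        """MA potential on the wake fold at VLPO drive ``D_v``."""
        dvp, _, vm = self._plus_branch()
        return np.interp(np.asarray(D_v, dtype=float), dvp, vm,
                         left=vm[0], right=np.nan)


def saddle_node_curve(p: PRParams, D_m_grid) -> SaddleNodeCurve:
    """Tabulate the saddle-node folds over a grid of MA drives."""
    D_m_grid = np.asarray(D_m_grid, dtype=float)
    n = len(D_m_grid)
    dvm = np.full(n, np.nan)
    dvp = np.full(n, np.nan)
    vvm = np.full(n, np.nan)
    vvp = np.full(n, np.nan)
    vmp = np.full(n, np.nan)
    for i, dm in enumerate(D_m_grid):
        folds = fold_points(p, dm)
        if len(folds) >= 2:
            wake, sleep = folds[0], folds[-1]
            dvp[i], vvp[i], vmp[i] = wake.D_v, wake.V_v, wake.V_m
            dvm[i], vvm[i] = sleep.D_v, sleep.V_v
    return SaddleNodeCurve(D_m=D_m_grid, D_v_minus=dvm, D_v_plus=dvp,
                           V_minus=vvm, V_plus=vvp, V_m_plus=vmp, params=p)


# ---------------------------------------------------------------------------
# Hard switch -> two-process translation
# ---------------------------------------------------------------------------

def pr_switch_to_two_process(sp: PRSwitchParams) -> TwoProcessParams:
    """Exact two-process equivalent of a hard-switch parameter set.

    On the slow manifold the switch model *is* a two-process model: the
    upper asymptote is ``mu_h * Q_bar``, both time constants equal ``chi``,
    the mean thresholds are set by the switch voltage and the VLPO drive,
    and their gap is the VLPO inhibition exerted by the active MA
    (``nu_vm * Q_bar``).  The circadian drive reappears, sign-flipped and
    scaled by ``1/nu_vh``, as the threshold modulation.
    """
    H0_minus = (sp.V_th - sp.D0_v) / sp.nu_vh
    H0_plus = H0_minus + sp.nu_vm * sp.Q_bar / sp.nu_vh
    if not H0_minus < H0_plus:
        raise ParameterError(
            "nu_vm",
            "mapped thresholds satisfy H0_minus >= H0_plus; the switch model needs "
            "a positive MA->VLPO inhibition nu_vm * Q_bar to produce hysteresis",
        )
    circ = CircadianWaveform(
        amplitude=-sp.circadian.amplitude / sp.nu_vh,
        omega=sp.circadian.omega,
        alpha=sp.circadian.alpha,
        coefficients=sp.circadian.coefficients,
    )
    return TwoProcessParams(
        mu=sp.mu_h * sp.Q_bar,
        chi_w=sp.chi,
        chi_s=sp.chi,
        H0_plus=H0_plus,
        H0_minus=H0_minus,
        circadian=circ,
        lower=0.0,
    )


# ---------------------------------------------------------------------------
# Calibration of the switch model from the sigmoid model
# ---------------------------------------------------------------------------

def _quadratic_extremum(t3, h3):
    """Vertex of the parabola through three points (sub-step extremum)."""
    t1, t2, t3_ = t3
    h1, h2, h3_ = h3
    denom = (t1 - t2) * (t1 - t3_) * (t2 - t3_)
    a = (t3_ * (h2 - h1) + t2 * (h1 - h3_) + t1 * (h3_ - h2)) / denom
    b = (t3_**2 * (h1 - h2) + t2**2 * (h3_ - h1) + t1**2 * (h2 - h3_)) / denom
    if a == 0:
        return t2, h2
    tv = -b / (2 * a)
    c = h2 - a * t2**2 - b * t2
    return tv, a * tv**2 + b * tv + c


def _cycle_extrema(series, t_from):
    """(t_min, H_min, t_max, H_max) of one converged cycle after ``t_from``."""
    t, H = series.t, series.H
    sel = t >= t_from
    t, H = t[sel], H[sel]
    dH = np.diff(H)
    mins, maxs = [], []
    for k in range(1, len(dH)):
        if dH[k - 1] < 0 <= dH[k]:
            mins.append(_quadratic_extremum(t[k - 1:k + 2], H[k - 1:k + 2]))
        elif dH[k - 1] > 0 >= dH[k]:
            maxs.append(_quadratic_extremum(t[k - 1:k + 2], H[k - 1:k + 2]))
    if not mins or not maxs:
        raise RuntimeError("no homeostat extrema found; is the cycle converged?")
    # first minimum followed by the next maximum (one wake phase)
    t_min, H_min = mins[0]
    later = [m for m in maxs if m[0] > t_min]
    if not later:
        raise RuntimeError("no homeostat maximum after the first minimum")
    t_max, H_max = later[0]
    return t_min, H_min, t_max, H_max


@dataclass
class EquivalenceReport:
    """Outcome of a cross-model comparison / calibration.

    Transition-time discrepancy arrays are in hours; extrema discrepancies
    in hours and pressure units.  ``mu`` retains some dependence on ``chi``
    through the used portion of the firing curve, so the fitted cycle
    quantities are exposed as fields rather than asserted against bounds.
    """

    two_process: TwoProcessParams
    switch: Optional[PRSwitchParams] = None
    H_min: float = np.nan
    H_max: float = np.nan
    t_min: float = np.nan
    t_max: float = np.nan
    H0_plus_fold: float = np.nan  # saddle-node identification of the upper threshold
    H0_minus_fold: float = np.nan  # saddle-node identification of the lower threshold
    transition_diff_pr_vs_2p: np.ndarray = field(default_factory=lambda: np.array([]))
    transition_diff_switch_vs_2p: np.ndarray = field(default_factory=lambda: np.array([]))
    extrema_time_diff: np.ndarray = field(default_factory=lambda: np.array([]))
    extrema_value_diff: np.ndarray = field(default_factory=lambda: np.array([]))

    def max_transition_diff(self) -> float:
        diffs = np.concatenate([
            np.abs(self.transition_diff_pr_vs_2p),
            np.abs(self.transition_diff_switch_vs_2p),
        ])
        return float(diffs.max()) if diffs.size else np.nan

    def to_dict(self):
        from . import io

        return {
            "two_process": io.params_to_dict(self.two_process),
            "switch": io.params_to_dict(self.switch) if self.switch else None,
            "H_min": self.H_min, "H_max": self.H_max,
            "t_min": self.t_min, "t_max": self.t_max,
            "transition_diff_pr_vs_2p": list(map(float, self.transition_diff_pr_vs_2p)),
            "transition_diff_switch_vs_2p": list(map(float, self.transition_diff_switch_vs_2p)),
            "extrema_time_diff": list(map(float, self.extrema_time_diff)),
            "extrema_value_diff": list(map(float, self.extrema_value_diff)),
        }


def calibrate_switch_from_pr(
    p: PRParams,
    discard_days: float = 20.0,
    compare_days: float = 10.0,
    full_report: bool = True,
):
    """Calibrate hard-switch parameters from the full sigmoid model.

    Three steps: (i) identify the two-process thresholds with the
    saddle-node drives of the slow manifold; (ii) integrate one converged
    cycle, extract the homeostat extrema (quadratic sub-step
    interpolation) and solve for the upper asymptote ``mu`` so the
    wake-phase exponential passes through them; (iii) take the lower
    asymptote as 0, then recover ``Q_bar = mu/mu_h``, ``V_th`` from the
    lower threshold, and rescale ``nu_vm`` so the switch model's threshold
    gap matches the fold gap (without this rescaling the switch model's
    upper threshold would sit above its asymptote and no wake-to-sleep
    switch could occur).

    Returns ``(PRSwitchParams, EquivalenceReport)``.  Requires a converged
    monophasic source cycle; anything else is refused (the construction is
    valid away from bifurcation points only).
    """
    # --- step (i): identify the thresholds with the fold drives -----------
    H0_plus_fold = H0_minus_fold = np.nan
    if isinstance(p, PRSwitchParams):
        # calibration is a fixed point on the switch model itself
        H0_plus_fold = (p.V_th - p.D0_v) / p.nu_vh + p.nu_vm * p.Q_bar / p.nu_vh
        H0_minus_fold = (p.V_th - p.D0_v) / p.nu_vh
    else:
        folds = fold_points(p)
        if len(folds) < 2:
            raise ParameterError("D0_v", "no bistable band: the slow manifold has no folds")
        H0_plus_fold = (folds[0].D_v - p.D0_v) / p.nu_vh
        H0_minus_fold = (folds[-1].D_v - p.D0_v) / p.nu_vh

    # --- step (ii): one converged cycle of the source model ---------------
    horizon = discard_days * 24.0 + 72.0
    series, pattern = simulate_pr(p, t_span=(0.0, horizon), sample_dt=0.02)
    tail = pattern.after(discard_days * 24.0)
    summary = classify_pattern(tail)
    if not (summary.converged and summary.period_days == 1 and summary.episodes_per_day == 1):
        raise ValueError(
            "calibration requires a converged monophasic source cycle "
            f"(got period={summary.period_days}, episodes/day={summary.episodes_per_day}); "
            "re-parametrise or calibrate away from bifurcation points"
        )
    t_min, H_min, t_max, H_max = _cycle_extrema(series, discard_days * 24.0)
    period = 24.0 * 2.0 * np.pi / p.circadian.omega / 24.0  # hours (24 for the default)
    wake_len = t_max - t_min
    sleep_len = t_min + period - t_max

    # Anchor the mapped model so its closed orbit switches exactly at the
    # measured extrema times: with the lower asymptote at zero the sleep
    # exponential from (t_max, H_max) arrives at t_min at H_arrive (close
    # to, but not exactly, H_min; the residual is reported), the wake
    # exponential is made to pass from there through (t_max, H_max) by the
    # choice of mu, and the mean thresholds are set so the thresholds pass
    # through the switch points.  They equal the saddle-node identification
    # up to the small dynamic delay of the fast transition (also reported).
    H_arrive = H_max * np.exp(-sleep_len / p.chi)
    decay = np.exp(-wake_len / p.chi)
    mu = (H_max - H_arrive * decay) / (1.0 - decay)
    circ2_amp = -p.circadian.amplitude / p.nu_vh
    circ2 = CircadianWaveform(amplitude=circ2_amp, omega=p.circadian.omega,
                              alpha=p.circadian.alpha, coefficients=p.circadian.coefficients)
    H0_plus = H_max - float(circ2.value(t_max))
    H0_minus = H_arrive - float(circ2.value(t_min))

    # --- step (iii): switch parameters ------------------------------------
    Q_bar = mu / p.mu_h
    V_th = p.nu_vh * H0_minus + p.D0_v
    nu_vm_sw = p.nu_vh * (H0_plus - H0_minus) / Q_bar
    sp = PRSwitchParams(
        Q_max=p.Q_max, theta=p.theta, sigma=p.sigma,
        nu_vm=nu_vm_sw, nu_mv=p.nu_mv, nu_vh=p.nu_vh,
        D0_v=p.D0_v, A=max(p.A, V_th + 0.5), chi=p.chi, mu_h=p.mu_h, tau=p.tau,
        circadian=p.circadian, asymptote_form="linear",
        Q_bar=Q_bar, V_th=V_th,
    )
    tp = pr_switch_to_two_process(sp)
    report = EquivalenceReport(two_process=tp, switch=sp,
                               H_min=H_min, H_max=H_max, t_min=t_min, t_max=t_max,
                               H0_plus_fold=float(H0_plus_fold),
                               H0_minus_fold=float(H0_minus_fold))
    if full_report:
        report = equivalence_report(p, sp, tp, source=(series, pattern),
                                    t_from=discard_days * 24.0, days=compare_days,
                                    base=report)
    return sp, report


def _paired_diffs(times_a, dirs_a, times_b, dirs_b, max_lag=6.0):
    """Pair transitions of equal direction in order; differences in hours."""
    diffs = []
    j = 0
    for t_a, d_a in zip(times_a, dirs_a):
        while j < len(times_b) and (dirs_b[j] != d_a or times_b[j] < t_a - max_lag):
            j += 1
        if j >= len(times_b):
            break
        diffs.append(times_b[j] - t_a)
        j += 1
    return np.asarray(diffs)


def equivalence_report(
    p: PRParams,
    sp: PRSwitchParams,
    tp: Optional[TwoProcessParams] = None,
    source=None,
    t_from: float = 480.0,
    days: float = 10.0,
    base: Optional[EquivalenceReport] = None,
) -> EquivalenceReport:
    """Compare full PR, hard-switch and mapped two-process trajectories.

    All three start from matched states at a converged sleep onset of the
    source run and are compared transition-by-transition over ``days``.
    """
    if tp is None:
        tp = pr_switch_to_two_process(sp)
    if source is None:
        source = simulate_pr(p, t_span=(0.0, t_from + days * 24.0 + 48.0), sample_dt=0.02)
    series, pattern = source
    onsets = pattern.sleep_onsets()
    onsets = onsets[onsets >= t_from]
    if len(onsets) == 0:
        raise ValueError("source run has no sleep onset after the transient")
    t_s = float(onsets[0])
    H_s = float(np.interp(t_s, series.t, series.H))
    t_end = t_s + days * 24.0
    if series.t[-1] < t_end:
        series, pattern = simulate_pr(p, t_span=(0.0, t_end + 24.0), sample_dt=0.02)

    # matched initial conditions: just after the wake->sleep switch
    y0_sw = np.array([p.nu_vh * H_s + p.D0_v + float(p.circadian.value(t_s)),
                      sp.A - sp.nu_mv * sp.Q_bar, H_s])
    _, pat_sw = simulate_pr(sp, init=y0_sw, t_span=(t_s, t_end), sample_dt=0.5)
    _, pat_2p = simulate_two_process(tp, H_init=H_s, state_init=SLEEP,
                                     t_span=(t_s, t_end), sample_dt=None)

    sel = (pattern.times >= t_s + 1.0) & (pattern.times <= t_end)
    times_pr = pattern.times[sel]
    dirs_pr = [d for d, k in zip(pattern.directions, sel) if k]

    diffs_pr = _paired_diffs(times_pr, dirs_pr, pat_2p.times, pat_2p.directions)
    diffs_sw = _paired_diffs(pat_sw.times, pat_sw.directions, pat_2p.times, pat_2p.directions)

    # extrema of the source H vs the mapped two-process H
    ts2, _ = simulate_two_process(tp, H_init=H_s, state_init=SLEEP,
                                  t_span=(t_s, t_end), sample_dt=0.02)
    et_diff, ev_diff = [], []
    t_cursor = t_s + 12.0
    while t_cursor + 30.0 < t_end:
        try:
            a = _cycle_extrema(series, t_cursor)
            b = _cycle_extrema(ts2, t_cursor)
        except RuntimeError:
            break
        et_diff.extend([b[0] - a[0], b[2] - a[2]])
        ev_diff.extend([b[1] - a[1], b[3] - a[3]])
        t_cursor += 24.0
    rep = base or EquivalenceReport(two_process=tp, switch=sp)
    rep.two_process = tp
    rep.switch = sp
    rep.transition_diff_pr_vs_2p = diffs_pr
    rep.transition_diff_switch_vs_2p = diffs_sw
    rep.extrema_time_diff = np.asarray(et_diff)
    rep.extrema_value_diff = np.asarray(ev_diff)
    return rep
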