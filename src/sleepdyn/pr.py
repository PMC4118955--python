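"""The mutual-inhibition (VLPO/MA) neuronal model and its hard-switch variant.

State is ``(V_v, V_m, H)``: mean cell-body potentials (mV, relative to
rest) of the sleep-promoting VLPO population and of the wake-promoting
mono-aminergic (MA) population, plus the homeostatic pressure ``H``.  The
populations inhibit each other; the VLPO is driven by the homeostatic
pressure and the circadian oscillation, the MA by a constant drive ``A``::

    tau dV_v/dt = -V_v + D_v(t, H) - nu_vm Q(V_m)
    tau dV_m/dt = -V_m + A         - nu_mv Q(V_v)
    chi dH/dt   = -H + P(Q(V_m))

with ``Q`` the sigmoid firing function (or a hard switch) and ``P`` the
homeostatic production (linear ``mu_h*Q`` or saturating).  Wake and sleep
are labelled by the MA firing rate crossing 1/s.
"""

from __future__ import annotations

import math
import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.special import expit

from .containers import SLEEP, WAKE, SleepWakePattern, StateTimeseries
from .params import PRParams, PRSwitchParams

__all__ = [
    "firing_rate",
    "firing_switch",
    "homeostatic_asymptote",
    "slow_manifold_solve",
    "simulate_pr",
    "wake_default_init",
]

#: Firing-rate threshold (1/s) whose crossing defines the wake/sleep label.
Q_LABEL = 1.0


def firing_rate(V, p: PRParams):
    """Sigmoid firing function ``Q(V)``: ``Q_max/2`` at ``V = theta``."""
    return p.Q_max * expit((np.asarray(V, dtype=float) - p.theta) / p.sigma)


def firing_rate_slope(V, p: PRParams):
    """Derivative ``dQ/dV`` of the sigmoid firing function."""
    Q = firing_rate(V, p)
    return Q * (p.Q_max - Q) / (p.Q_max * p.sigma)


def firing_switch(V, p: PRSwitchParams):
    """Hard switch: ``Q_bar`` strictly above ``V_th``, else 0."""
    return np.where(np.asarray(V, dtype=float) > p.V_th, p.Q_bar, 0.0)


def homeostatic_asymptote(Q_m, p: PRParams):
    """Upper asymptote of ``H`` as a function of the MA firing rate.

    Linear form: ``mu_h * Q_m`` (the asymptote tracks the firing rate).
    Saturating form: Michaelis-Menten limited production, normalised to
    agree with the linear form at the nominal wake firing rate ``Q(A)``,
    which keeps the asymptote approximately constant during (deprived)
    wake.
    """
    Q_m = np.asarray(Q_m, dtype=float)
    if p.asymptote_form == "linear":
        return p.mu_h * Q_m
    Q0 = p.Q_ref_sat if p.Q_ref_sat is not None else float(firing_rate(p.A, p))
    return p.mu_h * (Q0 + p.Q_half_sat) * Q_m / (Q_m + p.Q_half_sat)


# ---------------------------------------------------------------------------
# Slow manifold
# ---------------------------------------------------------------------------

def _reduced_residual(V_v, D_v, D_m, p):
    V_m = D_m - p.nu_mv * firing_rate(V_v, p)
    return V_v - D_v + p.nu_vm * firing_rate(V_m, p)


def slow_manifold_solve(D_v: float, D_m: float, p: PRParams,
                        v_range: tuple = (-80.0, 80.0), step: float = 0.02):
    """Equilibria of the fast (neuronal) subsystem at frozen drives.

    Returns a list of one or three ``(V_v, V_m)`` pairs, sorted by ``V_v``
    (first entry = wake branch, last = sleep branch when three exist).
    Each solution satisfies both frozen-drive equilibrium equations to
    high accuracy.
    """
    grid = np.arange(v_range[0], v_range[1] + step, step)
    res = _reduced_residual(grid, D_v, D_m, p)
    roots = []
    sign_change = np.nonzero(np.diff(np.signbit(res)))[0]
    for k in sign_change:
        root = brentq(_reduced_residual, grid[k], grid[k + 1],
                      args=(D_v, D_m, p), xtol=1e-13, rtol=8.9e-16)
        roots.append(float(root))
    # exact zeros on the grid (vanishingly unlikely, but keep them)
    for k in np.nonzero(res == 0.0)[0]:
        roots.append(float(grid[k]))
    roots = sorted(set(np.round(roots, 12)))
    return [(v, float(D_m - p.nu_mv * firing_rate(v, p))) for v in roots]


def wake_default_init(p: PRParams, t0: float = 0.0, H0: float = 13.0):
    """State on the wake branch of the slow manifold at time ``t0``."""
    D_v = float(p.drive_v(t0, H0))
    if isinstance(p, PRSwitchParams):
        return np.array([D_v - p.nu_vm * p.Q_bar, p.A, H0])
    sols = slow_manifold_solve(D_v, p.A, p)
    V_v, V_m = sols[0]  # lowest V_v = MA-active branch
    return np.array([V_v, V_m, H0])


# ---------------------------------------------------------------------------
# Simulation: sigmoid model
# ---------------------------------------------------------------------------

def _pr_rhs(t, y, p: PRParams):
    V_v, V_m, H = y
    Q_v = firing_rate(V_v, p)
    Q_m = firing_rate(V_m, p)
    D_v = p.nu_vh * H + p.D0_v + p.circadian.value(t)
    tau_h = p.tau_h
    return [
        (-V_v + D_v - p.nu_vm * Q_m) / tau_h,
        (-V_m + p.A - p.nu_mv * Q_v) / tau_h,
        (-H + homeostatic_asymptote(Q_m, p)) / p.chi,
    ]


def _v_at_q(q, p: PRParams) -> float:
    """Potential at which the sigmoid firing rate equals ``q``."""
    return p.theta + p.sigma * math.log(q / (p.Q_max - q))


def _simulate_pr_sigmoid(p, y0, t_span, sample_dt, rtol, atol):
    V_label = _v_at_q(Q_LABEL, p)

    def up(t, y, _p):
        return y[1] - V_label

    def down(t, y, _p):
        return y[1] - V_label

    up.direction, down.direction = 1.0, -1.0
    t_eval = np.arange(t_span[0], t_span[1] + 0.5 * sample_dt, sample_dt)
    t_eval = t_eval[t_eval <= t_span[1]]
    sol = solve_ivp(
        _pr_rhs, t_span, y0, args=(p,), method="LSODA",
        rtol=rtol, atol=atol, events=(up, down), t_eval=t_eval, max_step=1.0,
    )
    if not sol.success:
        raise RuntimeError(f"stiff integration failed at t = {sol.t[-1]:.4f} h: {sol.message}")
    wake_onsets = sol.t_events[0]
    sleep_onsets = sol.t_events[1]
    events = sorted(
        [(float(t), WAKE) for t in wake_onsets] + [(float(t), SLEEP) for t in sleep_onsets]
    )
    return sol.t, sol.y, events


# ---------------------------------------------------------------------------
# Simulation: hard-switch model (piecewise-linear fast subsystem)
# ---------------------------------------------------------------------------

def _switch_rhs(t, y, p: PRSwitchParams, v_on: bool, m_on: bool):
    V_v, V_m, H = y
    Q_v = p.Q_bar if v_on else 0.0
    Q_m = p.Q_bar if m_on else 0.0
    D_v = p.nu_vh * H + p.D0_v + p.circadian.value(t)
    tau_h = p.tau_h
    return [
        (-V_v + D_v - p.nu_vm * Q_m) / tau_h,
        (-V_m + p.A - p.nu_mv * Q_v) / tau_h,
        (-H + p.mu_h * Q_m) / p.chi,
    ]


def _simulate_pr_switch(p, y0, t_span, sample_dt, rtol, atol):
    t0, t1 = t_span
    y = np.array(y0, dtype=float)
    v_on = y[0] > p.V_th
    m_on = y[1] > p.V_th
    ts_chunks, ys_chunks, events = [], [], []
    t = t0
    guard = 0
    while t < t1 - 1e-12:
        guard += 1
        if guard > 200000:
            raise RuntimeError("hard-switch integration exceeded the segment budget")

        def ev_v(tt, yy, *a):
            return yy[0] - p.V_th

        def ev_m(tt, yy, *a):
            return yy[1] - p.V_th

        ev_v.direction = -1.0 if v_on else 1.0
        ev_m.direction = -1.0 if m_on else 1.0
        ev_v.terminal = ev_m.terminal = True
        t_eval = np.arange(t, t1 + 0.5 * sample_dt, sample_dt)
        t_eval = t_eval[t_eval <= t1]
        sol = solve_ivp(
            _switch_rhs, (t, t1), y, args=(p, v_on, m_on), method="LSODA",
            rtol=rtol, atol=atol, events=(ev_v, ev_m),
            t_eval=t_eval if len(t_eval) else None, max_step=1.0,
        )
        if not sol.success:
            raise RuntimeError(f"stiff integration failed at t = {sol.t[-1]:.4f} h: {sol.message}")
        if len(sol.t):
            ts_chunks.append(sol.t)
            ys_chunks.append(sol.y)
        hit_v = len(sol.t_events[0]) > 0
        hit_m = len(sol.t_events[1]) > 0
        if not hit_v and not hit_m:
            break
        candidates = ([sol.t_events[0][0]] if hit_v else []) + \
                     ([sol.t_events[1][0]] if hit_m else [])
        t_ev = min(candidates)
        if hit_v and (not hit_m or sol.t_events[0][0] <= sol.t_events[1][0]):
            y = sol.y_events[0][0].copy()
            v_on = not v_on
            y[0] = p.V_th + (1e-9 if v_on else -1e-9)
        else:
            y = sol.y_events[1][0].copy()
            m_on = not m_on
            y[1] = p.V_th + (1e-9 if m_on else -1e-9)
            events.append((float(t_ev), WAKE if m_on else SLEEP))
        t = float(t_ev)
    if ts_chunks:
        # drop duplicated boundary samples between chunks
        ts = np.concatenate(ts_chunks)
        ys = np.concatenate(ys_chunks, axis=1)
        keep = np.concatenate([[True], np.diff(ts) > 0])
        ts, ys = ts[keep], ys[:, keep]
    else:  # pragma: no cover - degenerate span
        ts, ys = np.array([t0]), np.array(y0, dtype=float)[:, None]
    return ts, ys, events


# ---------------------------------------------------------------------------
# Public entry point
# ---------------------------------------------------------------------------

def simulate_pr(
    p: PRParams,
    init=None,
    t_span: tuple = (0.0, 240.0),
    sample_dt: float = 0.02,
    rtol: float = 1e-8,
    atol: float = 1e-8,
):
    """Simulate the neuronal model (sigmoid or hard-switch firing).

    ``init`` is either an explicit ``(V_v, V_m, H)`` triple or ``None`` for
    the wake-branch default.  Returns ``(StateTimeseries, SleepWakePattern)``
    with the wake/sleep label derived from the MA firing rate crossing
    1/s (both crossing directions are root-found on the integrator's
    output).  If the rate never crosses 1/s the pattern has no
    transitions.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not (math.isfinite(t0) and math.isfinite(t1) and t1 > t0):
        raise ValueError("t_span must be a finite, increasing interval")
    y0 = wake_default_init(p, t0) if init is None else np.asarray(init, dtype=float)

    if isinstance(p, PRSwitchParams):
        ts, ys, events = _simulate_pr_switch(p, y0, (t0, t1), sample_dt, rtol, atol)
        Qf = lambda V: firing_switch(V, p)  # noqa: E731
        q0 = float(Qf(np.asarray(y0[1])))
    else:
        ts, ys, events = _simulate_pr_sigmoid(p, y0, (t0, t1), sample_dt, rtol, atol)
        Qf = lambda V: firing_rate(V, p)  # noqa: E731
        q0 = float(Qf(y0[1]))

    initial_state = WAKE if q0 > Q_LABEL else SLEEP
    # enforce strict alternation (numerical duplicates at tangencies)
    times, dirs = [], []
    prev = initial_state
    for t_ev, d in events:
        if d != prev:
            times.append(t_ev)
            dirs.append(d)
            prev = d
    pattern = SleepWakePattern(np.asarray(times), dirs, initial_state, (t0, t1))

    Q_v = np.asarray(Qf(ys[0]))
    Q_m = np.asarray(Qf(ys[1]))
    labels = np.asarray([pattern.state_at(t) for t in ts], dtype=object)
    series = StateTimeseries(
        t=ts, H=ys[2], state=labels,
        V_v=ys[0], V_m=ys[1], Q_v=Q_v, Q_m=Q_m, pattern=pattern,
    )
    return series, pattern
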