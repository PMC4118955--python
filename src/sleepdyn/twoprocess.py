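"""Event-driven simulation of the two-process model.

Between transitions the homeostatic pressure follows closed-form
exponentials, so episodes are propagated analytically and the switching
times are located by root-finding on ``H(t) - threshold(t)`` rather than
detected on an integration grid.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .containers import SLEEP, WAKE, SleepWakePattern, StateTimeseries
from .params import TwoProcessParams

__all__ = ["simulate_two_process", "episode_end", "wake_H", "sleep_H"]

#: Bracket-scan resolution (hours) used to locate a sign change before the
#: root is polished by Brent's method.  Threshold and pressure slopes are
#: O(1)/h, so only excursions within ~1e-6 pressure units of a tangency can
#: slip between grid points; grazing analysis refines those separately.
_SCAN_STEP = 0.01
_CHUNK = 2400  # scan chunk of one day


def wake_H(p: TwoProcessParams, H0: float, dt):
    """Pressure after ``dt`` hours of wake starting from ``H0``."""
    return p.mu + (H0 - p.mu) * np.exp(-np.asarray(dt, dtype=float) / p.chi_w)


def sleep_H(p: TwoProcessParams, H0: float, dt):
    """Pressure after ``dt`` hours of sleep starting from ``H0``."""
    return p.lower + (H0 - p.lower) * np.exp(-np.asarray(dt, dtype=float) / p.chi_s)


def _gap(p: TwoProcessParams, t0: float, H0: float, state: str, dt):
    """Signed distance of the trajectory to the active threshold."""
    t = t0 + np.asarray(dt, dtype=float)
    if state == WAKE:
        return wake_H(p, H0, dt) - p.upper_threshold(t)
    return sleep_H(p, H0, dt) - p.lower_threshold(t)


def episode_end(
    p: TwoProcessParams,
    t0: float,
    H0: float,
    state: str,
    max_days: float = 40.0,
) -> Optional[float]:
    """Absolute time at which the current episode ends, or ``None``.

    For a wake episode this is the first time ``H`` meets the upper
    threshold from below; for sleep, the lower threshold from above.
    ``None`` means no crossing occurred within ``max_days`` (a no-sleep or
    no-wake regime).  Equality at ``dt = 0`` does not end the episode
    (ties resolve in favour of the current state); a strictly wrong-signed
    start triggers an immediate transition.
    """
    sign = -1.0 if state == WAKE else 1.0  # expected sign of the gap during the episode
    g0 = float(_gap(p, t0, H0, state, 0.0))
    if g0 * sign < 0.0:
        return t0  # already past the threshold: transition immediately
    n_total = int(max_days * 24.0 / _SCAN_STEP)
    offset = 0
    while offset < n_total:
        n = min(_CHUNK, n_total - offset)
        dts = (offset + 1 + np.arange(n)) * _SCAN_STEP
        g = _gap(p, t0, H0, state, dts)
        crossed = np.nonzero(g * sign < 0.0)[0]
        if crossed.size:
            k = int(crossed[0])
            lo = dts[k] - _SCAN_STEP
            hi = dts[k]
            try:
                dt_star = brentq(
                    lambda d: float(_gap(p, t0, H0, state, d)),
                    lo, hi, xtol=1e-12, rtol=8.9e-16,
                )
            except Exception as exc:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"threshold-crossing root finding failed on interval "
                    f"[{t0 + lo:.6f}, {t0 + hi:.6f}] h"
                ) from exc
            return t0 + dt_star
        offset += n
    return None


def _propagate(p, H0, state, dt):
    return wake_H(p, H0, dt) if state == WAKE else sleep_H(p, H0, dt)


def episode_min_gap(p: TwoProcessParams, t0: float, H0: float, state: str, t_end: float):
    """Smallest interior gap to the active threshold along one episode.

    The gap is ``threshold - H`` during wake and ``H - threshold`` during
    sleep, so it is positive inside the episode and zero exactly at the
    crossings; only interior local minima are considered (the episode
    endpoints are excluded).  Returns ``(distance, |slope|)`` at the
    near-touch point, or ``(inf, nan)`` if the gap is monotone.  Used for
    tangency certificates of grazing analysis.
    """
    from scipy.optimize import minimize_scalar

    sign = -1.0 if state == WAKE else 1.0

    def f(t):
        return sign * float(_gap(p, t0, H0, state, t - t0))

    if t_end - t0 < 4e-3:
        return np.inf, np.nan
    grid = np.linspace(t0, t_end, max(int((t_end - t0) / 0.02), 8))
    vals = sign * _gap(p, t0, H0, state, grid - t0)
    best = (np.inf, np.nan)
    for k in range(1, len(grid) - 1):
        if vals[k] <= vals[k - 1] and vals[k] <= vals[k + 1]:
            res = minimize_scalar(f, bounds=(grid[k - 1], grid[k + 1]), method="bounded",
                                  options={"xatol": 1e-11})
            if res.fun < best[0]:
                h = 1e-5
                slope = (f(res.x + h) - f(res.x - h)) / (2.0 * h)
                best = (float(res.fun), abs(float(slope)))
    return best


def simulate_two_process(
    p: TwoProcessParams,
    H_init: float,
    state_init: str = WAKE,
    t_span: tuple = (0.0, 240.0),
    sample_dt: Optional[float] = 0.05,
    max_episode_days: float = 40.0,
):
    """Simulate the two-process model over ``t_span`` (hours).

    Returns ``(StateTimeseries, SleepWakePattern)``.  ``sample_dt=None``
    skips trajectory sampling (events only), which is the fast path used by
    return-map and scan machinery.  A regime in which one state never ends
    is reported as a truncated pattern, not an exception.
    """
    if H_init < 0:
        raise ValueError("H_init must be non-negative")
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not (math.isfinite(t0) and math.isfinite(t1) and t1 > t0):
        raise ValueError("t_span must be a finite, increasing interval")
    if state_init not in (WAKE, SLEEP):
        raise ValueError("state_init must be 'wake' or 'sleep'")

    times = []
    dirs = []
    seg_starts = [(t0, float(H_init), state_init)]  # (t, H, state) at segment starts
    t, H, state = t0, float(H_init), state_init
    truncated = None
    while True:
        t_end = episode_end(p, t, H, state, max_days=max_episode_days)
        if t_end is None:
            truncated = state
            break
        if t_end >= t1:
            break
        H = float(_propagate(p, H, state, t_end - t))
        state = SLEEP if state == WAKE else WAKE
        # guard against a zero-length episode producing a non-increasing grid
        t = t_end if t_end > t else t + 1e-12
        times.append(t)
        dirs.append(state)
        seg_starts.append((t, H, state))

    pattern = SleepWakePattern(np.asarray(times), dirs, state_init, (t0, t1), truncated)

    if sample_dt is None:
        ts = StateTimeseries(
            t=np.asarray([t0, t1]),
            H=np.asarray([H_init, float(_propagate(p, *_last_H_state(seg_starts, t1)))]),
            state=np.asarray([state_init, pattern.state_at(t1)]),
            pattern=pattern,
        )
        return ts, pattern

    grid = np.arange(t0, t1 + 0.5 * sample_dt, sample_dt)
    Hs = np.empty_like(grid)
    labels = np.empty(grid.shape, dtype=object)
    bounds = [s[0] for s in seg_starts] + [np.inf]
    for i, (ts_i, H_i, st_i) in enumerate(seg_starts):
        mask = (grid >= bounds[i]) & (grid < bounds[i + 1])
        if mask.any():
            Hs[mask] = _propagate(p, H_i, st_i, grid[mask] - ts_i)
            labels[mask] = st_i
    ts = StateTimeseries(t=grid, H=Hs, state=labels, pattern=pattern)
    return ts, pattern


def _last_H_state(seg_starts, t1):
    ts_i, H_i, st_i = seg_starts[-1]
    return H_i, st_i, t1 - ts_i
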