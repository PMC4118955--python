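"""The one-dimensional first-return map of sleep-onset times.

For the two-process model, a sleep onset at clock hour ``t`` (the pressure
sitting exactly on the upper threshold) determines the whole subsequent
trajectory; propagating through one sleep and one wake episode yields the
next onset.  Reduced modulo 24 h this is a discontinuous one-dimensional
map whose fixed points are entrained monophasic cycles and whose
discontinuities correspond to trajectories tangent to a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from .containers import SLEEP, WAKE
from .params import TwoProcessParams
from .twoprocess import episode_end, episode_min_gap, sleep_H, wake_H

__all__ = [
    "OnsetStep",
    "Discontinuity",
    "FixedPoint",
    "ReturnMap",
    "OnsetSequence",
    "next_onset",
    "build_return_map",
    "iterate_map",
    "wrap24",
    "wrap_half",
]

#: Jump between adjacent grid values flagging a candidate discontinuity
#: (well above interpolation error, well below genuine jumps of hours).
JUMP_THRESHOLD = 0.5

#: Convergence tolerance for iterated onset sequences (hours).
ITER_TOL = 1e-3


def wrap24(t):
    """Hours folded into the half-open interval [0, 24)."""
    return np.asarray(t, dtype=float) % 24.0


def wrap_half(dt):
    """Hour difference folded into (-12, 12]."""
    return -((12.0 - np.asarray(dt, dtype=float)) % 24.0 - 12.0)


class OnsetStep(NamedTuple):
    """One application of the sleep-onset return map."""

    t_next: float  # next onset, hours mod 24 (NaN if divergent)
    days_elapsed: int  # calendar days between the onsets
    t_abs: float  # absolute time of the next onset (hours from the start)
    diverged: bool


def next_onset(t_onset: float, p: TwoProcessParams, max_days: float = 40.0) -> OnsetStep:
    """Propagate a sleep onset through one sleep and one wake episode.

    The starting state lies on the upper threshold at ``t_onset`` (hours,
    taken mod 24).  Regimes that never return (no-wake or no-sleep) are
    reported as divergent steps, not exceptions.
    """
    t0 = float(wrap24(t_onset))
    H0 = float(p.upper_threshold(t0))
    t_wake = episode_end(p, t0, H0, SLEEP, max_days=max_days)
    if t_wake is None:
        return OnsetStep(np.nan, 0, np.nan, True)
    H_wake = float(sleep_H(p, H0, t_wake - t0))
    t_next = episode_end(p, t_wake, H_wake, WAKE, max_days=max_days)
    if t_next is None:
        return OnsetStep(np.nan, 0, np.nan, True)
    return OnsetStep(float(wrap24(t_next)), int(t_next // 24.0), float(t_next), False)


@dataclass(frozen=True)
class Discontinuity:
    """A refined jump of the return map with its tangency certificate."""

    t: float  # onset hour of the discontinuity
    left_limit: float  # map value just left of the jump (mod 24)
    right_limit: float  # map value just right (mod 24)
    certificate_distance: float  # min gap of the grazing trajectory to the threshold
    certificate_slope: float  # |d/dt gap| at the near-touch point


@dataclass(frozen=True)
class FixedPoint:
    t: float  # onset hour with map(t) = t (mod 24)
    slope: float  # finite-difference local slope
    stable: bool


@dataclass
class ReturnMap:
    """Tabulated sleep-onset first-return map with annotations."""

    params: TwoProcessParams
    t_grid: np.ndarray  # onset hours, strictly increasing in [0, 24)
    t_next: np.ndarray  # next onset hours mod 24 (NaN where divergent)
    days_elapsed: np.ndarray
    discontinuities: list = field(default_factory=list)
    fixed_points: list = field(default_factory=list)

    def __call__(self, t):
        """Interpolated map value (exact at grid nodes, linear between).

        Accurate away from discontinuities; between the two grid nodes
        that bracket a discontinuity the nearer side's value is used.
        """
        t = wrap24(t)
        scalar = np.ndim(t) == 0
        t = np.atleast_1d(t)
        out = np.empty_like(t)
        for i, ti in enumerate(t):
            k = int(np.searchsorted(self.t_grid, ti)) - 1
            k = max(0, min(k, len(self.t_grid) - 1))
            k2 = (k + 1) % len(self.t_grid)
            t_a, t_b = self.t_grid[k], self.t_grid[k2]
            span = wrap_half(t_b - t_a) if k2 != k else 24.0
            w = 0.0 if span == 0 else wrap_half(ti - t_a) / span
            y_a = self.t_next[k]
            jump = wrap_half(self.t_next[k2] - y_a)
            if self._disc_between(t_a, t_b):
                out[i] = y_a if w < 0.5 else self.t_next[k2]
            else:
                out[i] = wrap24(y_a + w * jump)
        return float(out[0]) if scalar else out

    def _disc_between(self, a, b):
        for d in self.discontinuities:
            if wrap_half(d.t - a) >= 0 and wrap_half(b - d.t) >= 0:
                return True
        return False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t_onset": self.t_grid,
            "t_next": self.t_next,
            "days_elapsed": self.days_elapsed,
        })

    def annotations(self):
        return {
            "discontinuities": [
                {"t": d.t, "left": d.left_limit, "right": d.right_limit,
                 "certificate_distance": d.certificate_distance,
                 "certificate_slope": d.certificate_slope}
                for d in self.discontinuities
            ],
            "fixed_points": [
                {"t": f.t, "slope": f.slope, "stable": f.stable}
                for f in self.fixed_points
            ],
        }


def _map_value(t, p):
    return next_onset(t, p).t_next


def _grazing_certificate(p: TwoProcessParams, t_d: float):
    """Tangency certificate at a map discontinuity.

    The trajectories launched immediately left and right of the jump are
    propagated through their return segment; the smallest interior gap to
    a threshold over all traversed episodes is the certificate distance
    ("trajectories that become tangent to the thresholds").
    """
    best = (np.inf, np.nan)
    for side in (-1e-7, 1e-7):
        t0 = float(wrap24(t_d + side))
        H = float(p.upper_threshold(t0))
        t, state = t0, SLEEP
        for _ in range(8):  # sleep + wake segments until the next onset
            t_end = episode_end(p, t, H, state, max_days=40.0)
            if t_end is None:
                break
            dist, slope = episode_min_gap(p, t, H, state, t_end)
            if dist < best[0]:
                best = (dist, slope)
            H = float(sleep_H(p, H, t_end - t)) if state == SLEEP else float(wake_H(p, H, t_end - t))
            state = WAKE if state == SLEEP else SLEEP
            t = t_end
            if state == SLEEP:
                break  # completed one full return segment
    return best


def build_return_map(
    p: TwoProcessParams,
    n_grid: int = 241,
    refine_tol: float = 1e-9,
) -> ReturnMap:
    """Tabulate the first-return map and annotate its structure.

    Discontinuities are flagged where adjacent grid values jump by more
    than half an hour, refined by bisection, and certified by the tangency
    of the mid trajectory; fixed points are root-found on the continuous
    segments with a finite-difference slope estimate.
    """
    if n_grid < 48:
        raise ValueError("n_grid must be at least 48")
    grid = np.linspace(0.0, 24.0, n_grid, endpoint=False)
    steps = [next_onset(t, p) for t in grid]
    t_next = np.array([s.t_next for s in steps])
    days = np.array([s.days_elapsed for s in steps])

    discontinuities = []
    for k in range(n_grid):
        k2 = (k + 1) % n_grid
        a, b = grid[k], grid[k2] if k2 else 24.0
        ya, yb = t_next[k], t_next[k2]
        if np.isnan(ya) or np.isnan(yb):
            continue
        if abs(wrap_half(yb - ya)) <= JUMP_THRESHOLD:
            continue
        lo, hi, y_lo, y_hi = a, b, ya, yb
        while hi - lo > refine_tol:
            mid = 0.5 * (lo + hi)
            ym = _map_value(mid, p)
            if np.isnan(ym):
                break
            if abs(wrap_half(ym - y_lo)) <= abs(wrap_half(ym - y_hi)):
                lo, y_lo = mid, ym
            else:
                hi, y_hi = mid, ym
        t_d = 0.5 * (lo + hi)
        dist, slope = _grazing_certificate(p, t_d)
        discontinuities.append(Discontinuity(
            t=float(wrap24(t_d)), left_limit=float(y_lo), right_limit=float(y_hi),
            certificate_distance=float(dist), certificate_slope=float(slope),
        ))

    fixed_points = []
    g = wrap_half(t_next - grid)
    for k in range(n_grid):
        k2 = (k + 1) % n_grid
        if np.isnan(g[k]) or np.isnan(g[k2]):
            continue
        a = grid[k]
        b = grid[k2] if k2 else 24.0
        if any(wrap_half(d.t - a) >= 0 and wrap_half(b - d.t) >= 0
               for d in discontinuities):
            continue
        if g[k] == 0.0 or g[k] * g[k2] < 0.0:
            if abs(g[k2] - g[k]) > 12.0:
                continue  # wrap artefact, not a sign change of the gap

            def gap(t):
                return float(wrap_half(_map_value(t, p) - t))

            try:
                t_star = brentq(gap, a, b, xtol=1e-10) if g[k] != 0.0 else a
            except ValueError:
                continue
            slope = _local_slope(p, t_star, discontinuities)
            fixed_points.append(FixedPoint(
                t=float(wrap24(t_star)), slope=float(slope), stable=abs(slope) < 1.0,
            ))

    return ReturnMap(params=p, t_grid=grid, t_next=t_next, days_elapsed=days,
                     discontinuities=discontinuities, fixed_points=fixed_points)


def _local_slope(p, t, discontinuities, h0: float = 1e-3):
    """Central-difference slope with step shrinking near discontinuities."""
    h = h0
    for d in discontinuities:
        gap = abs(wrap_half(d.t - t))
        while gap < 2.0 * h and h > 1e-7:
            h /= 4.0
    m_plus = _map_value(t + h, p)
    m_minus = _map_value(t - h, p)
    return wrap_half(m_plus - m_minus) / (2.0 * h)


@dataclass
class OnsetSequence:
    """An iterated sleep-onset sequence (cobweb orbit)."""

    onsets: np.ndarray  # hours mod 24
    days: np.ndarray  # calendar days elapsed per step
    converged: bool
    diverged: bool

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"iteration": np.arange(len(self.onsets)),
                             "onset_h": self.onsets,
                             "days_elapsed": self.days})


def iterate_map(t0: float, n: int, p: TwoProcessParams, tol: float = ITER_TOL) -> OnsetSequence:
    """Iterate the exact return map ``n`` times from onset hour ``t0``.

    The sequence is flagged converged when three consecutive successive
    differences (mod 24) stay below ``tol``; divergent regimes propagate
    the divergent marker.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    onsets = [float(wrap24(t0))]
    days = [0]
    small = 0
    converged = False
    diverged = False
    for _ in range(n):
        step = next_onset(onsets[-1], p)
        if step.diverged:
            diverged = True
            break
        onsets.append(step.t_next)
        days.append(step.days_elapsed)
        if abs(wrap_half(onsets[-1] - onsets[-2])) < tol:
            small += 1
            if small >= 3:
                converged = True
        else:
            small = 0
    return OnsetSequence(np.asarray(onsets), np.asarray(days), converged, diverged)
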