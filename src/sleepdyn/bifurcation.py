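"""Pattern classification, parameter scans and grazing-bifurcation location.

Transitions between different numbers of daily sleep episodes happen when a
trajectory becomes tangent to a switching threshold (a grazing / border
collision bifurcation of the underlying discontinuous one-dimensional map).
This module classifies converged sleep-wake patterns, scans parameters
(homeostatic time constant, mean VLPO drive, threshold shifts) and locates
the grazing points with a tangency certificate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .containers import MIN_EPISODE_H, SLEEP, WAKE, SleepWakePattern
from .params import PRParams, TwoProcessParams
from .pr import simulate_pr
from .twoprocess import episode_min_gap, simulate_two_process

__all__ = [
    "PatternSummary",
    "ScanSpec",
    "BifurcationScan",
    "GrazingResult",
    "classify_pattern",
    "scan_parameter",
    "locate_grazing",
    "find_period2_window",
    "apply_parameter",
]

#: Two onsets (mod the period) closer than this are "the same" (hours).
ONSET_TOL = 0.01

#: Periods above this many days are reported unconverged, not searched.
MAX_PERIOD_DAYS = 16


@dataclass(frozen=True)
class PatternSummary:
    """Converged-pattern statistics.

    ``episodes_per_day`` is rational (episodes per period / period length);
    entrained attractors have integer periods in days.
    """

    episodes_per_day: float
    period_days: Optional[int]
    daily_sleep_h: float
    converged: bool
    episodes_per_period: int = 0
    truncated_state: Optional[str] = None


def classify_pattern(pat: SleepWakePattern, tol: float = ONSET_TOL,
                     max_period: int = MAX_PERIOD_DAYS) -> PatternSummary:
    """Classify a (transient-free) sleep-wake pattern.

    The period is the smallest integer number of days after which the
    sleep-onset sequence repeats (mod 24 h, within ``tol``); episode
    statistics are computed over one period at the end of the record.
    Episodes shorter than one minute are merged before classification.
    """
    pat = pat.merged(MIN_EPISODE_H)
    if pat.truncated_state is not None and len(pat.times) == 0:
        return PatternSummary(0.0, None, 24.0 if pat.truncated_state == SLEEP else 0.0,
                              converged=False, truncated_state=pat.truncated_state)
    onsets = pat.sleep_onsets()
    end = pat.t_span[1]
    if len(onsets) == 0:
        daily = 24.0 if pat.initial_state == SLEEP and len(pat.times) == 0 else 0.0
        return PatternSummary(0.0, None, daily, converged=False,
                              truncated_state=pat.truncated_state)
    for p in range(1, max_period + 1):
        P = 24.0 * p
        lo, hi = end - 2.0 * P, end - P
        if lo < pat.t_span[0]:
            break
        window = onsets[(onsets >= lo) & (onsets < hi)]
        image = onsets[(onsets >= hi) & (onsets < end)]
        if len(window) == 0 or len(window) != len(image):
            continue
        if np.max(np.abs((window + P) - image)) < tol:
            sleep_h = sum(
                max(0.0, min(b, end) - max(a, hi))
                for a, b in pat.sleep_intervals()
            )
            return PatternSummary(
                episodes_per_day=len(image) / p,
                period_days=p,
                daily_sleep_h=sleep_h / p,
                converged=True,
                episodes_per_period=len(image),
                truncated_state=None,
            )
    return PatternSummary(np.nan, None, np.nan, converged=False,
                          truncated_state=pat.truncated_state)


# ---------------------------------------------------------------------------
# Parameter application and scans
# ---------------------------------------------------------------------------

def apply_parameter(p, name: str, value: float):
    """Return a copy of ``p`` with the scan axis ``name`` set to ``value``.

    ``chi`` sets both two-process time constants (they coincide in the
    mapped model) or the PR homeostatic constant; ``threshold_shift`` moves
    both two-process mean thresholds by ``value`` (their gap is preserved);
    ``mean_vlpo_drive`` sets ``D0_v`` of the PR model.
    """
    if isinstance(p, TwoProcessParams):
        if name == "chi":
            return replace(p, chi_w=value, chi_s=value)
        if name == "threshold_shift":
            return replace(p, H0_plus=p.H0_plus + value, H0_minus=p.H0_minus + value)
        raise ValueError(f"unsupported two-process scan axis: {name!r}")
    if isinstance(p, PRParams):
        if name == "chi":
            return replace(p, chi=value)
        if name == "mean_vlpo_drive":
            return replace(p, D0_v=value)
        raise ValueError(f"unsupported PR scan axis: {name!r}")
    raise TypeError(f"unsupported parameter object: {type(p).__name__}")


@dataclass(frozen=True)
class ScanSpec:
    """Definition of a one-parameter scan."""

    name: str  # "chi" | "threshold_shift" | "mean_vlpo_drive"
    grid: Sequence[float]
    discard_days: float = 30.0
    classify_days: float = 32.0

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        d = np.diff(g)
        if len(g) > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("scan grid must be strictly monotone")
        object.__setattr__(self, "grid", g)


@dataclass
class BifurcationScan:
    """Result of a one-parameter scan with per-value pattern summaries."""

    name: str
    grid: np.ndarray
    summaries: list
    rasters: list  # per value: list of (day, start mod 24, duration) sleep bars
    critical: list  # (param_lo, param_hi, kind) brackets between grid points

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "param": self.grid,
            "episodes_per_day": [s.episodes_per_day for s in self.summaries],
            "period_days": [s.period_days for s in self.summaries],
            "daily_sleep_h": [s.daily_sleep_h for s in self.summaries],
            "converged": [s.converged for s in self.summaries],
        })


def _simulate_converged(p, discard_days, classify_days, H0=None, state0=WAKE):
    """Long run minus transient; returns (tail pattern, final H, final state)."""
    T = (discard_days + classify_days) * 24.0
    if isinstance(p, TwoProcessParams):
        H0 = 0.5 * (p.H0_plus + p.H0_minus) if H0 is None else H0
        H0 = min(max(H0, p.lower + 1e-9), p.mu - 1e-9) if p.mu > p.lower else H0
        ts, pat = simulate_two_process(p, H_init=H0, state_init=state0,
                                       t_span=(0.0, T), sample_dt=None)
        H_end = float(ts.H[-1])
        state_end = pat.state_at(T)
    else:
        init = None if H0 is None else np.asarray(H0, dtype=float)
        ts, pat = simulate_pr(p, init=init, t_span=(0.0, T), sample_dt=0.05)
        H_end = np.array([ts.V_v[-1], ts.V_m[-1], ts.H[-1]])
        state_end = pat.state_at(T)
    return pat.after(discard_days * 24.0), H_end, state_end


def scan_parameter(p, spec: ScanSpec) -> BifurcationScan:
    """Scan one parameter, warm-starting each grid point from the previous.

    Non-convergence at isolated grid points is recorded in the summary and
    the scan continues.  Critical brackets are reported wherever the
    episodes-per-day count changes between neighbouring grid points
    (episode-adding) and where truncated no-sleep / no-wake regimes begin.
    """
    summaries, rasters = [], []
    H0, state0 = None, WAKE
    for value in spec.grid:
        pv = apply_parameter(p, spec.name, value)
        try:
            tail, H0, state0 = _simulate_converged(pv, spec.discard_days,
                                                   spec.classify_days, H0, state0)
            summary = classify_pattern(tail)
        except Exception:
            summary = PatternSummary(np.nan, None, np.nan, converged=False)
            tail = None
            H0, state0 = None, WAKE
        summaries.append(summary)
        rasters.append(_raster(tail, summary) if tail is not None else [])
    critical = []
    for a, b, sa, sb in zip(spec.grid[:-1], spec.grid[1:], summaries[:-1], summaries[1:]):
        kind = None
        if sa.truncated_state != sb.truncated_state and (sa.truncated_state or sb.truncated_state):
            trunc = sb.truncated_state or sa.truncated_state
            kind = "no-wake boundary" if trunc == SLEEP else "no-sleep boundary"
        elif sa.converged and sb.converged and sa.episodes_per_day != sb.episodes_per_day:
            kind = "episode-adding"
        if kind:
            critical.append((float(a), float(b), kind))
    return BifurcationScan(spec.name, np.asarray(spec.grid, dtype=float),
                           summaries, rasters, critical)


def _raster(tail: SleepWakePattern, summary: PatternSummary):
    """Sleep bars folded mod 24 h, onsets assigned to the day of their start."""
    bars = []
    t0 = tail.t_span[0]
    for a, b in tail.merged().sleep_intervals():
        day = int((a - t0) // 24.0)
        bars.append((day, float(a % 24.0), float(b - a)))
    return bars


# ---------------------------------------------------------------------------
# Grazing bifurcations
# ---------------------------------------------------------------------------

@dataclass
class GrazingResult:
    """A located grazing (episode-adding) bifurcation with its certificate."""

    param: str
    critical_value: float
    bracket: tuple
    episodes_low_side: float
    episodes_high_side: float
    certificate_distance: float  # min |trajectory - threshold| at near-miss
    certificate_slope: float  # |d/dt (trajectory - threshold)| at the near-miss
    certificate_param: float  # parameter value at which the certificate was measured
    map_discontinuity: Optional[float] = None  # onset hour where the map jump crosses the diagonal


def _near_miss_distance(p: TwoProcessParams, discard_days=40.0, span_days=8.0,
                        H0=None, state0=WAKE):
    """Smallest interior gap between trajectory and its active threshold.

    Wake episodes are measured against the upper threshold, sleep episodes
    against the lower one; episode endpoints (where the gap is zero by
    definition) are excluded.  Returns ``(distance, slope_at_min)``.
    """
    T0, T1 = discard_days * 24.0, (discard_days + span_days) * 24.0
    if H0 is None:
        H0 = 0.5 * (p.H0_plus + p.H0_minus)
    ts, pat = simulate_two_process(p, H_init=H0, state_init=state0,
                                   t_span=(0.0, T1), sample_dt=None)
    best = (np.inf, np.nan)
    for a, b, state in pat.after(T0).episodes():
        if b - a < 4.0 * MIN_EPISODE_H:
            continue
        try:
            H_a = _state_H_at(p, pat, a)
        except ValueError:
            continue  # window-start partial episode: skip
        dist, slope = episode_min_gap(p, a, H_a, state, b)
        if dist < best[0]:
            best = (dist, slope)
    return best


def _state_H_at(p: TwoProcessParams, pat: SleepWakePattern, t: float) -> float:
    """Pressure at time ``t``: a transition time or the initial instant."""
    # at transition times H sits exactly on the corresponding threshold
    k = np.searchsorted(pat.times, t)
    if k < len(pat.times) and abs(pat.times[k] - t) < 1e-9:
        entered = pat.directions[k]
        return float(p.upper_threshold(t)) if entered == SLEEP else float(p.lower_threshold(t))
    if k > 0 and abs(pat.times[k - 1] - t) < 1e-9:
        entered = pat.directions[k - 1]
        return float(p.upper_threshold(t)) if entered == SLEEP else float(p.lower_threshold(t))
    raise ValueError("t is not a transition time of the pattern")


def _episodes_at(p, name, value, discard_days, classify_days):
    pv = apply_parameter(p, name, value)
    tail, _, _ = _simulate_converged(pv, discard_days, classify_days)
    return classify_pattern(tail)


def locate_grazing(
    p,
    name: str,
    bracket: tuple,
    xtol: float = 1e-6,
    discard_days: float = 40.0,
    classify_days: float = 16.0,
    certify: bool = True,
) -> GrazingResult:
    """Bisect an episode-adding bifurcation inside ``bracket``.

    The bracket endpoints must exhibit different episodes-per-day counts.
    Bisection keeps the side matching the low endpoint's count; the
    certificate is measured on that side, where the converged trajectory
    comes close to, but does not touch, the grazed threshold: the reported
    distance is the minimum gap and the reported slope its time derivative
    at the near-touch point (tangency).  For two-process parameters the
    return-map footprint of the grazing (the discontinuity that crosses
    the diagonal) is attached when ``certify`` is set.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    s_lo = _episodes_at(p, name, lo, discard_days, classify_days)
    s_hi = _episodes_at(p, name, hi, discard_days, classify_days)
    e_lo, e_hi = s_lo.episodes_per_day, s_hi.episodes_per_day
    if not (s_lo.converged or s_lo.truncated_state) or not (s_hi.converged or s_hi.truncated_state):
        raise ValueError("bracket endpoints must yield converged (or truncated) patterns")
    if e_lo == e_hi:
        raise ValueError("bracket endpoints exhibit the same episode count; no grazing inside")
    while abs(hi - lo) > xtol * max(1.0, abs(lo)):
        mid = 0.5 * (lo + hi)
        s_mid = _episodes_at(p, name, mid, discard_days, classify_days)
        if s_mid.episodes_per_day == e_lo:
            lo = mid
        else:
            hi, e_hi = mid, s_mid.episodes_per_day
    critical = 0.5 * (lo + hi)
    dist = slope = np.nan
    cert_param = lo if e_lo < e_hi else hi
    t_disc = None
    if certify and isinstance(p, TwoProcessParams):
        pv = apply_parameter(p, name, cert_param)
        dist, slope = _near_miss_distance(pv, discard_days=discard_days,
                                          span_days=classify_days / 2.0)
        t_disc = _diagonal_crossing_discontinuity(apply_parameter(p, name, critical))
    return GrazingResult(
        param=name, critical_value=float(critical), bracket=(lo, hi),
        episodes_low_side=e_lo, episodes_high_side=e_hi,
        certificate_distance=float(dist), certificate_slope=float(slope),
        certificate_param=float(cert_param), map_discontinuity=t_disc,
    )


def _diagonal_crossing_discontinuity(p: TwoProcessParams):
    """Onset hour of a return-map discontinuity whose jump straddles the diagonal."""
    from .retmap import build_return_map, wrap_half

    rm = build_return_map(p, n_grid=193)
    for d in rm.discontinuities:
        left = wrap_half(d.left_limit - d.t)
        right = wrap_half(d.right_limit - d.t)
        if left == 0.0 or right == 0.0 or (left < 0.0) != (right < 0.0):
            return float(d.t)
    return None


def find_period2_window(
    p: TwoProcessParams,
    bracket: tuple,
    name: str = "chi",
    xtol: float = 1e-5,
    discard_days: float = 40.0,
    classify_days: float = 16.0,
):
    """Locate a period-2 window between the monophasic and biphasic regimes.

    Between ``n`` and ``n+1`` daily episodes there is a window in which the
    converged pattern repeats only every two days (an extra episode on
    alternate days).  Starting from a bracket whose endpoints are
    monophasic and polyphasic, the upper edge is the grazing point of the
    monophasic pattern; probing just below it yields the period-2 pattern,
    and its lower edge is bisected against the period-1 polyphasic regime.
    Returns ``(lo, hi, GrazingResult)``.
    """
    res = locate_grazing(p, name, bracket, xtol=xtol, discard_days=discard_days,
                         classify_days=classify_days, certify=False)
    hi_edge = res.critical_value
    lo_end = min(bracket)
    # probe geometrically below the grazing point for a period-2 pattern
    probe = None
    step = max(xtol, abs(hi_edge) * 1e-5)
    while probe is None and step < abs(hi_edge - lo_end):
        candidate = hi_edge - step
        s = _episodes_at(p, name, candidate, discard_days, classify_days)
        if s.converged and s.period_days == 2:
            probe = candidate
            break
        if s.converged and s.period_days == 1 and s.episodes_per_day > res.episodes_low_side:
            break  # fell straight into the polyphasic regime: window narrower than xtol
        step *= 2.0
    if probe is None:
        return None
    lo, hi = lo_end, probe
    s_lo = _episodes_at(p, name, lo, discard_days, classify_days)
    if s_lo.converged and s_lo.period_days == 2:
        raise ValueError("bracket lower end already inside the period-2 window")
    while abs(hi - lo) > xtol * max(1.0, abs(lo)):
        mid = 0.5 * (lo + hi)
        s = _episodes_at(p, name, mid, discard_days, classify_days)
        if s.converged and s.period_days == 2:
            hi = mid
        else:
            lo = mid
    return (0.5 * (lo + hi), hi_edge, res)
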