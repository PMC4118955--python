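"""Time-series and sleep-wake pattern containers shared by both models."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["StateTimeseries", "SleepWakePattern", "WAKE", "SLEEP", "MIN_EPISODE_H"]

WAKE = "wake"
SLEEP = "sleep"

#: Episodes shorter than one minute are merged into their neighbours before
#: pattern statistics, suppressing numerical chatter at grazing parameters.
MIN_EPISODE_H = 1.0 / 60.0


@dataclass
class SleepWakePattern:
    """Ordered wake/sleep transition events of one simulation.

    ``times`` are transition times in hours; ``directions[i]`` is the state
    entered at ``times[i]`` (``"sleep"`` for a wake-to-sleep event).
    ``initial_state`` is the state before the first event.  ``t_span`` is
    the simulated interval.  ``truncated_state`` is set when the run ended
    in a state it never left again within the search horizon (``"wake"``
    for a no-sleep regime, ``"sleep"`` for no-wake).
    """

    times: np.ndarray
    directions: list
    initial_state: str
    t_span: tuple
    truncated_state: Optional[str] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.directions):
            raise ValueError("times and directions must have equal length")
        for i in range(1, len(self.directions)):
            if self.directions[i] == self.directions[i - 1]:
                raise ValueError("transition directions must strictly alternate")

    def __len__(self) -> int:
        return len(self.times)

    def state_at(self, t: float) -> str:
        i = int(np.searchsorted(self.times, t, side="right"))
        return self.initial_state if i == 0 else self.directions[i - 1]

    def sleep_onsets(self) -> np.ndarray:
        """Times of wake-to-sleep transitions (hours)."""
        mask = [d == SLEEP for d in self.directions]
        return self.times[np.asarray(mask, dtype=bool)] if len(self.times) else self.times

    def wake_onsets(self) -> np.ndarray:
        mask = [d == WAKE for d in self.directions]
        return self.times[np.asarray(mask, dtype=bool)] if len(self.times) else self.times

    def episodes(self):
        """List of ``(start, end, state)`` covering the simulated span."""
        out = []
        t0, t1 = self.t_span
        bounds = [t0, *self.times.tolist(), t1]
        states = [self.initial_state, *self.directions]
        for i, s in enumerate(states):
            if bounds[i + 1] > bounds[i]:
                out.append((bounds[i], bounds[i + 1], s))
        return out

    def merged(self, min_duration: float = MIN_EPISODE_H) -> "SleepWakePattern":
        """Merge episodes shorter than ``min_duration`` into their neighbours."""
        times = self.times.tolist()
        dirs = list(self.directions)
        changed = True
        while changed and len(times) >= 2:
            changed = False
            for i in range(len(times) - 1):
                if times[i + 1] - times[i] < min_duration:
                    # removing both bounding transitions reabsorbs the episode
                    del times[i:i + 2]
                    del dirs[i:i + 2]
                    changed = True
                    break
        return SleepWakePattern(np.asarray(times), dirs, self.initial_state,
                                self.t_span, self.truncated_state)

    def sleep_intervals(self):
        """List of ``(start, end)`` sleep intervals."""
        return [(a, b) for a, b, s in self.episodes() if s == SLEEP]

    def total_sleep(self) -> float:
        return float(sum(b - a for a, b in self.sleep_intervals()))

    def after(self, t: float) -> "SleepWakePattern":
        """The pattern restricted to times ``>= t`` (transient discard)."""
        keep = self.times >= t
        return SleepWakePattern(
            self.times[keep],
            [d for d, k in zip(self.directions, keep) if k],
            self.state_at(t),
            (t, self.t_span[1]),
            self.truncated_state,
        )

    def events_frame(self) -> pd.DataFrame:
        trans = [f"{WAKE}_to_{SLEEP}" if d == SLEEP else f"{SLEEP}_to_{WAKE}"
                 for d in self.directions]
        return pd.DataFrame({"time_h": self.times, "transition": trans})


@dataclass
class StateTimeseries:
    """Sampled trajectory with a wake/sleep label per sample.

    ``V_v``/``V_m``/``Q_v``/``Q_m`` are ``None`` for pure two-process runs.
    """

    t: np.ndarray
    H: np.ndarray
    state: np.ndarray  # array of "wake"/"sleep" labels
    V_v: Optional[np.ndarray] = None
    V_m: Optional[np.ndarray] = None
    Q_v: Optional[np.ndarray] = None
    Q_m: Optional[np.ndarray] = None
    pattern: Optional[SleepWakePattern] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.t, "H": self.H}
        for name in ("V_v", "V_m", "Q_v", "Q_m"):
            col = getattr(self, name)
            if col is not None:
                data[name] = col
        data["state"] = self.state
        return pd.DataFrame(data)
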