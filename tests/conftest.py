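"""Shared fixtures: canonical parameter sets and the (expensive) calibration."""

import numpy as np
import pytest

from sleepdyn.params import (
    CircadianWaveform,
    TwoProcessParams,
    pr_human,
    pr_switch_human,
    two_process_human,
)


@pytest.fixture(scope="session")
def pr_params():
    return pr_human()


@pytest.fixture(scope="session")
def tp_human():
    return two_process_human()


@pytest.fixture(scope="session")
def sp_human():
    return pr_switch_human()


@pytest.fixture(scope="session")
def calibration(pr_params):
    """Full calibration with a 10-day three-way equivalence comparison."""
    from sleepdyn.mapping import calibrate_switch_from_pr

    return calibrate_switch_from_pr(pr_params, full_report=True, compare_days=10.0)


@pytest.fixture(scope="session")
def human_return_map(tp_human):
    from sleepdyn.retmap import build_return_map

    return build_return_map(tp_human, n_grid=481)


@pytest.fixture()
def flat_two_process():
    """Constant-threshold (a = 0) set with closed-form episode durations."""
    return TwoProcessParams(
        mu=1.0, chi_w=18.0, chi_s=4.0, H0_plus=0.75, H0_minus=0.25,
        circadian=CircadianWaveform(amplitude=0.0),
    )


def brute_force_two_process(p, H_init, state_init, t_span, step=1e-4):
    """Independent fixed-step oracle for two-process transition times.

    Propagates the closed-form exponentials on a dense grid and detects
    threshold crossings by grid comparison only (no root polishing), so
    transition times carry an O(step) error.
    """
    from sleepdyn.containers import SLEEP, WAKE

    t, H, state = float(t_span[0]), float(H_init), state_init
    transitions = []
    while t < t_span[1]:
        n = int(min(t_span[1] - t, 48.0) / step)
        if n == 0:
            break
        dts = step * np.arange(1, n + 1)
        tt = t + dts
        if state == WAKE:
            Hs = p.mu + (H - p.mu) * np.exp(-dts / p.chi_w)
            crossed = Hs > p.H0_plus + p.circadian.value(tt)
        else:
            Hs = p.lower + (H - p.lower) * np.exp(-dts / p.chi_s)
            crossed = Hs < p.H0_minus + p.circadian.value(tt)
        idx = np.nonzero(crossed)[0]
        if idx.size == 0:
            t = t + n * step
            H = float(Hs[-1])
            continue
        k = int(idx[0])
        t = float(tt[k])
        H = float(Hs[k])
        state = SLEEP if state == WAKE else WAKE
        transitions.append((t, state))
    return transitions
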