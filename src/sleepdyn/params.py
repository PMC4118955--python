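"""Parameter sets for the two model families of sleep-wake regulation.

Two interoperable descriptions are covered:

* the two-process model: a homeostatic sleep pressure ``H`` relaxing
  exponentially between an upper asymptote (wake) and a lower asymptote
  (sleep), switching state at circadian-modulated thresholds;
* the mutual-inhibition ("flip-flop") neuronal model: sleep-promoting VLPO
  neurons and wake-promoting mono-aminergic (MA) neurons of the ascending
  arousal system, mutually inhibitory, driven by the same homeostatic and
  circadian processes, plus its hard-switch reduction.

Units follow the mixed convention that is standard for these models: hours
for slow time constants (``chi``), seconds for the neuronal relaxation time
(``tau``, converted internally), millivolts for potentials and drives, and
concentration-like "pressure" units for ``H`` (dimensionless in the pure
two-process setting).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParameterError",
    "CircadianWaveform",
    "TwoProcessParams",
    "PRParams",
    "PRSwitchParams",
    "circadian_value",
    "pr_human",
    "pr_switch_human",
    "two_process_human",
]


class ParameterError(ValueError):
    """Invalid parameter value; ``field`` names the offending entry."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ParameterError(field_name, message)


@dataclass(frozen=True)
class CircadianWaveform:
    """A ~24-h periodic drive/threshold modulation.

    The value at time ``t`` (hours) is::

        a * sum_k c_k * sin(k * (omega * t + alpha))

    where ``c_k`` are ``coefficients`` (first entry 1 for the fundamental;
    higher entries give the skewed-sine shapes used in threshold models).
    ``amplitude`` may be negative, which flips the waveform's sign; this is
    used when translating a drive modulation into a threshold modulation.
    """

    amplitude: float
    omega: float = 2.0 * math.pi / 24.0
    alpha: float = 0.0
    coefficients: tuple[float, ...] = (1.0,)

    def __post_init__(self):
        _require(self.omega > 0, "omega", "angular frequency must be positive")
        coeffs = tuple(float(c) for c in self.coefficients)
        object.__setattr__(self, "coefficients", coeffs)
        _require(len(coeffs) >= 1, "coefficients", "need at least the fundamental")
        if self.amplitude != 0.0 and coeffs[0] != 1.0:
            raise ParameterError("coefficients", "first (fundamental) coefficient must be 1")

    @property
    def period(self) -> float:
        """Period in hours (24 for the default ``omega``)."""
        return 2.0 * math.pi / self.omega

    def value(self, t):
        """Waveform value at time ``t`` (hours); accepts arrays."""
        t = np.asarray(t, dtype=float)
        phase = self.omega * t + self.alpha
        out = np.zeros_like(phase)
        for k, c in enumerate(self.coefficients, start=1):
            if c != 0.0:
                out += c * np.sin(k * phase)
        return self.amplitude * out

    def negated(self) -> "CircadianWaveform":
        """The same waveform with opposite sign (drive vs threshold view)."""
        return CircadianWaveform(
            amplitude=-self.amplitude,
            omega=self.omega,
            alpha=self.alpha,
            coefficients=self.coefficients,
        )


def circadian_value(t, w: CircadianWaveform):
    """Evaluate a circadian waveform at time ``t`` in hours."""
    return w.value(t)


@dataclass(frozen=True)
class TwoProcessParams:
    """Two-process model: thresholds, asymptotes, time constants, circadian.

    ``H`` rises during wake toward ``mu`` with time constant ``chi_w`` and
    decays during sleep toward ``lower`` with time constant ``chi_s``.
    Switching thresholds are ``H0_plus + C(t)`` (wake to sleep) and
    ``H0_minus + C(t)`` (sleep to wake), with ``C`` the circadian waveform.
    """

    mu: float
    chi_w: float
    chi_s: float
    H0_plus: float
    H0_minus: float
    circadian: CircadianWaveform
    lower: float = 0.0

    def __post_init__(self):
        _require(self.chi_w > 0, "chi_w", "wake time constant must be positive")
        _require(self.chi_s > 0, "chi_s", "sleep time constant must be positive")
        _require(self.H0_minus < self.H0_plus, "H0_minus", "lower mean threshold must lie below upper")
        _require(self.mu > self.lower, "mu", "upper asymptote must exceed lower asymptote")
        amp = sum(abs(c) for c in self.circadian.coefficients) * abs(self.circadian.amplitude)
        if self.mu <= self.H0_plus + amp:
            warnings.warn(
                "mu does not exceed the maximum of the upper threshold; wake episodes "
                "may never end over part of the circadian cycle",
                stacklevel=2,
            )

    def upper_threshold(self, t):
        """Wake-to-sleep threshold at time ``t`` (hours)."""
        return self.H0_plus + self.circadian.value(t)

    def lower_threshold(self, t):
        """Sleep-to-wake threshold at time ``t`` (hours)."""
        return self.H0_minus + self.circadian.value(t)

    def threshold_gap(self) -> float:
        return self.H0_plus - self.H0_minus


@dataclass(frozen=True)
class PRParams:
    """Mutual-inhibition (VLPO/MA) model parameters.

    All weights are positive; inhibition carries an explicit minus sign in
    the equations.  The mean circadian drive component is absorbed into
    ``D0_v`` and the oscillatory part lives in ``circadian`` (mV).

    ``asymptote_form`` selects how homeostatic production depends on MA
    firing: ``"linear"`` (production ``mu_h * Q_m``, so the upper asymptote
    tracks the firing rate) or ``"saturating"`` (Michaelis-Menten limited,
    keeping the asymptote approximately constant during wake).
    """

    Q_max: float  # maximum firing rate, 1/s
    theta: float  # mean firing threshold, mV
    sigma: float  # sigmoid width, mV
    nu_vm: float  # VLPO <- MA inhibitory weight, mV s
    nu_mv: float  # MA <- VLPO inhibitory weight, mV s
    nu_vh: float  # homeostatic drive weight, mV per pressure unit
    D0_v: float  # constant VLPO drive incl. mean circadian component, mV
    A: float  # constant drive to MA, mV
    chi: float  # homeostatic time constant, hours
    mu_h: float  # homeostatic production gain, pressure * s
    tau: float  # neuronal relaxation time, seconds
    circadian: CircadianWaveform
    asymptote_form: str = "linear"
    Q_half_sat: float = 1.0  # half-saturation firing rate of the saturating form, 1/s
    #: Reference firing rate at which the saturating production matches the
    #: linear form (None: use the uninhibited rate Q(A)).  Calibration sets
    #: it to the mean wake firing rate so the normal cycle is unchanged.
    Q_ref_sat: float | None = None

    def __post_init__(self):
        for name in ("Q_max", "sigma", "tau", "chi", "mu_h"):
            _require(getattr(self, name) > 0, name, "must be positive")
        _require(self.asymptote_form in ("linear", "saturating"), "asymptote_form",
                 "must be 'linear' or 'saturating'")
        _require(self.Q_half_sat > 0, "Q_half_sat", "must be positive")
        eps = self.tau / (self.chi * 3600.0)
        if eps > 1e-2:
            warnings.warn(
                f"timescale separation tau/chi = {eps:.2e} exceeds 1e-2; the slow-manifold "
                "reduction underlying the two-process equivalence may be inaccurate",
                stacklevel=2,
            )

    @property
    def tau_h(self) -> float:
        """Neuronal relaxation time in hours."""
        return self.tau / 3600.0

    def drive_v(self, t, H):
        """Total VLPO drive ``D_v`` (mV) at time ``t`` and pressure ``H``."""
        return self.nu_vh * np.asarray(H, dtype=float) + self.D0_v + self.circadian.value(t)


@dataclass(frozen=True)
class PRSwitchParams(PRParams):
    """Hard-switch reduction of the mutual-inhibition model.

    The sigmoid firing function is replaced by ``Q(V) = Q_bar`` for
    ``V > V_th`` and 0 otherwise; ``sigma`` is unused.
    """

    Q_bar: float = 5.0  # switch-on firing rate, 1/s
    V_th: float = 1.5  # switch voltage, mV

    def __post_init__(self):
        super().__post_init__()
        _require(0.0 < self.Q_bar <= self.Q_max, "Q_bar", "must lie in (0, Q_max]")
        if self.Q_bar > 0.25 * self.Q_max:
            warnings.warn(
                "Q_bar should be far below Q_max (it represents the mean population "
                "firing rate during wake, not the single-neuron maximum)",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# Canonical human parameter sets
# ---------------------------------------------------------------------------

#: Phase of the circadian drive chosen so that, at the canonical human
#: parameters, sleep onset of the converged cycle falls in the late evening
#: (clock time is an arbitrary reference in these autonomous models).
_HUMAN_ALPHA = math.pi / 9.0


def pr_human(asymptote_form: str = "linear") -> PRParams:
    """Canonical human parameter set of the mutual-inhibition model.

    Values are the standard set of the Phillips-Robinson flip-flop model
    with the mean circadian drive folded into ``D0_v`` and all weights
    positive.  This set produces a converged monophasic ~24-h sleep-wake
    cycle (asserted in the test-suite).
    """
    return PRParams(
        Q_max=100.0,
        theta=10.0,
        sigma=3.0,
        nu_vm=2.1,
        nu_mv=1.8,
        nu_vh=1.0,
        D0_v=-13.05,
        A=1.3,
        chi=45.0,
        mu_h=4.4,
        tau=10.0,
        circadian=CircadianWaveform(amplitude=2.9, alpha=_HUMAN_ALPHA),
        asymptote_form=asymptote_form,
    )


def _load_param_file(name: str):
    from . import io  # local import to avoid a cycle

    import importlib.resources as res

    with res.files("sleepdyn").joinpath("params", name).open("r") as fh:
        return io.params_from_dict(io._json_load(fh))


def pr_switch_human() -> PRSwitchParams:
    """Hard-switch human set, derived by calibration from :func:`pr_human`."""
    return _load_param_file("pr_switch_human.json")


def two_process_human() -> TwoProcessParams:
    """Human-equivalent two-process set, derived by calibration from :func:`pr_human`."""
    return _load_param_file("two_process_human.json")
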