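# Methods

This note records the models as implemented, the parameter choices, the
numerical procedures, and the design decisions taken where more than one
reasonable construction exists.

## Models and state

**Two-process model.** State is the scalar pressure `H` plus a binary
wake/sleep label.  Within an episode `H` follows the closed-form
exponential toward the active asymptote (`mu` in wake with time constant
`chi_w`; `lower`, default 0, in sleep with `chi_s`).  Thresholds are
`H0_plus + C(t)` and `H0_minus + C(t)` with a shared circadian waveform
`C(t) = a Σ_k c_k sin(k(ωt + α))`, fundamental coefficient 1, ω = 2π/24 h⁻¹
by default.  A negative amplitude is permitted and is how a *drive*
modulation (high at night) is expressed as a *threshold* modulation (low
at night) when translating from the neuronal model.

**Mutual-inhibition model.** State is `(V_v, V_m, H)` — mean cell-body
potentials (mV relative to rest) of the VLPO and MA populations and the
homeostatic pressure (concentration-like units, e.g. nM of a somnogen
such as adenosine).  The wake/sleep label is defined by the MA firing
rate crossing 1 s⁻¹, which differs from the pressure extrema by a few
minutes; both crossing directions are event-located.  The hard-switch
variant replaces the sigmoid by `Q̄·[V > V_th]` and is integrated as a
piecewise-linear system with terminal events at the switch voltage.

## Default parameters

`pr_human()` ships the canonical human set of the mutual-inhibition
model: `Q_max = 100 s⁻¹`, `θ = 10 mV`, `σ′ = 3 mV`, `ν_vm = 2.1 mV s`,
`ν_mv = 1.8 mV s`, `ν_vh = 1 mV per pressure unit`, `μ_h = 4.4 pressure·s`,
`χ = 45 h`, `τ = 10 s`, `A = 1.3 mV`, circadian amplitude `2.9 mV`, mean
drive folded into `D0_v = −13.05 mV` (all weights positive, inhibition
carrying explicit signs).  The circadian phase `α = π/9` only fixes the
clock reference; it is chosen so the converged cycle falls asleep in the
late evening.  The test-suite verifies this set produces a converged
monophasic 24-h cycle (≈8.6 h sleep, wake MA firing ≈5 s⁻¹, pressure
range ≈12.1–15.1) before anything else is built on it.

`two_process_human()` and `pr_switch_human()` are *derived* sets: frozen
outputs of the calibration pipeline below, regenerated and checked by the
test-suite.  Their provenance is recorded inside the files.

## Slow manifold and saddle-node curves

At frozen drives the fast subsystem reduces to a scalar equation in
`V_v`; equilibria are found by a dense sign-change scan (grid step 0.02 mV
over ±80 mV) polished by Brent's method — one or three solutions, the
outer ones being the wake (low `V_v`) and sleep branches.  Folds solve
the tangency condition `ν_vm ν_mv Q′(V_m) Q′(V_v) = 1` along the branch
parametrisation `D_v(V_v)`; root-finding on the derivative uses the same
scan-then-Brent scheme, which is robust near fold coalescence because the
bracket comes from the sign structure, not from a Newton start.  The fold
pair `(D_v⁻, D_v⁺)` bounds the bistable band of VLPO drives (≈1.45–2.46 mV
at defaults).  Tabulating the folds against the MA drive `D_m` gives the
saddle-node curve used for wake effort; along it the reachable VLPO drive
saturates near `ν_vm Q_max` (the "corner"), beyond which wake cannot be
maintained.

## Calibration of the hard switch and the two-process equivalent

Given a sigmoid-model parameter set with a converged monophasic cycle:

1. the fold drives identify the mean thresholds physiologically
   (`H0± = (D_v± − D0_v)/ν_vh`);
2. one converged cycle is integrated densely and the pressure extrema
   `(t_min, H_min)`, `(t_max, H_max)` are extracted with quadratic
   sub-step interpolation;
3. the mapped model is anchored so its closed orbit switches exactly at
   the extrema *times*: with the lower asymptote fixed at 0 the sleep
   exponential from `(t_max, H_max)` arrives at `t_min` at a value
   `H_arrive` close to (but not exactly) `H_min`; `mu` is chosen so the
   wake exponential joins `(t_min, H_arrive)` to `(t_max, H_max)`, and the
   mean thresholds are set so the threshold curves pass through the two
   switch points.  The fold-based identification is reported alongside;
   at defaults the two differ by ≲0.2 pressure units (the dynamic delay
   of the fast transition past the fold).  The residual `H_min − H_arrive`
   (≈0.08 at defaults) is exposed in the equivalence report rather than
   hidden: with a zero lower asymptote the sleep phase cannot match both
   the time and the value of the minimum, and the times are what the
   construction preserves.
4. switch parameters follow from the exact equivalence relations:
   `Q̄ = mu/μ_h` (the mean wake firing rate), `V_th = ν_vh H0⁻ + D0_v`,
   and — a point the equivalence forces — a rescaled inhibition weight
   `ν_vm^switch = ν_vh (H0⁺ − H0⁻)/Q̄`.  The full model's fold gap (≈1 mV)
   is much smaller than `ν_vm Q̄` (≈10 mV) because the VLPO potential at
   the two folds differs between branches, a cancellation the
   single-voltage switch cannot express; without the rescaling the switch
   model's upper threshold would sit above its asymptote and no
   wake-to-sleep switch would ever occur.  `A` is raised to `V_th + 0.5 mV`
   when necessary so the MA can fire at all; on the slow timescale `A`
   enters nowhere else.

Calibration is a fixed point on a switch-model input (the relations are
exact there), which the tests verify.  The equivalence report compares
full-sigmoid, hard-switch and mapped two-process trajectories from
matched states over ten days: at defaults the switch and two-process
transitions coincide to under a minute (the residual is the fast
relaxation `τ ln(...)` plus the O(τ/χ) slow-manifold error), the full
sigmoid model stays within ~6 minutes (the intrinsic offset between the
firing-rate label and the pressure extrema), and the extrema times match
to under half a minute.

`mu` retains some dependence on `chi` through the portion of the firing
curve the cycle visits; following the fixed-asymptote policy, calibration
is performed once at the default point and the asymptotes are *not*
recalibrated during parameter scans.  This shifts the mapped model's
bifurcation points relative to the neuronal model's (the
monophasic→biphasic transition sits at χ ≈ 18.4 h for the mapped model vs
≈ 16.0 h for the neuronal model, a ~14% shift verified in the tests).

## Return map, classification, grazing

`next_onset` propagates an onset through exactly one sleep and one wake
episode semi-analytically: the closed forms are scanned at 0.01-h
resolution for a sign change of `H − threshold`, then Brent-polished to
1e-12 h.  Ties at a threshold resolve in favour of the current state,
which suppresses chattering at tangencies; only excursions within ~1e-6
pressure units of a perfect tangency can slip between scan points, and
those are exactly the cases the grazing machinery treats explicitly.
Episodes shorter than one minute are merged before any pattern statistic.

The tabulated map (default 241 nodes on [0, 24)) flags a discontinuity
where adjacent values jump by more than 0.5 h — well above interpolation
error, well below genuine jumps of hours — refines it by bisection to
1e-9 h, and certifies it by launching trajectories from both sides and
measuring the minimum interior gap to the thresholds (a tangency: the
certificate distance is <1e-6 pressure units with near-zero gap
derivative).  Fixed points are roots of `map(t) − t` (mod 24) on the
continuous segments, with central-difference slopes whose step shrinks
near discontinuities.  Pattern period is the smallest integer number of
days after which the onset sequence repeats mod 24 h within 0.01 h (two
full periods are compared); periods above 16 days are reported
unconverged rather than searched — free-running (a = 0) cycles are
therefore "unconverged" by design, since the period detector certifies
entrained states.

Scans warm-start each grid point from the previous point's final state
(attractor continuation, which stabilises classification near
bifurcations) with a 30-day discard and a 32-day classification window.
`locate_grazing` bisects the parameter on the episodes-per-day count and
certifies the result on the lower-count side, where the converged
trajectory grazes: interior minimum gap < 1e-4 pressure units with
matching time-derivatives, and a map discontinuity whose jump straddles
the diagonal.  Between n and n+1 daily episodes lies a period-2 window
(an extra episode on alternate days); `find_period2_window` probes
geometrically below the grazing point and bisects the window's lower
edge.

## Deprivation and wake effort

Deprivation protocols are lists of enforced-wake intervals.  The
two-process model simply continues the wake exponential through them (the
upper threshold is, in effect, moved with the state).  The neuronal model
is integrated on the slow manifold: branch-tracked `H`-only dynamics with
fold-crossing events, and during enforced wake past the natural fold the
state follows the saddle-node boundary of the `D_m`-boosted system (the
ghost of the wake state).  Wake effort is `ΔD_m(t) = D_m^fold(D_v(t)) − A`,
clipped at zero, NaN beyond the fold curve's reach; the two-process
counterpart applies a least-squares linear-plus-quadratic fit of that
same fold geometry to the pressure excess `H − H⁺(t)`.  The fit window
spans the excess reached after four days of enforced wake (≈10 pressure
units at defaults); over it the relation is close to linear (a pure-line
refit already fits to ~6% rms of range; the quadratic fit to ~1%).

Two production forms are implemented.  The linear form `P = μ_h Q_m`
makes the asymptote track the MA firing rate; on the ghost this feedback
has gain above one at the default parameters (`μ_h ν_vh dQ^fold/dD_v > 1`),
so production grows without levelling off and the effort diverges from
the two-process computation — the known "unrealistically high production
at high firing rates" that motivated the saturating variant.  The
saturating form is Michaelis–Menten,
`P = μ_h (Q₀ + Q_h) Q/(Q + Q_h)` with `Q_h = 1 s⁻¹`, normalised at a
reference rate `Q₀` so that it matches the linear form there; the
comparison pipeline sets `Q₀` to the calibrated mean wake firing rate
`mu/μ_h`, leaving the normal cycle unchanged while limiting production on
the ghost.  The exact saturating expression used in the wake-effort
literature is not reproduced here; this form realises its documented
purpose and its two free choices (`Q_h`, the normalisation point) are
fixed once, as above.  With it, the two effort formulations agree to a
few percent through day 3 and differ by ≈8–10% at day 4, the residual
being precisely the remaining firing-rate dependence of the asymptote.
Relative differences are quoted on the daily effort maxima and at the
protocol end; inside the circadian dips both efforts pass through zero
and pointwise ratios are ill-conditioned (absolute agreement, <0.4 mV,
holds there).

A symmetric "sleep effort" (lowering `D_m` to hold sleep) is implemented
as the span of the sleep-side fold under reduced MA drive and reported
only as an inequality: at defaults the achievable wake extension exceeds
the achievable sleep extension (the sleep ghost is less prominent).  No
quantitative claims are attached to it.

## What the defaults do and do not show

All experiments are self-generated from parameter sets; there is no
stochastic component anywhere, so every run is exactly reproducible from
its resolved configuration.  The canonical set reproduces the *structure*
of human sleep regulation — a monophasic entrained cycle, realistic MA/VLPO
firing ranges, episode-adding under faster homeostatic clearance, bounded
wake effort — but none of the quantities here have been fitted to recorded
human or animal data: clock times are a phase convention, the pressure
unit is model-internal, and passing tests certify internal consistency
and cross-model equivalence, not empirical adequacy.  EEG markers,
light-driven circadian entrainment, and chronic sleep-restriction
asymptote dynamics are out of scope.

## Numerical settings

Stiff integration of the full neuronal model uses LSODA with
rtol = atol = 1e-8 and a 1-h step cap (the fast/slow gap is ~1.6×10⁴);
slow-manifold deprivation dynamics use rtol 1e-9/atol 1e-10.  Event
location uses the integrator's root-finding; two-process events use the
semi-analytic scan + Brent scheme above.  Problem sizes in the shipped
tests and the acceptance script (10-day equivalence comparisons, 30+32-day
scan windows, 4-day deprivation, 241–481-node maps) were chosen as the
smallest at which the measured quantities are stable to well within their
asserted tolerances.
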