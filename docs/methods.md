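# Methods

## The model

`rtgrowth` simulates a well-mixed solid tumour as four coupled ODEs for the
undamaged viable volume fraction `T`, the sub-lethally damaged fraction
`T_S`, the lethally damaged (dead) fraction `T_R`, and the oxygen
concentration `c` (relative to the vascular concentration). With
`Σ = T + T_S + T_R + V0` the total occupied volume and `H` the unit step
(`H(0) = 1`),

```
dT/dt   = q2 c T (1-Σ) - [δ1 (c_min - c) H(c_min - c) + λ c R + ν c R] T + μ T_S
dT_S/dt = θ2 q2 c T_S (1-Σ) - [δ1S (c_min - c) H(c_min - c) + λ_S c R + μ + ξ] T_S + ν c R T
dT_R/dt = λ c R T + (ξ + λ_S c R) T_S - η_R T_R
dc/dt   = g (1-c) V0 - q1 (T + θ1 T_S) c - q3 (T + θ2 T_S) c (1-Σ)
```

Two growth-arrest mechanisms are built in. Proliferation is proportional to
the free space `1 - Σ`, so growth stops at full occupancy with no cell
death (**space-limited**, SL). Below the anoxic threshold `c_min`, cells
die at a rate proportional to `c_min - c`, so growth can instead arrest
with proliferation and starvation death in balance (**nutrient-limited**,
NL). Radiation (dose rate `R`, nonzero only during fraction windows)
converts `T` to `T_S` and `T_R` at rates proportional to `c R` — the oxygen
enhancement of radiosensitivity — and `T_S` either repairs (rate `μ`),
accumulates lethal damage (`λ_S c R`), or dies of mitotic catastrophe
(`ξ`). Dead cells occupy space until cleared (`η_R`). Radiation effects on
the vasculature are deliberately excluded: `V0` is a fixed parameter, which
is what makes the steady-state structure treatment-invariant.

The system is dimensionless; the time unit is one minute (chosen to resolve
intrafraction damage kinetics), so all scheduling arithmetic is in minutes.

## Parameters

Defaults (all dimensionless):

| parameter | meaning | default |
|---|---|---|
| `q1` | O₂ consumption, maintenance | free, `[1e-2, 10]` |
| `q3` | O₂ consumption, proliferation | free, `[1e-2, 10]` |
| `V0` | vascular volume fraction | free, `(0, 5e-3]` |
| `c_min` | anoxic threshold | 1e-2 |
| `g` | O₂ exchange rate per unit vessel volume | 5 |
| `k` | proliferation/consumption conversion, `q2 = k q3` | 1e-2 |
| `θ1`, `θ2` | damaged-cell rate multipliers (`q1S = θ1 q1`, `q2S = q3S/... = θ2 ·`) | 10, 0.1 |
| `ν` | sub-lethal damage rate | 10 |
| `λ = λ_S` | lethal damage rates | 1 |
| `μ` | repair rate | 5e-3 |
| `ξ` | mitotic-catastrophe death rate (≈24 h half-life) | 5e-4 |
| `η_R` | dead-cell clearance rate | 5e-5 |

Derived couplings (`q2 = k q3`, `δ1 = q2`, `δ1S = θ2 q2`, `q1S = θ1 q1`,
`q2S = θ2 q2`, `q3S = θ2 q3`) are re-derived whenever a base parameter
changes; explicitly pinning a derived value is allowed but logged, so the
couplings never break silently.

## Steady states, regimes and thresholds

With `R = 0` and no damaged cells the SL equilibrium is closed-form:
`T* = 1 - V0`, `c* = g V0 / (g V0 + q1 (1 - V0))`, admissible iff
`c* ≥ c_min`. On the NL branch the viable-cell balance (with `δ1 = q2`)
gives `c = c_min / (2 - Σ)` — hence any admissible NL state has
`c_min/2 < c* < c_min` — and the oxygen balance becomes one nonlinear
equation in `T`, solved by scanning 400 uniform brackets over
`(0, 1 - V0)` and polishing with Brent's method. Stability is decided from
the central-difference Jacobian (step 1e-7) of the reduced two-variable
system, requiring all eigenvalue real parts below −1e-12; if several stable
roots existed, the smallest (the attractor of small tumours) would be
returned. Admissibility conventions: `c* ≥ c_min` for SL (non-strict),
`c* < c_min` for NL (strict).

`V_N = c_min q1 / (g (1 - c_min) + c_min q1)` is closed-form (the V0 at
which the SL oxygen level touches `c_min`). `V_S` is found by bisection (to
1e-9 in V0) on the predicate "NL state admissible", which is monotone in V0
by the bifurcation structure; when the NL state is already inadmissible
just above `V_N` there is no bistable window and `V_S` is reported as
undefined. The proximity index `V_d = (V0 - V_N)/(V_S - V_N)` is defined
only in the bistable regime. Note that `V_d` is hypersensitive to `V_N`
when `V0 - V_N` is tiny; reported values agree with an independent
forward-integration check of the regime boundaries, but quantities of
magnitude ~1e-3 should be quoted with that sensitivity in mind.

A structural result the package tests rather than proves: every steady
state of the full four-variable system with `R = 0` has `T_S* = T_R* = 0`
(the dead-cell balance forces `T_S* = (η_R/ξ) T_R*`, and nonzero damaged
pools contradict the viable-cell balance in both oxygen regimes). Treatment
therefore never creates new equilibria — it can only move a bistable tumour
between the NL and SL basins.

## Scheduling conventions

Fractions deliver `D` Gy in `δ_R = 10` min windows at dose rate
`R = D/(δ_R R_max)` with `R_max = 1` Gy/min. The week is 10080 min with
`t = 0` at Monday 00:00; fractions start at the top of the day on Mon–Fri
(5/week), Mon/Wed/Fri (3/week) or Monday (1/week). The fraction count is
`floor(80 Gy / D)`, which reproduces the reference course durations
(40 fractions/8 weeks at 2 Gy; 26 fractions giving 5.2 or 8.67 weeks at
3 Gy) — note this is "total dose never exceeds the cap", not "closest
multiple of D to 80".

## Numerical integration

LSODA (rtol 1e-8, atol 1e-10 by default) with the right-hand side compiled
by numba. The oxygen variable relaxes on a ~1/(q1 T) minute timescale while
the volumes evolve over weeks, so the system is stiff for purely explicit
pairs; LSODA integrates a full 8-week course ~3× faster than RK45 at equal
tolerance and the two agree to more than four significant figures on all
reported metrics. Integration is restarted at every fraction-window
boundary (the forcing is discontinuous there). The starvation switch at
`c = c_min` keeps the RHS continuous but kinks it; crossings are located
with direction-aware terminal events and integration restarts a forward-
Euler nudge (1e-7 min) past the located crossing, which prevents the event
from re-firing at the restart point.

Accepted states are projected onto the physical region: components are
clipped at zero and the cell volumes rescaled if `Σ` overshoots 1, with a
hard error if any violation exceeds 1e-7. The exact flow preserves these
bounds; a tolerance-controlled solver can overshoot by O(rtol) when the
solution approaches a boundary asymptotically (measured ~2e-9 at default
tolerances near full occupancy, shrinking to ~2e-12 at rtol 1e-10), so the
projection magnitude is bounded by solver error and audited.

Post-treatment attractors are labelled by continuing with `R = 0` to
2.5e5 min and matching the terminal state to an equilibrium
(`|T - T*| < 1e-4`, oxygen on the matching side of `c_min`, damaged pools
below 1e-4); if the state is still in transit the horizon doubles, up to
five times, before an error is raised. The equilibria are separated by
ΔT ≳ 0.1, so the matching tolerance is not delicate.

## Treatment-response metrics

Responses are summarised by time averages over the **last week of
treatment**: the final 10080 minutes ending at the Sunday of the calendar
week containing the last fraction (a full 10080-min window even when the
final week is partial, so the averaging length is protocol-independent).
Averages use trapezoidal quadrature of the solver's dense output at
1-minute resolution. From the averages and the pre-treatment steady state
`T0` (`Σ0 = T0 + V0`):

```
Δ_viable = 100 ((T̄ + T̄_S) - T0) / T0
Δ_total  = 100 (Σ̄ - Σ0) / Σ0
%X       = 100 X̄ / Σ0   for X in {T, T_S, T_R, V0}
```

with the exact identity `Δ_total = %T + %T_S + %T_R + %V0 - 100`. The
window definition matters quantitatively: a Mon–Fri-only window (treatment
days only) shifts `Δ_viable` by up to ~0.5 percentage points for
nutrient-limited tumours, because weekend regrowth raises the full-week
mean. The full calendar week is used throughout — it weighs treated and
recovery days alike and keeps the metric comparable across weekly
fraction counts.

Periodicity of the weekly waveforms (used as a convergence diagnostic) is
measured pointwise between weeks 7 and 8, normalising volume compartments
by the tumour's initial total volume `Σ0` and oxygen by its weekly
maximum. Per-variable self-normalisation is deliberately not used: the
dead-cell pool equilibrates on a 1/η_R ≈ 2-week timescale, so `T_R` still
drifts by ~1% of its own (small) scale in the final week even though every
compartment is stationary to <0.4% of the tumour's size.

## Virtual cohorts

A cohort fixes `V0` per regime (NL 0.0005, SL 0.005, BS 0.00275) and draws
`(q1, q3)` pairs uniformly from `[1e-2, 10]²`, keeping those whose
steady-state classification at that `V0` matches the requested regime
(rejection sampling, so the accepted points are uniform over the regime's
region, not over the box). Rejection against the classifier was chosen
over precomputed per-regime bounds: it needs no closed-form description of
the region boundary and cannot clip the region at its margins, at the cost
of wasted proposals (acceptance runs from ~100% for NL down to ~5% for BS,
a negligible overhead next to the simulations). Sampling is
driven by a single seeded PCG64 generator drawing sequentially; identical
seeds give identical cohorts. Batch runs record individual member failures
without aborting, and report medians, quartiles and responder fractions of
both Δ metrics.

Cohort sizes: the study value is N = 250 per regime (used by
`scripts/acceptance.py`); the test suite samples N = 100 per regime to
keep a full run of the suite in single-digit minutes.

## What the experiments do and do not show

All inputs are generated by the package itself — parameter sets, protocols
and cohorts; there is no external data. Passing tests show that the
*model's* reported behaviour is reproduced (regime structure, typical and
extremal responses, dose/frequency effects, steady-state switching), not
that real tumours behave this way. Known model limitations: no
angiogenesis or vascular damage (fixed `V0`), no spatial structure, no
cell-cycle phase dependence of radiosensitivity, instantaneous well-mixed
oxygen, and survival is not calibrated to clinical dose-response data (the
linear-quadratic formalism is intentionally not used).
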