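"""Event-aware numerical integration over growth and treatment horizons.

The dose rate R(t) is piecewise constant, so integration is restarted at
every fraction-window boundary rather than letting the solver step across a
forcing discontinuity.  The starvation switch at ``c = c_min`` makes the
right-hand side continuous but non-smooth; crossings are located with
direction-aware solver events and integration restarts just past the located
crossing so the switch is never smeared across a step.

The default solver is LSODA: the oxygen kinetics are much faster than the
cell-volume kinetics (relaxation rate up to ``q1*T`` per minute against
treatment horizons of 1e5 minutes), which makes the system stiff for a
purely explicit pair.  Tolerances default to rtol 1e-8 / atol 1e-10, tight
enough that the response metrics are solver-converged to well below their
quoted precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from ._compiled import rhs_core
from .model import ModelParameters
from .schedule import Schedule
from .steady_state import (
    Equilibrium,
    classify_regime,
    nl_steady_state,
    sl_steady_state,
)

__all__ = [
    "Trajectory",
    "simulate_growth",
    "simulate_treatment",
    "pretreatment_state",
    "post_treatment_attractor",
    "DEFAULT_GROWTH_HORIZON",
    "DEFAULT_POST_TREATMENT_HORIZON",
]

#: Horizon (minutes) for untreated growth-to-steady-state runs.
DEFAULT_GROWTH_HORIZON = 2e5
#: Horizon (minutes) for post-treatment relaxation runs.
DEFAULT_POST_TREATMENT_HORIZON = 2.5e5

#: Time nudge (minutes) applied across a located c = c_min crossing.
_SWITCH_EPS = 1e-7
#: Invariant violations beyond this cannot be explained by solver error.
_HARD_INVARIANT_TOL = 1e-7
#: |T - T*| tolerance for matching a terminal state to an equilibrium.
_MATCH_TOL = 1e-4
#: Damaged compartments must have decayed below this for attractor labelling.
_DAMAGED_TOL = 1e-4


@dataclass
class Trajectory:
    """Time-stamped solution of one integration.

    ``t`` is strictly increasing (minutes); ``y`` has shape (4, n) with rows
    T, TS, TR, c.  ``segments`` keeps the solver's dense-output interpolants
    so the solution can be resampled exactly (used for quadrature-accurate
    time averages); ``events`` logs fraction boundaries and anoxic-threshold
    crossings as ``(time, kind)`` pairs.
    """

    t: np.ndarray
    y: np.ndarray
    params: ModelParameters
    schedule: Schedule | None = None
    events: list[tuple[float, str]] = field(default_factory=list)
    segments: list = field(default_factory=list)  # (t0, t1, OdeSolution)

    @property
    def T(self) -> np.ndarray:
        return self.y[0]

    @property
    def TS(self) -> np.ndarray:
        return self.y[1]

    @property
    def TR(self) -> np.ndarray:
        return self.y[2]

    @property
    def c(self) -> np.ndarray:
        return self.y[3]

    @property
    def sigma(self) -> np.ndarray:
        return self.y[0] + self.y[1] + self.y[2] + self.params.V0

    @property
    def final_state(self) -> np.ndarray:
        return self.y[:, -1]

    def sample(self, times) -> np.ndarray:
        """Evaluate the dense solution at arbitrary times within the horizon."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if times.size and (times[0] < self.t[0] - 1e-9 or times[-1] > self.t[-1] + 1e-9):
            raise ValueError(
                f"requested times [{times[0]}, {times[-1]}] outside the "
                f"integrated horizon [{self.t[0]}, {self.t[-1]}]"
            )
        out = np.empty((4, times.size))
        starts = np.array([seg[0] for seg in self.segments])
        idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(self.segments) - 1)
        for k in np.unique(idx):
            mask = idx == k
            out[:, mask] = self.segments[k][2](times[mask])
        return out

    def to_frame(self):
        """Tidy table with columns t_min, T, TS, TR, c, Sigma, R."""
        import pandas as pd

        from .schedule import dose_rate

        R = (dose_rate(self.t, self.schedule) if self.schedule is not None
             else np.zeros_like(self.t))
        return pd.DataFrame({
            "t_min": self.t, "T": self.T, "TS": self.TS, "TR": self.TR,
            "c": self.c, "Sigma": self.sigma, "R": R,
        })

    def extend(self, other: "Trajectory") -> "Trajectory":
        """Concatenate a continuation run (must start where this one ends)."""
        if abs(other.t[0] - self.t[-1]) > 1e-6:
            raise ValueError("continuation must start at the end of this trajectory")
        return Trajectory(
            t=np.concatenate([self.t, other.t[1:]]),
            y=np.concatenate([self.y, other.y[:, 1:]], axis=1),
            params=self.params,
            schedule=self.schedule,
            events=self.events + other.events,
            segments=self.segments + other.segments,
        )


def _event_factory(c_min: float, direction: int):
    def event(t, y, pv, R):
        return y[3] - c_min
    event.terminal = True
    event.direction = direction
    return event


def _integrate(
    params: ModelParameters,
    y0: np.ndarray,
    pieces: Sequence[tuple[float, float, float]],
    *,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    locate_switch: bool = True,
    max_switch_restarts: int = 5000,
) -> Trajectory:
    """Integrate over ``pieces`` of (t_start, t_end, R) with constant R each."""
    pv = params.as_vector()
    c_min = params.c_min
    ev_up = _event_factory(c_min, +1)
    ev_dn = _event_factory(c_min, -1)
    y = np.asarray(y0, dtype=float).copy()
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    segments: list = []
    events: list[tuple[float, str]] = []
    n_restarts = 0
    for a, b, R in pieces:
        if b <= a:
            continue
        if R > 0:
            events.append((a, "fraction_start"))
        t0 = a
        while t0 < b - 1e-9:
            ev = (ev_up if y[3] < c_min else ev_dn) if locate_switch else None
            sol = solve_ivp(
                rhs_core, (t0, b), y, args=(pv, R), method=method,
                rtol=rtol, atol=atol, dense_output=True,
                events=ev if ev is None else [ev],
            )
            if sol.status < 0:
                raise RuntimeError(
                    f"integration failed on [{t0}, {b}] (R={R}): {sol.message}"
                )
            keep = slice(1, None) if ts and sol.t[0] == ts[-1][-1] else slice(None)
            ts.append(sol.t[keep])
            ys.append(sol.y[:, keep])
            segments.append((sol.t[0], sol.t[-1], sol.sol))
            y = sol.y[:, -1].copy()
            t0 = sol.t[-1]
            if sol.status == 1:  # located a c = c_min crossing
                events.append((t0, f"c_min_{'up' if ev is ev_up else 'down'}"))
                # Euler-nudge across the crossing; the RHS is continuous there
                # so the local error is O(eps^2) with eps = 1e-7 minutes.
                y = y + _SWITCH_EPS * rhs_core(t0, y, pv, R)
                t0 = t0 + _SWITCH_EPS
                n_restarts += 1
                if n_restarts > max_switch_restarts:
                    raise RuntimeError(
                        f"more than {max_switch_restarts} anoxic-threshold "
                        f"crossings; the trajectory is chattering at c = c_min"
                    )
        if R > 0:
            events.append((b, "fraction_end"))
    t_arr = np.concatenate(ts)
    y_arr = np.concatenate(ys, axis=1)
    _enforce_state_invariants(y_arr, params)
    return Trajectory(t=t_arr, y=y_arr, params=params, events=events, segments=segments)


def _enforce_state_invariants(y: np.ndarray, params: ModelParameters) -> None:
    """Project accepted states onto the physical region (in place).

    The exact flow preserves nonnegativity, ``Sigma <= 1`` and
    ``0 <= c <= 1``, but a tolerance-controlled solver may overshoot these
    boundaries by O(rtol) when the solution approaches them asymptotically
    (e.g. full occupancy in the space-limited regime).  Violations within
    solver error are projected away — negatives clipped, cell volumes
    rescaled so Sigma <= 1 — while anything larger than 1e-7 indicates a
    genuine integration failure and raises.
    """
    worst_neg = float(y.min(initial=0.0))
    sigma = y[0] + y[1] + y[2] + params.V0
    sigma_excess = float(sigma.max(initial=0.0)) - 1.0
    c_excess = float(y[3].max(initial=0.0)) - 1.0
    if worst_neg < -_HARD_INVARIANT_TOL or sigma_excess > _HARD_INVARIANT_TOL \
            or c_excess > _HARD_INVARIANT_TOL:
        raise RuntimeError(
            f"integrated trajectory violates state invariants beyond solver "
            f"error (min component {worst_neg:.3g}, Sigma excess "
            f"{sigma_excess:.3g}, c excess {c_excess:.3g})"
        )
    np.clip(y, 0.0, None, out=y)
    np.clip(y[3], None, 1.0, out=y[3])
    if sigma_excess > 0.0:
        over = sigma > 1.0
        if np.any(over):
            scale = (1.0 - params.V0) / (sigma[over] - params.V0)
            y[:3, over] *= scale


def simulate_growth(
    params: ModelParameters,
    initial_state=(0.05, 0.0, 0.0, 1.0),
    t_end: float = DEFAULT_GROWTH_HORIZON,
    **solver_options,
) -> Trajectory:
    """Integrate the untreated model (R = 0) from ``initial_state``.

    The default initial state is a small well-oxygenated tumour, which for
    bistable parameter sets converges to the NL equilibrium.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end!r}")
    y0 = np.asarray(initial_state, dtype=float)
    return _integrate(params, y0, [(0.0, float(t_end), 0.0)], **solver_options)


def pretreatment_state(params: ModelParameters) -> Equilibrium:
    """Steady state used as the initial condition for treatment runs.

    Monostable tumours start at their unique equilibrium.  Bistable tumours
    start at the NL equilibrium — the attractor of physically realistic
    small initial tumours.
    """
    regime = classify_regime(params)
    if regime == "SL":
        return sl_steady_state(params)
    return nl_steady_state(params)


def _schedule_pieces(schedule: Schedule, t_end: float) -> list[tuple[float, float, float]]:
    pieces: list[tuple[float, float, float]] = []
    cursor = 0.0
    R = schedule.R_value
    for start, end in schedule.windows:
        if start >= t_end:
            break
        if start > cursor:
            pieces.append((cursor, start, 0.0))
        pieces.append((start, min(end, t_end), R))
        cursor = min(end, t_end)
    if cursor < t_end:
        pieces.append((cursor, t_end, 0.0))
    return pieces


def simulate_treatment(
    params: ModelParameters,
    schedule: Schedule,
    t_end: float | None = None,
    **solver_options,
) -> Trajectory:
    """Integrate a treatment course from the untreated steady state.

    The initial condition is ``(T*, 0, 0, c*)`` from
    :func:`pretreatment_state`.  ``t_end`` defaults to the end of the
    calendar week containing the last fraction, so the final-week averaging
    window is always covered; it must not fall before the last window ends.
    A null schedule reproduces treatment-free growth from the steady state.
    """
    if t_end is None:
        t_end = schedule.end_of_last_week if not schedule.is_null else DEFAULT_GROWTH_HORIZON
    if not schedule.is_null and t_end < schedule.treatment_end:
        raise ValueError(
            f"t_end={t_end} ends before the last fraction window at "
            f"{schedule.treatment_end} min"
        )
    eq = pretreatment_state(params)
    y0 = np.array([eq.T, 0.0, 0.0, eq.c])
    traj = _integrate(params, y0, _schedule_pieces(schedule, float(t_end)),
                      **solver_options)
    traj.schedule = schedule
    return traj


def post_treatment_attractor(
    params: ModelParameters,
    schedule: Schedule,
    t_end_long: float = DEFAULT_POST_TREATMENT_HORIZON,
    *,
    max_extensions: int = 5,
    treatment_trajectory: Trajectory | None = None,
    return_trajectory: bool = False,
    **solver_options,
):
    """Label the equilibrium a treated tumour relaxes to after the course.

    Integration continues with R = 0 beyond the last fraction until the
    state matches an admissible equilibrium: |T - T*| below 1e-4, oxygen on
    the matching side of c_min, and both damaged compartments decayed away.
    If the state is still in transit at ``t_end_long`` the horizon is
    doubled, up to ``max_extensions`` times, before giving up.

    Monostable tumours always return their pre-treatment regime; bistable
    tumours may be driven across the basin boundary by treatment and settle
    on the SL branch instead of the original NL one.
    """
    traj = treatment_trajectory
    if traj is None:
        traj = simulate_treatment(params, schedule, **solver_options)
    nl = nl_steady_state(params)
    sl = sl_steady_state(params)
    horizon = max(float(t_end_long), traj.t[-1] + 1.0)
    for _ in range(max_extensions + 1):
        cont = _integrate(params, traj.final_state,
                          [(traj.t[-1], horizon, 0.0)], **solver_options)
        traj = traj.extend(cont)
        label = _match_equilibrium(traj.final_state, nl, sl, params.c_min)
        if label is not None:
            return (label, traj) if return_trajectory else label
        horizon = traj.t[-1] + (horizon - traj.t[0])  # double the elapsed span
    state = traj.final_state
    raise RuntimeError(
        f"terminal state T={state[0]:.6g}, TS={state[1]:.3g}, TR={state[2]:.3g}, "
        f"c={state[3]:.6g} matches neither equilibrium after t={traj.t[-1]:.3g} min; "
        f"a longer horizon is advised"
    )


def _match_equilibrium(state, nl, sl, c_min) -> str | None:
    T, TS, TR, c = state
    if TS > _DAMAGED_TOL or TR > _DAMAGED_TOL:
        return None
    if nl is not None and abs(T - nl.T) < _MATCH_TOL and c < c_min:
        return "NL"
    if sl is not None and abs(T - sl.T) < _MATCH_TOL and c >= c_min:
        return "SL"
    return None
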