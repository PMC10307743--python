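"""Treatment-free equilibria, growth-regime classification and thresholds.

With no irradiation and no damaged cells the model reduces to two variables
(T, c) and admits two families of physically realistic equilibria:

* **space limited (SL)** — proliferation stops because the tumour fills all
  available space: ``T* = 1 - V0`` with no cell death, which requires the
  oxygen at equilibrium, ``c* = g V0 / (g V0 + q1 (1 - V0))``, to stay at or
  above the anoxic threshold ``c_min``;
* **nutrient limited (NL)** — proliferation balances starvation-driven death
  below the anoxic threshold.  Setting the viable-cell balance to zero (with
  ``delta1 = q2``) gives ``c = c_min / (2 - Sigma)``; substituting into the
  oxygen balance leaves a single nonlinear equation in T that is solved by
  bracketing on ``T in (0, 1 - V0)``.

Which family is admissible is controlled mainly by the vascular volume V0.
``V_N`` is the threshold below which only NL states exist (the SL oxygen
level reaches ``c_min`` exactly at ``V_N``; it is independent of q3), and —
when the proliferative oxygen demand q3 is large enough relative to q1 —
``V_S > V_N`` is the threshold at and above which only SL states exist.  In
the window ``V_N < V0 < V_S`` both stable states coexist (bistable, BS) and
the proximity index ``V_d = (V0 - V_N) / (V_S - V_N)`` in (0, 1) measures
how close the tumour sits to each monostable regime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from .model import ModelParameters, build_parameters, rhs

__all__ = [
    "Equilibrium",
    "SteadyStateReport",
    "sl_steady_state",
    "nl_steady_state",
    "compute_VN",
    "compute_VS",
    "classify_regime",
    "compute_Vd",
    "steady_state_report",
    "verify_no_damaged_steady_state",
]

#: Eigenvalue threshold for calling an equilibrium stable.
_STABLE_TOL = -1e-12
#: Grid resolution for bracketing NL roots in T.
_N_SCAN = 400


class Equilibrium(NamedTuple):
    T: float
    c: float


@dataclass(frozen=True)
class SteadyStateReport:
    """Admissible equilibria, regime label and V0 thresholds for one tumour."""

    regime: str
    nl: Equilibrium | None
    sl: Equilibrium | None
    V_N: float
    V_S: float | None
    V_d: float | None


def _sl_values(params: ModelParameters) -> Equilibrium:
    """SL equilibrium values regardless of admissibility."""
    T = 1.0 - params.V0
    c = params.g * params.V0 / (params.g * params.V0 + params.q1 * T)
    return Equilibrium(T, c)


def sl_steady_state(params: ModelParameters) -> Equilibrium | None:
    """Space-limited equilibrium, or None when inadmissible (c* < c_min)."""
    eq = _sl_values(params)
    return eq if eq.c >= params.c_min else None


def _reduced_rhs(T: float, c: float, params: ModelParameters) -> np.ndarray:
    """(dT/dt, dc/dt) of the treatment-free two-variable system."""
    free = 1.0 - T - params.V0
    H = 1.0 if params.c_min - c >= 0 else 0.0
    dT = params.q2 * c * T * free - params.delta1 * (params.c_min - c) * H * T
    dc = (params.g * (1.0 - c) * params.V0 - params.q1 * T * c
          - params.q3 * T * c * free)
    return np.array([dT, dc])

def _is_stable(T: float, c: float, params: ModelParameters, h: float = 1e-7) -> bool:
    """Stability of a reduced-system equilibrium via a central-difference Jacobian."""
    J = np.empty((2, 2))
    for j, (dT_, dc_) in enumerate(((h, 0.0), (0.0, h))):
        J[:, j] = (_reduced_rhs(T + dT_, c + dc_, params)
                   - _reduced_rhs(T - dT_, c - dc_, params)) / (2 * h)
    return bool(np.all(np.linalg.eigvals(J).real < _STABLE_TOL))


def _nl_oxygen_residual(T: float, params: ModelParameters) -> float:
    """Oxygen balance along the NL branch c(T) = c_min / (2 - Sigma)."""
    sigma = T + params.V0
    c = params.c_min / (2.0 - sigma)
    return (params.g * (1.0 - c) * params.V0 - params.q1 * T * c
            - params.q3 * T * c * (1.0 - sigma))


def nl_steady_state(params: ModelParameters) -> Equilibrium | None:
    """Stable nutrient-limited equilibrium, or None when inadmissible.

    Roots of the oxygen residual are bracketed on a uniform grid over
    ``T in (0, 1 - V0)`` and polished with Brent's method; each candidate is
    kept only if it lies strictly below the anoxic threshold
    (``c* < c_min``, i.e. ``T* < 1 - V0``) and is linearly stable.  When
    several stable roots exist the smallest (the attractor of small initial
    tumours) is returned.
    """
    Tmax = 1.0 - params.V0
    grid = np.linspace(0.0, Tmax, _N_SCAN + 1)
    vals = np.array([_nl_oxygen_residual(T, params) for T in grid])
    roots: list[float] = []
    for i in range(_N_SCAN):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0.0:
            roots.append(brentq(_nl_oxygen_residual, grid[i], grid[i + 1],
                                args=(params,), xtol=1e-15, rtol=8.9e-16))
    stable: list[Equilibrium] = []
    for T in roots:
        if not (0.0 < T < Tmax):
            continue
        c = params.c_min / (2.0 - (T + params.V0))
        if not (0.0 <= c < params.c_min):
            continue
        if _is_stable(T, c, params):
            stable.append(Equilibrium(T, c))
    if not stable:
        return None
    return min(stable, key=lambda eq: eq.T)


def compute_VN(q1: float, g: float = 5.0, c_min: float = 1e-2) -> float:
    """Vascular-volume threshold below which only NL equilibria exist.

    Closed form from requiring the SL oxygen level to equal the anoxic
    threshold: ``V_N = c_min q1 / (g (1 - c_min) + c_min q1)``.  Independent
    of q3, strictly increasing in q1.
    """
    if q1 <= 0 or g <= 0 or c_min <= 0:
        raise ValueError("q1, g and c_min must be positive")
    return c_min * q1 / (g * (1.0 - c_min) + c_min * q1)


def _nl_admissible_at(V0: float, q1: float, q3: float, g: float, c_min: float) -> bool:
    params = build_parameters(q1, q3, V0, overrides={"g": g, "c_min": c_min},
                              enforce_ranges=False)
    return nl_steady_state(params) is not None


def compute_VS(
    q1: float,
    q3: float,
    g: float = 5.0,
    c_min: float = 1e-2,
    *,
    xtol: float = 1e-9,
) -> float | None:
    """Vascular-volume threshold at/above which only SL equilibria exist.

    Found by bisection on NL admissibility over V0, which is monotone by the
    bifurcation structure (the NL branch terminates as V0 grows).  Returns
    None when no bistable window exists (q3 not sufficiently larger than q1:
    the NL state is already inadmissible just above V_N).
    """
    V_N = compute_VN(q1, g, c_min)
    lo = V_N * (1.0 + 1e-9)
    if not _nl_admissible_at(lo, q1, q3, g, c_min):
        return None
    hi = max(2.0 * V_N, 1e-6)
    while _nl_admissible_at(hi, q1, q3, g, c_min):
        hi *= 2.0
        if hi >= 1.0:
            return None  # NL branch never terminates in the physical range
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if _nl_admissible_at(mid, q1, q3, g, c_min):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def classify_regime(params: ModelParameters) -> str:
    """Growth-regime label: 'NL', 'SL' or 'BS' (both admissible)."""
    nl = nl_steady_state(params)
    sl = sl_steady_state(params)
    if nl is not None and sl is not None:
        return "BS"
    if nl is not None:
        return "NL"
    if sl is not None:
        return "SL"
    raise RuntimeError(
        f"no admissible equilibrium for q1={params.q1}, q3={params.q3}, "
        f"V0={params.V0}; this violates the model's bifurcation structure"
    )


def compute_Vd(params: ModelParameters) -> float:
    """Proximity index ``(V0 - V_N) / (V_S - V_N)`` for a bistable tumour.

    Tends to 0 as V0 approaches the NL-only threshold and to 1 as it
    approaches the SL-only threshold.
    """
    regime = classify_regime(params)
    if regime != "BS":
        raise ValueError(f"V_d is defined only in the bistable regime; tumour is {regime}")
    V_N = compute_VN(params.q1, params.g, params.c_min)
    V_S = compute_VS(params.q1, params.q3, params.g, params.c_min)
    if V_S is None:  # cannot happen when classify says BS; defensive
        raise RuntimeError("bistable tumour but V_S bracketing failed")
    return (params.V0 - V_N) / (V_S - V_N)


def steady_state_report(params: ModelParameters) -> SteadyStateReport:
    """Full steady-state summary: equilibria, regime, thresholds, V_d."""
    nl = nl_steady_state(params)
    sl = sl_steady_state(params)
    regime = classify_regime(params)
    V_N = compute_VN(params.q1, params.g, params.c_min)
    V_S = compute_VS(params.q1, params.q3, params.g, params.c_min)
    V_d = None
    if regime == "BS" and V_S is not None:
        V_d = (params.V0 - V_N) / (V_S - V_N)
    return SteadyStateReport(regime=regime, nl=nl, sl=sl, V_N=V_N, V_S=V_S, V_d=V_d)


def verify_no_damaged_steady_state(
    params: ModelParameters,
    state,
    tol: float = 1e-8,
    residual_tol: float = 1e-6,
) -> bool:
    """Check that a converged treatment-free state carries no damaged cells.

    Any steady state of the full four-variable system with R = 0 must have
    ``TS* = TR* = 0`` (the damaged-cell balance forces ``TS* = (etaR/xi) TR*``
    and both contradictions with the viable-cell balance otherwise).  This
    regression check takes a numerically converged long-run state and returns
    True iff both damaged compartments are below ``tol``.

    Raises if the state is not actually converged (RHS residual above
    ``residual_tol``).
    """
    y = np.asarray(state, dtype=float)
    if y[1] >= tol or y[2] >= tol:
        return False  # damaged cells present: the claim fails outright
    residual = np.max(np.abs(rhs(y, 0.0, params, R=0.0)))
    if residual > residual_tol:
        raise ValueError(
            f"state is not converged (max |dy/dt| = {residual:.3g} > {residual_tol:g}); "
            f"integrate longer before verifying"
        )
    return bool(y[1] < tol and y[2] < tol)
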