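"""Compiled right-hand side of the ODE system.

The integrator evaluates the RHS tens of thousands of times per treatment
course, so it is JIT-compiled with numba when available; the pure-Python
fallback is bit-for-bit identical.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=False)
def rhs_core(t: float, y: np.ndarray, pv: np.ndarray, R: float) -> np.ndarray:
    """Derivatives of (T, TS, TR, c).

    ``pv`` layout (see ModelParameters.as_vector): q1, q3, q2, V0, c_min, g,
    theta1, theta2, nu, lam, lamS, mu, xi, etaR, delta1, delta1S.
    The Heaviside uses H(0) = 1, so the starvation switch is on exactly at
    c = c_min (where the death terms vanish continuously anyway).
    """
    T = y[0]
    TS = y[1]
    TR = y[2]
    c = y[3]
    q1 = pv[0]
    q3 = pv[1]
    q2 = pv[2]
    V0 = pv[3]
    c_min = pv[4]
    g = pv[5]
    theta1 = pv[6]
    theta2 = pv[7]
    nu = pv[8]
    lam = pv[9]
    lamS = pv[10]
    mu = pv[11]
    xi = pv[12]
    etaR = pv[13]
    delta1 = pv[14]
    delta1S = pv[15]

    free = 1.0 - (T + TS + TR + V0)
    H = 1.0 if (c_min - c) >= 0.0 else 0.0
    starv = delta1 * (c_min - c) * H
    starvS = delta1S * (c_min - c) * H

    out = np.empty(4)
    out[0] = q2 * c * T * free - (starv + lam * c * R + nu * c * R) * T + mu * TS
    out[1] = (theta2 * q2 * c * TS * free
              - (starvS + lamS * c * R + mu + xi) * TS + nu * c * R * T)
    out[2] = lam * c * R * T + (xi + lamS * c * R) * TS - etaR * TR
    out[3] = (g * (1.0 - c) * V0 - q1 * (T + theta1 * TS) * c
              - q3 * (T + theta2 * TS) * c * free)
    return out
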