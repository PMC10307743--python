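"""Dimensionless tumour-growth model with explicit radiation damage kinetics.

The model tracks four state variables, all dimensionless:

``T``
    undamaged viable tumour cells, as a fraction of the total available space;
``TS``
    sub-lethally damaged cells, which may repair (rate ``mu``), accumulate
    lethal damage during irradiation (rate ``lamS * c * R``) or die of mitotic
    catastrophe (rate ``xi``);
``TR``
    lethally damaged (dead) cells, cleared at rate ``etaR``;
``c``
    oxygen concentration as a fraction of the vascular concentration.

Growth is limited by two distinct mechanisms.  Proliferation is proportional
to the free space ``1 - Sigma`` (with ``Sigma = T + TS + TR + V0`` the total
occupied volume), so growth arrests when space runs out.  When oxygen drops
below the anoxic threshold ``c_min``, cells die of nutrient starvation at a
rate proportional to ``c_min - c``, so growth can also arrest with
proliferation and starvation death in balance.  Radiation couples to both:
damage rates are proportional to the oxygen concentration (the oxygen
enhancement of radiosensitivity) and to the instantaneous dose rate ``R``.

The time unit of the dimensionless system is one minute, chosen to resolve
the damage/repair kinetics during a radiation fraction; all scheduling
arithmetic elsewhere in the package is done in minutes.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import yaml

from ._compiled import rhs_core

__all__ = [
    "ModelParameters",
    "build_parameters",
    "heaviside",
    "rhs",
    "Q_RANGE",
    "V0_RANGE",
]

logger = logging.getLogger(__name__)

#: Biologically motivated default ranges for the free parameters.
Q_RANGE = (1e-2, 10.0)
V0_RANGE = (0.0, 5e-3)  # open at 0, closed at 5e-3

# Fields that are derived from the base parameters unless explicitly pinned.
_DERIVED = ("q2", "delta1", "delta1S", "q1S", "q2S", "q3S")
_BASE = (
    "q1", "q3", "V0", "c_min", "g", "k", "theta1", "theta2",
    "nu", "lam", "lamS", "mu", "xi", "etaR",
)


def heaviside(x: float) -> float:
    """Unit step with the convention ``H(0) = 1``.

    This convention matters at the anoxic threshold: the starvation death
    term ``delta1 * (c_min - c) * H(c_min - c)`` vanishes continuously at
    ``c = c_min`` regardless, but the switch itself is defined to be *on*
    exactly at the threshold.
    """
    x = float(x)
    if not math.isfinite(x):
        raise ValueError(f"heaviside requires a finite argument, got {x!r}")
    return 1.0 if x >= 0.0 else 0.0


@dataclass(frozen=True)
class ModelParameters:
    """Complete dimensionless parameter set for one tumour.

    Only ``q1`` (oxygen consumption for maintenance), ``q3`` (oxygen
    consumption for proliferation) and ``V0`` (vascular volume fraction) are
    tumour-specific; the remaining rates default to the study's reference
    values.  Derived couplings are resolved at construction time:

    * ``q2 = k * q3`` — proliferation rate tied to proliferative oxygen demand;
    * ``delta1 = q2`` and ``delta1S = theta2 * q2`` — starvation death rates
      tied to the proliferation rates;
    * ``q1S = theta1 * q1``, ``q2S = theta2 * q2``, ``q3S = theta2 * q3`` —
      damaged-cell rates scaled from undamaged-cell rates.

    Passing an explicit value for a derived field pins it (a warning is
    logged); otherwise the couplings hold exactly.
    """

    q1: float
    q3: float
    V0: float
    c_min: float = 1e-2
    g: float = 5.0
    k: float = 1e-2
    theta1: float = 10.0
    theta2: float = 0.1
    nu: float = 10.0
    lam: float = 1.0
    lamS: float = 1.0
    mu: float = 5e-3
    xi: float = 5e-4
    etaR: float = 5e-5
    # Derived unless explicitly pinned.
    q2: float | None = None
    delta1: float | None = None
    delta1S: float | None = None
    q1S: float | None = None
    q2S: float | None = None
    q3S: float | None = None

    def __post_init__(self) -> None:
        defaults = {
            "q2": self.k * self.q3,
            "q1S": self.theta1 * self.q1,
            "q3S": self.theta2 * self.q3,
        }
        for name in ("q2", "q1S", "q3S"):
            self._resolve(name, defaults[name])
        # Couplings through q2 use the (possibly pinned) value of q2.
        self._resolve("q2S", self.theta2 * self.q2)
        self._resolve("delta1", self.q2)
        self._resolve("delta1S", self.theta2 * self.q2)
        self._validate()

    def _resolve(self, name: str, derived_value: float) -> None:
        value = getattr(self, name)
        if value is None:
            object.__setattr__(self, name, float(derived_value))
        elif not math.isclose(float(value), derived_value, rel_tol=1e-12):
            logger.warning(
                "parameter %s explicitly set to %g, overriding the derived "
                "coupling value %g", name, value, derived_value,
            )

    def _validate(self) -> None:
        for name in _BASE + _DERIVED:
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0.0:
                raise ValueError(f"parameter {name} must be strictly positive, got {value!r}")
        if not self.V0 < 1.0:
            raise ValueError(f"V0 must be a volume fraction < 1, got {self.V0!r}")
        if not self.c_min < 1.0:
            raise ValueError(f"c_min must be < 1 (fraction of vascular oxygen), got {self.c_min!r}")
        if not self.theta2 < 1.0 < self.theta1:
            raise ValueError(
                f"need theta2 < 1 < theta1 (damaged cells proliferate slower, "
                f"consume more for maintenance); got theta1={self.theta1!r}, theta2={self.theta2!r}"
            )

    # -- fast-path support ---------------------------------------------------

    def as_vector(self) -> np.ndarray:
        """Parameter vector consumed by the compiled right-hand side.

        Order: q1, q3, q2, V0, c_min, g, theta1, theta2, nu, lam, lamS,
        mu, xi, etaR, delta1, delta1S.
        """
        return np.array(
            [self.q1, self.q3, self.q2, self.V0, self.c_min, self.g,
             self.theta1, self.theta2, self.nu, self.lam, self.lamS,
             self.mu, self.xi, self.etaR, self.delta1, self.delta1S],
            dtype=float,
        )

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(
                f"unknown parameter keys {sorted(unknown)}; valid keys are {sorted(known)}"
            )
        return cls(**{k: float(v) for k, v in data.items() if v is not None})

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelParameters":
        data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ValueError("parameter YAML must be a flat key-value mapping")
        return cls.from_dict(data)

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with ``changes`` applied and couplings re-derived."""
        base = {name: getattr(self, name) for name in _BASE}
        pinned = {
            name: getattr(self, name) for name in _DERIVED
            if name in changes
        }
        base.update({k: v for k, v in changes.items() if k in _BASE})
        base.update({k: changes[k] for k in changes if k in _DERIVED})
        unknown = set(changes) - set(_BASE) - set(_DERIVED)
        if unknown:
            raise KeyError(f"unknown parameter keys {sorted(unknown)}")
        base.update(pinned)
        return ModelParameters(**base)


def build_parameters(
    q1: float,
    q3: float,
    V0: float,
    overrides: Mapping | None = None,
    *,
    enforce_ranges: bool = True,
) -> ModelParameters:
    """Construct a fully derived parameter set for a tumour.

    Parameters
    ----------
    q1, q3
        Dimensionless oxygen consumption rates for maintenance and
        proliferation; the study samples both from ``[1e-2, 10]``.
    V0
        Vascular volume as a fraction of the total space, in ``(0, 5e-3]``.
    overrides
        Optional mapping of other parameters (base or derived) to pin.
    enforce_ranges
        When true (default), reject ``q1``, ``q3`` or ``V0`` outside the
        study ranges unless the same key also appears in ``overrides``
        (which documents the relaxation explicitly).
    """
    overrides = dict(overrides or {})
    if enforce_ranges:
        lo, hi = Q_RANGE
        for name, value in (("q1", q1), ("q3", q3)):
            if name not in overrides and not (lo <= value <= hi):
                raise ValueError(
                    f"{name}={value!r} outside the study range [{lo}, {hi}]; "
                    f"pass it via overrides to relax the check"
                )
        if "V0" not in overrides and not (V0_RANGE[0] < V0 <= V0_RANGE[1]):
            raise ValueError(
                f"V0={V0!r} outside the study range ({V0_RANGE[0]}, {V0_RANGE[1]}]; "
                f"pass it via overrides to relax the check"
            )
    overrides.setdefault("q1", q1)
    overrides.setdefault("q3", q3)
    overrides.setdefault("V0", V0)
    return ModelParameters.from_dict(overrides)


def rhs(state, t: float, params: ModelParameters, R: float = 0.0) -> np.ndarray:
    """Time derivatives ``(dT/dt, dTS/dt, dTR/dt, dc/dt)`` of the model.

    ``R`` is the instantaneous dimensionless dose rate (dose in Gy per
    fraction divided by fraction duration in minutes, relative to the
    1 Gy/min reference).  The oxygen equation consumes at rate
    ``q1 * (T + theta1*TS) * c`` for maintenance and
    ``q3 * (T + theta2*TS) * c * (1 - Sigma)`` for proliferation.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (4,):
        raise ValueError(f"state must have four components (T, TS, TR, c), got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"state must be finite, got {y!r}")
    if not (math.isfinite(R) and R >= 0.0):
        raise ValueError(f"dose rate R must be finite and non-negative, got {R!r}")
    return rhs_core(float(t), y, params.as_vector(), float(R))
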