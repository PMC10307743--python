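"""Fractionated radiotherapy protocols and the piecewise-constant dose rate.

A protocol delivers a dose ``D`` (Gy) per fraction at a constant rate over a
short irradiation window (``delta_R`` minutes, default 10).  Fractions are
placed on weekdays at the same time of day: 5/week on Mon-Fri, 3/week on
Mon/Wed/Fri, 1/week on Monday, with the first fraction starting at t = 0
(Monday 00:00 of week 1).  The total number of fractions is
``floor(total_dose_cap / D)`` so the realised total dose never exceeds the
cap (80 Gy by default); with D = 3 this gives 26 fractions, i.e. 5.2 weeks
at 5/week or 8.67 weeks at 3/week.

All times are in minutes, matching the dimensionless time unit of the model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "Schedule",
    "build_schedule",
    "dose_rate",
    "MINUTES_PER_DAY",
    "MINUTES_PER_WEEK",
]

MINUTES_PER_DAY = 24 * 60
MINUTES_PER_WEEK = 7 * MINUTES_PER_DAY

#: Weekday offsets (0 = Monday) for the supported weekly fraction counts.
_WEEKDAY_PATTERN = {5: (0, 1, 2, 3, 4), 3: (0, 2, 4), 1: (0,)}


@dataclass(frozen=True)
class Schedule:
    """An ordered set of irradiation windows with a common dose rate.

    ``R_value = D / (delta_R * R_max)`` is the dimensionless dose rate applied
    inside each window; ``windows`` are closed intervals ``(start, end)`` in
    minutes.  A null schedule (no windows, ``D = 0``) represents the
    treatment-free model.
    """

    D: float
    n_per_week: int
    delta_R: float
    R_max: float
    total_dose_cap: float
    windows: tuple[tuple[float, float], ...]

    @property
    def is_null(self) -> bool:
        return len(self.windows) == 0

    @property
    def n_fractions(self) -> int:
        return len(self.windows)

    @property
    def R_value(self) -> float:
        if self.is_null:
            return 0.0
        return self.D / (self.delta_R * self.R_max)

    @property
    def total_dose(self) -> float:
        """Realised total dose in Gy."""
        return self.n_fractions * self.D

    @property
    def duration_weeks(self) -> float:
        if self.is_null:
            return 0.0
        return self.n_fractions / self.n_per_week

    @property
    def treatment_end(self) -> float:
        """End of the last irradiation window, minutes."""
        if self.is_null:
            return 0.0
        return self.windows[-1][1]

    @property
    def end_of_last_week(self) -> float:
        """End (Sunday 24:00) of the calendar week containing the last fraction."""
        if self.is_null:
            return 0.0
        return MINUTES_PER_WEEK * math.ceil(self.treatment_end / MINUTES_PER_WEEK)

    @classmethod
    def null(cls) -> "Schedule":
        """The no-treatment protocol (R identically zero)."""
        return cls(D=0.0, n_per_week=0, delta_R=10.0, R_max=1.0,
                   total_dose_cap=0.0, windows=())

    def in_window(self, t: float) -> bool:
        """True if ``t`` lies inside an irradiation window (closed interval)."""
        for start, end in self.windows:
            if start <= t <= end:
                return True
            if start > t:
                break
        return False

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "D": self.D,
            "n_per_week": self.n_per_week,
            "delta_R": self.delta_R,
            "R_max": self.R_max,
            "total_dose_cap": self.total_dose_cap,
            "R_value": self.R_value,
            "n_fractions": self.n_fractions,
            "duration_weeks": self.duration_weeks,
            "windows": [list(w) for w in self.windows],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Schedule":
        data = json.loads(text)
        return cls(
            D=float(data["D"]),
            n_per_week=int(data["n_per_week"]),
            delta_R=float(data["delta_R"]),
            R_max=float(data["R_max"]),
            total_dose_cap=float(data["total_dose_cap"]),
            windows=tuple((float(a), float(b)) for a, b in data["windows"]),
        )


def build_schedule(
    D: float,
    n_per_week: int,
    delta_R: float = 10.0,
    total_dose_cap: float = 80.0,
    R_max: float = 1.0,
) -> Schedule:
    """Build a weekday fractionation protocol.

    Parameters
    ----------
    D
        Dose per fraction in Gy (the study sweeps integers 1-5).
    n_per_week
        Fractions per week; one of {1, 3, 5}.
    delta_R
        Fraction duration in minutes.
    total_dose_cap
        Total-dose budget in Gy; ``floor(total_dose_cap / D)`` fractions are
        scheduled so the realised dose never exceeds it.

    Raises
    ------
    ValueError
        If ``D <= 0`` (use :meth:`Schedule.null` for no treatment) or
        ``n_per_week`` is unsupported.
    """
    if D <= 0:
        raise ValueError("D must be positive; use Schedule.null() for the no-treatment protocol")
    if n_per_week not in _WEEKDAY_PATTERN:
        raise ValueError(f"n_per_week must be one of {sorted(_WEEKDAY_PATTERN)}, got {n_per_week!r}")
    if delta_R <= 0:
        raise ValueError(f"delta_R must be positive, got {delta_R!r}")
    if delta_R > MINUTES_PER_DAY:
        raise ValueError(f"a fraction must fit within one day, got delta_R={delta_R!r} min")
    if total_dose_cap < D:
        raise ValueError(
            f"total_dose_cap={total_dose_cap!r} Gy admits no fraction of D={D!r} Gy"
        )
    n_fractions = int(math.floor(total_dose_cap / D))
    days = _WEEKDAY_PATTERN[n_per_week]
    windows = []
    for i in range(n_fractions):
        week, slot = divmod(i, n_per_week)
        start = week * MINUTES_PER_WEEK + days[slot] * MINUTES_PER_DAY
        windows.append((float(start), float(start) + delta_R))
    return Schedule(
        D=float(D), n_per_week=int(n_per_week), delta_R=float(delta_R),
        R_max=float(R_max), total_dose_cap=float(total_dose_cap),
        windows=tuple(windows),
    )


def dose_rate(t: float | Iterable[float], schedule: Schedule):
    """Dimensionless dose rate R(t): ``schedule.R_value`` inside a window, else 0."""
    if np.ndim(t) == 0:
        if t < 0:
            raise ValueError(f"t must be non-negative, got {t!r}")
        return schedule.R_value if schedule.in_window(float(t)) else 0.0
    ts = np.asarray(t, dtype=float)
    if np.any(ts < 0):
        raise ValueError("t must be non-negative")
    out = np.zeros_like(ts)
    for start, end in schedule.windows:
        out[(ts >= start) & (ts <= end)] = schedule.R_value
    return out
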