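"""Treatment-response metrics: last-week time averages and percent changes.

The response of a tumour to a fractionation course is summarised by time
averages over the *last week of treatment* — the final 10080 minutes ending
at the end (Sunday 24:00) of the calendar week containing the last fraction.
For protocols whose last week is partial (e.g. 26 fractions at 5/week end on
the Monday of week 6) the window still spans a full 10080 minutes ending at
that week's Sunday, so the averaging length is identical across protocols.

From the averages ``Tbar, TSbar, TRbar`` and the pre-treatment steady state
``T0`` (total volume ``Sigma0 = T0 + V0``):

* ``delta_viable = 100 * ((Tbar + TSbar) - T0) / T0`` — percent change in
  mean viable volume;
* ``delta_total = 100 * (Sigmabar - Sigma0) / Sigma0`` — percent change in
  mean total volume;
* composition percentages ``%T, %TS, %TR, %V0``, each relative to
  ``Sigma0``, which satisfy the exact identity
  ``delta_total = (%T + %TS + %TR + %V0) - 100``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelParameters
from .schedule import MINUTES_PER_WEEK, Schedule
from .simulate import Trajectory, pretreatment_state

__all__ = ["ResponseSummary", "last_week_means", "response_summary", "summaries_to_frame"]

#: Sampling interval (minutes) for quadrature inside the averaging window.
_GRID_DT = 1.0

#: Stable column order for serialised summaries.
_COLUMNS = ["t0", "sigma0", "tbar", "tsbar", "trbar", "cbar",
            "delta_viable", "delta_total", "pct_t", "pct_ts", "pct_tr",
            "pct_v0", "attractor"]


@dataclass(frozen=True)
class ResponseSummary:
    """Per-tumour treatment response record."""

    T0: float
    Sigma0: float
    Tbar: float
    TSbar: float
    TRbar: float
    cbar: float
    delta_viable: float
    delta_total: float
    pctT: float
    pctTS: float
    pctTR: float
    pctV0: float
    attractor: str | None = None

    def to_row(self) -> dict:
        return {
            "t0": self.T0, "sigma0": self.Sigma0, "tbar": self.Tbar,
            "tsbar": self.TSbar, "trbar": self.TRbar, "cbar": self.cbar,
            "delta_viable": self.delta_viable, "delta_total": self.delta_total,
            "pct_t": self.pctT, "pct_ts": self.pctTS, "pct_tr": self.pctTR,
            "pct_v0": self.pctV0, "attractor": self.attractor,
        }


def last_week_means(traj: Trajectory, schedule: Schedule):
    """Time averages of (T, TS, TR, c) over the last treatment week.

    Trapezoidal quadrature on the solver's dense output sampled at 1-minute
    resolution over ``[end_of_last_week - 10080, end_of_last_week]``.
    """
    t_end = schedule.end_of_last_week
    t_start = t_end - MINUTES_PER_WEEK
    if traj.t[-1] < t_end - 1e-6 or traj.t[0] > t_start + 1e-6:
        raise ValueError(
            f"trajectory [{traj.t[0]}, {traj.t[-1]}] does not cover the last "
            f"treatment week [{t_start}, {t_end}]"
        )
    grid = np.arange(t_start, t_end + _GRID_DT / 2, _GRID_DT)
    vals = traj.sample(grid)
    means = np.trapezoid(vals, grid, axis=1) / (t_end - t_start)
    return tuple(float(m) for m in means)


def response_summary(
    params: ModelParameters,
    schedule: Schedule,
    traj: Trajectory,
    attractor: str | None = None,
) -> ResponseSummary:
    """Assemble the full response record for one treated tumour."""
    eq = pretreatment_state(params)
    T0 = eq.T
    sigma0 = T0 + params.V0
    Tbar, TSbar, TRbar, cbar = last_week_means(traj, schedule)
    sigmabar = Tbar + TSbar + TRbar + params.V0
    return ResponseSummary(
        T0=T0,
        Sigma0=sigma0,
        Tbar=Tbar,
        TSbar=TSbar,
        TRbar=TRbar,
        cbar=cbar,
        delta_viable=100.0 * ((Tbar + TSbar) - T0) / T0,
        delta_total=100.0 * (sigmabar - sigma0) / sigma0,
        pctT=100.0 * Tbar / sigma0,
        pctTS=100.0 * TSbar / sigma0,
        pctTR=100.0 * TRbar / sigma0,
        pctV0=100.0 * params.V0 / sigma0,
        attractor=attractor,
    )


def summaries_to_frame(summaries) -> "pd.DataFrame":  # noqa: F821
    """Stack ResponseSummary records into a tidy table with stable columns."""
    import pandas as pd

    rows = [s.to_row() for s in summaries]
    return pd.DataFrame(rows, columns=_COLUMNS)
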