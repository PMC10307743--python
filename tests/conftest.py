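"""Shared fixtures: representative tumours and their treatment trajectories.

The heavier simulations (full 8-week conventional courses) are session-scoped
so the metrics, simulation-property and acceptance tests share one
integration each.
"""

from __future__ import annotations

import numpy as np
import pytest

import rtgrowth as rg

# Representative tumours: (q1, q3, V0) triples used throughout the study.
SL_REP = (1.08, 8.83, 0.005)
NL_REP = (0.832, 2.98, 0.0005)
BS_TYPICAL = (0.787, 8.38, 0.00275)

# The four representative nutrient-limited tumours (V0 = 0.0005).
NL_QUARTET = {
    "A1": (8.91e-1, 1.14e-1),
    "B1": (7.78, 4.01e-2),
    "C1": (8.91e-1, 9.75),
    "D1": (7.60, 9.94),
}

# The four representative bistable tumours (V0 = 0.00275).
BS_QUARTET = {
    "A3": (4.55e-2, 7.94),
    "B3": (1.06, 4.92),
    "C3": (3.92e-2, 9.96),
    "D3": (1.36, 9.93),
}


@pytest.fixture(scope="session")
def conventional_schedule() -> rg.Schedule:
    """5 x 2 Gy per week for 8 weeks (80 Gy total)."""
    return rg.build_schedule(2.0, 5)


@pytest.fixture(scope="session")
def sl_rep_params() -> rg.ModelParameters:
    return rg.build_parameters(*SL_REP)


@pytest.fixture(scope="session")
def nl_rep_params() -> rg.ModelParameters:
    return rg.build_parameters(*NL_REP)


@pytest.fixture(scope="session")
def sl_rep_traj(sl_rep_params, conventional_schedule) -> rg.Trajectory:
    return rg.simulate_treatment(sl_rep_params, conventional_schedule)


@pytest.fixture(scope="session")
def nl_rep_traj(nl_rep_params, conventional_schedule) -> rg.Trajectory:
    return rg.simulate_treatment(nl_rep_params, conventional_schedule)


@pytest.fixture(scope="session")
def nl_quartet_summaries(conventional_schedule) -> dict:
    """Response summaries for the four representative NL tumours."""
    out = {}
    for name, (q1, q3) in NL_QUARTET.items():
        params = rg.build_parameters(q1, q3, 0.0005)
        traj = rg.simulate_treatment(params, conventional_schedule)
        out[name] = rg.response_summary(params, conventional_schedule, traj)
    return out


def weekly_periodicity_defect(traj: rg.Trajectory, week_a: int, week_b: int) -> float:
    """Worst pointwise mismatch between two weekly waveforms.

    Volume compartments are normalised by the tumour's total volume at the
    start of treatment (the natural size scale for volume fractions) and
    oxygen by its own weekly maximum.  Returns the max over variables and
    time points.
    """
    week = rg.MINUTES_PER_WEEK
    grid = np.arange(0.0, week, 10.0)
    wa = traj.sample(week_a * week + grid)
    wb = traj.sample(week_b * week + grid)
    sigma0 = float(traj.y[:3, 0].sum() + traj.params.V0)
    scales = np.array([sigma0, sigma0, sigma0, np.abs(wb[3]).max()])
    return float((np.abs(wa - wb) / scales[:, None]).max())


def random_states(rng: np.random.Generator, n: int, V0: float) -> np.ndarray:
    """Random physically valid states (nonnegative, Sigma <= 1, c in [0, 1])."""
    fractions = rng.dirichlet(np.ones(4), size=n) * (1.0 - V0)
    states = np.empty((n, 4))
    states[:, :3] = fractions[:, :3]
    states[:, 3] = rng.uniform(0.0, 1.0, size=n)
    return states
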