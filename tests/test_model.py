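"""Unit and property tests for the parameter container and the ODE right-hand side."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rtgrowth as rg
from rtgrowth.model import ModelParameters

from conftest import random_states


def reference_rhs(state, params, R):
    """Independent term-by-term arithmetic evaluation of the model equations.

    Deliberately written from the equations, term by term, with no code
    shared with the production right-hand side.
    """
    T, TS, TR, c = state
    p = params
    sigma = T + TS + TR + p.V0
    H = 1.0 if (p.c_min - c) >= 0 else 0.0
    proliferation_T = p.q2 * c * T * (1 - sigma)
    starvation_T = p.delta1 * (p.c_min - c) * H * T
    lethal_direct = p.lam * c * R * T
    sublethal_hit = p.nu * c * R * T
    repair = p.mu * TS
    dT = proliferation_T - starvation_T - lethal_direct - sublethal_hit + repair

    proliferation_S = p.theta2 * p.q2 * c * TS * (1 - sigma)
    starvation_S = p.delta1S * (p.c_min - c) * H * TS
    lethal_indirect = p.lamS * c * R * TS
    catastrophe = p.xi * TS
    dTS = proliferation_S - starvation_S + sublethal_hit - repair - catastrophe - lethal_indirect

    dTR = lethal_direct + catastrophe + lethal_indirect - p.etaR * TR

    supply = p.g * (1 - c) * p.V0
    maintenance = p.q1 * (T + p.theta1 * TS) * c
    prolif_demand = p.q3 * (T + p.theta2 * TS) * c * (1 - sigma)
    dc = supply - maintenance - prolif_demand
    return np.array([dT, dTS, dTR, dc])


class TestHeaviside:
    @pytest.mark.parametrize("x,expected", [(0.0, 1.0), (-1e-12, 0.0), (0.5, 1.0),
                                            (-3.0, 0.0), (1e-300, 1.0)])
    def test_step_convention(self, x, expected):
        assert rg.heaviside(x) == expected

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -float("inf")])
    def test_rejects_non_finite(self, bad):
        with pytest.raises(ValueError):
            rg.heaviside(bad)


class TestBuildParameters:
    def test_derived_couplings(self):
        p = rg.build_parameters(0.5, 5.0, 0.003)
        assert p.q2 == pytest.approx(0.05, abs=0)
        assert p.delta1 == pytest.approx(0.05, abs=0)
        assert p.q1S == pytest.approx(5.0, abs=0)
        assert p.q2S == pytest.approx(0.005, rel=1e-12)
        assert p.q3S == pytest.approx(0.5)
        assert p.delta1S == pytest.approx(0.005)

    def test_space_limited_representative_is_valid(self):
        p = rg.build_parameters(1.08, 8.83, 0.005)
        assert rg.classify_regime(p) == "SL"

    @pytest.mark.parametrize("kwargs", [
        dict(q1=0.5, q3=5.0, V0=1.5),     # V0 not a volume fraction
        dict(q1=-1.0, q3=5.0, V0=0.003),  # negative rate
        dict(q1=0.5, q3=50.0, V0=0.003),  # q3 outside the study range
        dict(q1=0.5, q3=5.0, V0=0.02),    # V0 outside the study range
    ])
    def test_rejects_invalid_inputs(self, kwargs):
        with pytest.raises(ValueError):
            rg.build_parameters(**kwargs)

    def test_explicit_override_can_relax_ranges(self):
        p = rg.build_parameters(0.5, 5.0, 0.004, overrides={"V0": 0.004, "g": 7.0})
        assert p.g == 7.0

    def test_override_recomputes_coupled_rates(self):
        p = rg.build_parameters(0.5, 5.0, 0.003).replace(q3=2.0)
        assert p.q2 == pytest.approx(0.02)
        assert p.delta1 == pytest.approx(0.02)
        assert p.q3S == pytest.approx(0.2)

    def test_yaml_roundtrip_and_unknown_key_rejection(self):
        p = rg.build_parameters(0.5, 5.0, 0.003)
        assert ModelParameters.from_yaml(p.to_yaml()) == p
        with pytest.raises(KeyError, match="unknown parameter"):
            ModelParameters.from_dict({"q1": 1, "q3": 1, "V0": 1e-3, "bogus": 2})


class TestRhs:
    def test_empty_tumour_only_oxygen_supply(self):
        p = rg.build_parameters(0.5, 5.0, 0.003)
        dy = rg.rhs((0, 0, 0, 0.5), 0.0, p, R=0.0)
        np.testing.assert_allclose(dy, [0, 0, 0, p.g * 0.5 * p.V0], atol=1e-15)

    def test_vanishes_at_space_limited_equilibrium(self):
        p = rg.build_parameters(0.5, 5.0, 0.003)
        eq = rg.sl_steady_state(p)
        dy = rg.rhs((eq.T, 0, 0, eq.c), 0.0, p, R=0.0)
        np.testing.assert_allclose(dy, 0.0, atol=1e-12)

    def test_matches_term_by_term_reference(self):
        p = rg.build_parameters(1.0, 1.0, 0.003)
        state = np.array([0.1, 0.05, 0.02, 0.5])
        np.testing.assert_allclose(
            rg.rhs(state, 0.0, p, R=0.2), reference_rhs(state, p, 0.2),
            rtol=1e-13,
        )

    def test_matches_reference_on_random_states(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            q1, q3 = rng.uniform(1e-2, 10, size=2)
            V0 = rng.uniform(1e-4, 5e-3)
            p = rg.build_parameters(q1, q3, V0)
            state = random_states(rng, 1, V0)[0]
            R = rng.choice([0.0, 0.1, 0.5])
            np.testing.assert_allclose(
                rg.rhs(state, 0.0, p, R=R), reference_rhs(state, p, R),
                rtol=1e-12, atol=1e-16,
            )

    def test_rejects_negative_dose_rate(self):
        p = rg.build_parameters(0.5, 5.0, 0.003)
        with pytest.raises(ValueError):
            rg.rhs((0.1, 0, 0, 0.5), 0.0, p, R=-0.1)


# -- invariants of the equations, property-tested ---------------------------

state_strategy = st.tuples(
    st.floats(0, 0.9), st.floats(0, 0.4), st.floats(0, 0.4), st.floats(0, 1),
)
params_strategy = st.builds(
    rg.build_parameters,
    q1=st.floats(1e-2, 10), q3=st.floats(1e-2, 10), V0=st.floats(1e-4, 5e-3),
)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(state=state_strategy, params=params_strategy)
def test_no_damage_reduction_recovers_growth_model(state, params):
    """With no irradiation and no damaged cells the two-compartment growth
    model is recovered exactly: damaged pools stay empty and (dT, dc) carry
    only proliferation, starvation, supply and consumption terms."""
    T, _, _, c = state
    dy = rg.rhs((T, 0.0, 0.0, c), 0.0, params, R=0.0)
    assert dy[1] == 0.0 and dy[2] == 0.0
    sigma = T + params.V0
    H = 1.0 if params.c_min >= c else 0.0
    dT_expected = (params.q2 * c * T * (1 - sigma)
                   - params.delta1 * (params.c_min - c) * H * T)
    dc_expected = (params.g * (1 - c) * params.V0 - params.q1 * T * c
                   - params.q3 * T * c * (1 - sigma))
    assert dy[0] == pytest.approx(dT_expected, rel=1e-12, abs=1e-16)
    assert dy[3] == pytest.approx(dc_expected, rel=1e-12, abs=1e-16)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(state=state_strategy, params=params_strategy, R=st.floats(0, 0.5))
def test_mass_bookkeeping_rt_terms_cancel(state, params, R):
    """Irradiation transfer and repair terms only move volume between
    compartments: the total cell-volume rate is proliferation minus
    starvation death minus dead-cell clearance, independent of R."""
    T, TS, TR, c = state
    dy = rg.rhs(state, 0.0, params, R=R)
    sigma = T + TS + TR + params.V0
    H = 1.0 if params.c_min >= c else 0.0
    expected = (params.q2 * c * T * (1 - sigma)
                + params.theta2 * params.q2 * c * TS * (1 - sigma)
                - params.delta1 * (params.c_min - c) * H * T
                - params.delta1S * (params.c_min - c) * H * TS
                - params.etaR * TR)
    assert dy[:3].sum() == pytest.approx(expected, rel=1e-10, abs=1e-14)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(params=params_strategy, R=st.floats(0, 0.5), split=st.floats(0, 1),
       c=st.floats(0, 1))
def test_boundedness_at_state_space_boundary(params, R, split, c):
    """The flow points inward at the boundary of the physical region: total
    volume cannot grow past full occupancy and oxygen stays in [0, 1]."""
    total = 1.0 - params.V0
    T = total * split
    TS = (total - T) * 0.5
    TR = total - T - TS  # Sigma == 1 exactly
    dy_full = rg.rhs((T, TS, TR, c), 0.0, params, R=R)
    assert dy_full[:3].sum() <= 1e-14
    dy_c1 = rg.rhs((0.3, 0.05, 0.05, 1.0), 0.0, params, R=R)
    assert dy_c1[3] <= 0.0
    dy_c0 = rg.rhs((0.3, 0.05, 0.05, 0.0), 0.0, params, R=R)
    assert dy_c0[3] >= 0.0


def test_starvation_terms_vanish_continuously_at_threshold():
    """The death switch is continuous at c = c_min: both one-sided limits of
    the RHS agree with the on-threshold value."""
    p = rg.build_parameters(0.5, 5.0, 0.003)
    state = np.array([0.2, 0.1, 0.05, p.c_min])
    at = rg.rhs(state, 0.0, p, R=0.3)
    for eps in (1e-12, -1e-12):
        shifted = state.copy()
        shifted[3] = p.c_min + eps
        np.testing.assert_allclose(rg.rhs(shifted, 0.0, p, R=0.3), at,
                                   rtol=1e-9, atol=1e-12)
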