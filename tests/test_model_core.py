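"""Constitutive functions: albedos, outgoing flux, growth rate, drift."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from climveg import (ClimateParams, State, drift, growth_rate, jacobian,
                     ocean_albedo, outgoing_radiation, planetary_albedo)

TEMPS = st.floats(min_value=200.0, max_value=350.0)
FRACS = st.floats(min_value=0.0, max_value=1.0)


@pytest.mark.parametrize("T, expected", [
    (263.0, 0.85),        # at/below the lower ramp edge: fully ice-covered
    (240.0, 0.85),
    (300.0001, 0.25),     # above the upper edge: ice-free
    (281.5, 0.55),        # ramp midpoint
    (300.0, 0.25),        # continuity at the upper breakpoint
])
def test_ocean_albedo_ramp(params, T, expected):
    assert ocean_albedo(T, params) == pytest.approx(expected, abs=1e-12)


@given(t1=TEMPS, t2=TEMPS)
@settings(max_examples=200, derandomize=True)
def test_ocean_albedo_monotone_nonincreasing(t1, t2):
    p = ClimateParams()
    lo, hi = sorted((t1, t2))
    assert ocean_albedo(lo, p) >= ocean_albedo(hi, p)


@pytest.mark.parametrize("T, A, expected", [
    (250.0, 0.0, 0.715),    # ice-covered ocean + bare land
    (310.0, 1.0, 0.205),    # ice-free ocean + full vegetation
    (281.5, 0.5, 0.46),
])
def test_planetary_albedo_values(params, T, A, expected):
    assert planetary_albedo(T, A, params) == pytest.approx(expected, abs=1e-12)


@given(T=TEMPS, A=FRACS)
@settings(max_examples=200, derandomize=True)
def test_planetary_albedo_bounds_default_params(T, A):
    """For the default parameters alpha lies in [0.205, 0.715]."""
    a = planetary_albedo(T, A, ClimateParams())
    assert 0.205 - 1e-12 <= a <= 0.715 + 1e-12


def test_planetary_albedo_rejects_bad_fraction(params):
    with pytest.raises(ValueError):
        planetary_albedo(280.0, 1.2, params)


@pytest.mark.parametrize("T, expected", [
    (283.0, 200.0),          # at T_opt the flux equals B0
    (293.0, 225.0),
    (242.045, 97.6125),      # equals absorbed flux at the snowball state
])
def test_outgoing_radiation(params, T, expected):
    assert outgoing_radiation(T, params) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("T, expected", [
    (283.0, 1.0),
    (273.0, 0.6),
    (299.0, 0.0),   # outside the support: clipped to zero
    (250.0, 0.0),
])
def test_growth_rate_values(params, T, expected):
    assert growth_rate(T, params) == pytest.approx(expected, abs=1e-12)


@given(d=st.floats(min_value=0.0, max_value=60.0))
@settings(max_examples=100, derandomize=True)
def test_growth_rate_symmetric_and_nonnegative(d):
    p = ClimateParams()
    lo, hi = growth_rate(p.T_opt - d, p), growth_rate(p.T_opt + d, p)
    assert lo == pytest.approx(hi, abs=1e-12)
    assert lo >= 0.0


class TestDrift:
    def test_snowball_is_equilibrium(self):
        p = ClimateParams(gamma=0.02)
        dT, dA = drift(State(242.045, 0.0), p)
        assert abs(dT) < 1e-9 and dA == 0.0

    def test_bare_line_invariant(self):
        dT, dA = drift(State(283.0, 0.0), ClimateParams(gamma=0.02))
        assert dA == 0.0

    def test_vegetation_equation_hand_value(self):
        _, dA = drift(State(283.0, 0.5), ClimateParams(gamma=0.02))
        assert dA == pytest.approx(0.24, abs=1e-12)

    @given(T=TEMPS)
    @settings(max_examples=100, derandomize=True)
    def test_edge_rates_every_temperature(self, T):
        """dA/dt is 0 at A=0 and -gamma at A=1, so A=1 is never an
        equilibrium when gamma > 0."""
        p = ClimateParams(gamma=0.07)
        assert drift(State(T, 0.0), p)[1] == 0.0
        assert drift(State(T, 1.0), p)[1] == pytest.approx(-p.gamma, abs=1e-12)

    def test_vectorized_matches_scalar(self, params):
        T = np.array([250.0, 283.0, 301.0])
        A = np.array([0.1, 0.5, 0.9])
        dT, dA = drift((T, A), params)
        for i in range(3):
            sT, sA = drift(State(T[i], A[i]), params)
            assert dT[i] == pytest.approx(sT) and dA[i] == pytest.approx(sA)


class TestJacobian:
    def test_snowball_eigenvalues_closed_form(self):
        """On the ice-covered bare branch the Jacobian is
        diag(-B1/C_T, beta(T) - gamma)."""
        p = ClimateParams(gamma=0.02)
        J = jacobian(State(242.045, 0.0), p)
        eigs = sorted(np.linalg.eigvals(J).real)
        assert eigs == pytest.approx([-0.02, -0.005], abs=1e-12)
        assert J[0, 1] > 0  # more vegetation darkens the planet -> warming

    @pytest.mark.parametrize("state", [
        State(281.0, 0.3), State(298.6, 0.1), State(270.0, 0.9),
    ])
    def test_matches_finite_differences(self, params, state):
        h = 1e-6
        J = jacobian(state, params)
        for j, dx in enumerate([(h, 0.0), (0.0, h)]):
            up = drift(State(state.T + dx[0], state.A + dx[1]), params)
            dn = drift(State(state.T - dx[0], state.A - dx[1]), params)
            fd = (np.array(up) - np.array(dn)) / (2 * h)
            scale = np.maximum(np.abs(fd), 1e-3)
            assert np.all(np.abs(J[:, j] - fd) / scale < 1e-4)


class TestParamValidation:
    def test_vegetation_must_be_darker_than_ground(self):
        with pytest.raises(ValueError, match="alpha_v < alpha_g"):
            ClimateParams(alpha_v=0.5, alpha_g=0.4)

    @pytest.mark.parametrize("kw", [
        {"alpha_min": 0.9}, {"T_alpha_l": 305.0}, {"p": 1.4},
        {"C_T": -1.0}, {"gamma": 0.0}, {"k": float("nan")},
    ])
    def test_invariants_rejected(self, kw):
        with pytest.raises(ValueError):
            ClimateParams(**kw)
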