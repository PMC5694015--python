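"""Model core: Hill terms, paracrine perception, right-hand side, fixed points."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axisbreak import (
    EmbryoState,
    ModelParameters,
    hill_act,
    hill_inh,
    homogeneous_steady_states,
    perceived_signal,
    rhs,
)
from axisbreak.model import hill_act_deriv, _uniform_rhs

from conftest import random_state


class TestHill:
    @pytest.mark.parametrize("K,n", [(0.3, 4.0), (1.0, 1.0), (2.5, 2.0)])
    def test_midpoint_and_zero(self, K, n):
        assert hill_act(K, K, n) == pytest.approx(0.5)
        assert hill_inh(K, K, n) == pytest.approx(0.5)
        assert hill_act(0.0, K, n) == 0.0
        assert hill_inh(0.0, K, n) == 1.0

    def test_closed_form(self):
        assert hill_act(2.0, 1.0, 4.0) == pytest.approx(16.0 / 17.0)

    @settings(derandomize=True, max_examples=1000)
    @given(x=st.floats(0.0, 50.0), K=st.floats(0.01, 10.0), n=st.floats(1.0, 8.0))
    def test_complementarity_and_bounds(self, x, K, n):
        a, i = hill_act(x, K, n), hill_inh(x, K, n)
        assert a + i == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= a <= 1.0

    def test_monotone(self):
        x = np.linspace(0, 5, 200)
        a = hill_act(x, 0.7, 4.0)
        assert np.all(np.diff(a) >= 0)
        assert np.all(np.diff(hill_inh(x, 0.7, 4.0)) <= 0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            hill_act(-0.1, 1.0, 4.0)
        with pytest.raises(ValueError):
            hill_act(1.0, 0.0, 4.0)
        with pytest.raises(ValueError):
            hill_inh(1.0, 1.0, 0.5)

    def test_derivative_matches_finite_difference(self):
        xs = np.linspace(0.01, 3.0, 50)
        h = 1e-6
        num = (hill_act(xs + h, 0.6, 4.0) - hill_act(xs - h, 0.6, 4.0)) / (2 * h)
        assert hill_act_deriv(xs, 0.6, 4.0) == pytest.approx(num, rel=1e-5)


class TestPerceivedSignal:
    def test_uniform_field_any_radius(self):
        state = EmbryoState.homogeneous(10, (0.7, 0.2, 0.0, 0.0))
        for r in (0, 1, 3):
            assert perceived_signal(state, "B", r) == pytest.approx(0.7 * np.ones(10))

    def test_radius_zero_is_identity(self, ring5):
        assert perceived_signal(ring5, "B", 0) == pytest.approx(ring5.B)

    def test_hand_window_means(self, ring5):
        # B = (3,0,0,0,0), r=1 on a ring: window means (1,1,0,0,1)
        assert perceived_signal(ring5, "B", 1) == pytest.approx([1, 1, 0, 0, 1])

    def test_unknown_species_rejected(self, ring5):
        with pytest.raises(ValueError):
            perceived_signal(ring5, "X", 1)

    def test_arc_truncation(self):
        # one cut at 0 -> open arc; end windows average available cells only
        B = np.array([3.0, 0.0, 0.0, 0.0, 0.0])
        state = EmbryoState(B, B * 0, B * 0, B * 0, cuts=(0,))
        s = perceived_signal(state, "B", 1)
        assert s == pytest.approx([1.5, 1.0, 0.0, 0.0, 0.0])


def scalar_rhs_oracle(state: EmbryoState, p: ModelParameters):
    """Hand-written scalar evaluation of the four formulas, cell by cell,
    independent of the vectorized implementation."""
    n = state.n_cells
    out = np.zeros((4, n))
    for i in range(n):
        SB = sum(state.B[(i + m) % n] for m in range(-p.coupling_radius, p.coupling_radius + 1)) / (2 * p.coupling_radius + 1)
        SV = sum(state.V[(i + m) % n] for m in range(-p.coupling_radius, p.coupling_radius + 1)) / (2 * p.coupling_radius + 1)
        h = p.hill_exponent
        act = lambda x, K: x**h / (K**h + x**h) if x > 0 else 0.0
        inh = lambda x, K: K**h / (K**h + x**h)
        dFB = p.alpha_B * act(SB, p.K_BB) * inh(SV, p.K_VB) - p.delta_F * state.FB[i]
        dFV = p.alpha_V * inh(SB, p.K_hi) * (act(SV, p.K_VV) + p.c_BV * act(SB, p.K_lo)) - p.delta_F * state.FV[i]
        dB = p.beta_B * state.FB[i] - p.delta_B * state.B[i]
        dV = p.beta_V * state.FV[i] - p.delta_V * state.V[i]
        out[:, i] = (dB, dV, dFB, dFV)
    return out


class TestRhs:
    def test_zero_state_is_fixed_point(self):
        p = ModelParameters(n_cells=8, coupling_radius=1)
        state = EmbryoState.homogeneous(8, (0, 0, 0, 0))
        d = rhs(state, p)
        assert d.max_abs() == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scalar_oracle_on_ring5(self, seed):
        p = ModelParameters(n_cells=5, coupling_radius=1, K_VB=0.5, c_BV=1.2)
        state = random_state(5, seed)
        d = rhs(state, p).stacked()
        assert d == pytest.approx(scalar_rhs_oracle(state, p), abs=1e-14)

    def test_single_cell_limit(self):
        # n_cells=3 with r=0: each cell evolves as the isolated scalar system
        p = ModelParameters(n_cells=3, coupling_radius=0)
        state = random_state(3, 7)
        d = rhs(state, p).stacked()
        for i in range(3):
            q = np.array([state.B[i], state.V[i], state.FB[i], state.FV[i]])
            expect = _uniform_rhs(q, p)
            assert d[:, i] == pytest.approx(expect, abs=1e-14)

    def test_rotation_equivariance(self):
        p = ModelParameters(n_cells=9, coupling_radius=2)
        state = random_state(9, 3)
        for k in (1, 4):
            rot = EmbryoState(np.roll(state.B, k), np.roll(state.V, k),
                              np.roll(state.FB, k), np.roll(state.FV, k))
            d0 = rhs(state, p).stacked()
            dr = rhs(rot, p).stacked()
            assert np.array_equal(np.roll(d0, k, axis=1), dr)

    def test_reflection_equivariance(self):
        p = ModelParameters(n_cells=9, coupling_radius=2)
        state = random_state(9, 4)
        refl = EmbryoState(state.B[::-1].copy(), state.V[::-1].copy(),
                           state.FB[::-1].copy(), state.FV[::-1].copy())
        d0 = rhs(state, p).stacked()
        dr = rhs(refl, p).stacked()
        assert np.array_equal(d0[:, ::-1], dr)

    def test_source_shape_mismatch(self):
        p = ModelParameters(n_cells=5, coupling_radius=1)
        state = random_state(5, 0)
        with pytest.raises(ValueError):
            rhs(state, p, src_B=np.zeros(4))

    def test_production_bounded(self):
        p = ModelParameters(n_cells=6, coupling_radius=1)
        state = random_state(6, 5)
        d = rhs(state, p)
        assert np.all(d.dFB + p.delta_F * state.FB <= p.alpha_B + 1e-12)
        assert np.all(d.dFV + p.delta_F * state.FV <= p.alpha_V * (1 + p.c_BV) + 1e-12)


class TestHomogeneousSteadyStates:
    def test_contains_zero_and_residuals(self):
        p = ModelParameters()
        states = homogeneous_steady_states(p)
        assert any(np.allclose(q, 0) for q in states)
        n = p.n_cells
        for q in states:
            st = EmbryoState.homogeneous(n, q)
            assert rhs(st, p).max_abs() < 1e-8

    def test_sorted_by_B(self):
        states = homogeneous_steady_states(ModelParameters())
        bs = [q[0] for q in states]
        assert bs == sorted(bs)

    def test_nontrivial_both_on_exists_at_defaults(self):
        states = homogeneous_steady_states(ModelParameters())
        assert any(q[0] > 1e-3 and q[1] > 1e-3 for q in states)


class TestParameters:
    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            ModelParameters(K_lo=2.0, K_hi=1.0)
        with pytest.raises(ValueError):
            ModelParameters(n_cells=5, coupling_radius=3)
        with pytest.raises(ValueError):
            ModelParameters(hill_exponent=0.5)
        with pytest.raises(ValueError):
            ModelParameters(alpha_B=0.0)
        with pytest.raises(ValueError):
            ModelParameters(sigma_init=-0.1)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ModelParameters.from_dict({"K_BB": 0.3, "bogus": 1.0})

    def test_missing_keys_filled(self):
        p = ModelParameters.from_dict({"n_cells": 50})
        assert p.n_cells == 50
        assert p.K_hi == ModelParameters().K_hi
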