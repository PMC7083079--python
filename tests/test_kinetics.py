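"""Unit tests of the model's closed forms, production laws and derivatives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from ogttfit.kinetics import (
    ModelState,
    ModelValidityError,
    apparent_glycemia,
    delayed_jejunal_forcing,
    derive_basal_production,
    gastric_chain_closed_form,
    hepatic_production,
    insulin_sensitivity,
    model_rhs,
    secretion_fraction,
)
from ogttfit.params import ParameterSet, default_parameters


class TestGastricChain:
    def test_initial_conditions(self, params):
        S, J = gastric_chain_closed_form(params, 0.0)
        assert S == params.D == 75000.0
        assert J == 0.0

    def test_gastric_half_life(self, params):
        p = params.replace(k_js=np.log(2) / 30)
        S, _ = gastric_chain_closed_form(p, 30.0)
        assert S == pytest.approx(37500.0, rel=1e-12)

    def test_jejunum_matches_fine_step_integration(self, params):
        p = params.replace(k_js=0.05, k_gj=0.02, k_jl=0.01)
        sol = solve_ivp(
            lambda t, y: [-p.k_js * y[0], p.k_js * y[0] - (p.k_gj + p.k_jl) * y[1]],
            (0, 20), [p.D, 0.0], method="RK45", rtol=1e-12, atol=1e-9,
        )
        _, J = gastric_chain_closed_form(p, 20.0)
        assert J == pytest.approx(sol.y[1, -1], rel=1e-8)

    def test_degenerate_rate_continuity(self, params):
        # k_js == k_gj + k_jl switches to the analytic limit t*D*k_js*e^-k_js*t
        p_eq = params.replace(k_js=0.05, k_gj=0.03, k_jl=0.02)
        p_near = params.replace(k_js=0.05 + 1e-12, k_gj=0.03, k_jl=0.02)
        _, J_eq = gastric_chain_closed_form(p_eq, 40.0)
        _, J_near = gastric_chain_closed_form(p_near, 40.0)
        assert J_eq == pytest.approx(40 * p_eq.D * 0.05 * np.exp(-0.05 * 40), rel=1e-12)
        assert J_near == pytest.approx(J_eq, rel=1e-6)

    def test_negative_time_rejected(self, params):
        with pytest.raises(ValueError):
            gastric_chain_closed_form(params, -1.0)


class TestDelayedForcing:
    def test_zero_before_delay(self, params):
        p = params.replace(tau=40.0)
        assert delayed_jejunal_forcing(p, 39.9) == 0.0

    def test_zero_delay_identity(self, params):
        p = params.replace(tau=0.0)
        ts = np.linspace(0, 200, 50)
        _, J = gastric_chain_closed_form(p, ts)
        np.testing.assert_allclose(delayed_jejunal_forcing(p, ts), p.k_jl * J)

    def test_shifted_evaluation(self, params):
        p = params.replace(tau=40.0)
        _, J20 = gastric_chain_closed_form(p, 20.0)
        assert delayed_jejunal_forcing(p, 60.0) == pytest.approx(p.k_jl * J20)

    def test_continuity_at_delay(self, params):
        p = params.replace(tau=40.0)
        assert delayed_jejunal_forcing(p, 40.0) == pytest.approx(
            p.k_jl * gastric_chain_closed_form(p, 0.0)[1])


class TestHepaticProduction:
    def test_basal_anchor(self, params):
        assert hepatic_production(params, params.G_b) == pytest.approx(
            derive_basal_production(params), rel=1e-14)

    def test_saturation_limit(self, params):
        assert hepatic_production(params, 1e9) < 1e-5
        assert hepatic_production(params, 1e9) > 0

    @given(
        k_lambda=st.floats(20, 500),
        k_xg=st.floats(1e-3, 0.05),
        G=st.floats(90, 400),
    )
    @settings(max_examples=50, deadline=None)
    def test_monod_form_equivalence(self, k_lambda, k_xg, G):
        # k_lambda/(k2 + G) with k2 = k_lambda/Gprod0 - G_b equals the
        # basal-anchored form for every admissible (parameters, G)
        p = default_parameters().replace(k_lambda=k_lambda, k_xg=k_xg)
        monod = k_lambda / (p.k2 + G)
        assert hepatic_production(p, G) == pytest.approx(monod, rel=1e-12)

    def test_strictly_decreasing(self, params):
        G = np.linspace(75, 300, 500)
        vals = hepatic_production(params, G)
        assert np.all(np.diff(vals) < 0)

    def test_rate_law_consistency(self, params):
        # dGprod/dG == -(Gprod/G)(1 - (k2/k_lambda) Gprod), checked against
        # a complex-step derivative of the Monod form (machine precision)
        k2 = params.k2
        for G in np.linspace(80, 250, 25):
            h = 1e-20
            dnum = (params.k_lambda / (k2 + (G + 1j * h))).imag / h
            gprod = hepatic_production(params, G)
            rhs = -(gprod / G) * (1 - (k2 / params.k_lambda) * gprod)
            assert dnum == pytest.approx(rhs, rel=1e-10)

    def test_domain_violation_signals(self, params):
        p = params.replace(k_lambda=20.0, k_xg=0.05, k_xgi=4e-3)
        # far below basal the denominator goes non-positive
        with pytest.raises(ModelValidityError):
            hepatic_production(p, 1e-3)


class TestApparentGlycemiaAndSecretion:
    def test_no_absorption(self, params):
        assert apparent_glycemia(params, 95.0, 0.0, 0.0) == 95.0

    def test_incretin_disabled(self, params):
        p = params.replace(f_gj=1e-300)
        assert apparent_glycemia(p, 95.0, 5e3, 2e3) == pytest.approx(95.0)

    def test_arithmetic_example(self, params):
        p = params.replace(f_gj=0.5, k_gj=0.02, k_gl=0.01)
        assert apparent_glycemia(p, 100.0, 1000.0, 500.0) == pytest.approx(112.5)

    def test_secretion_is_one_at_basal(self, params):
        assert secretion_fraction(params, params.G_b) == pytest.approx(1.0, rel=1e-14)

    def test_secretion_log_space_no_overflow(self, params):
        # exponents far beyond float range must not overflow
        p = params.replace(gamma=400.0, beta=10.0)
        # naive evaluation gives inf/inf = nan here; log space gives the limit
        lo = secretion_fraction(p, p.G_b / 10)
        assert lo == 0.0
        p2 = params.replace(gamma=200.0, beta=1.2)
        hi = secretion_fraction(p2, 2 * p2.G_b)
        assert np.isfinite(hi) and hi > 1.0


class TestModelRhs:
    def test_basal_point_is_equilibrium(self, params):
        state = ModelState(0.0, 0.0, 0.0, params.G_b, params.I_b)
        p0 = params.replace(D=0.0)
        np.testing.assert_allclose(model_rhs(p0, 0.0, state), np.zeros(5), atol=1e-14)

    def test_insulin_equilibrium_at_basal_signal(self, params):
        # I = I_b with G~ = G_b gives dI/dt = 0 for any beta, gamma
        for beta, gamma in [(0.3, 1.0), (5.0, 7.5)]:
            p = params.replace(beta=beta, gamma=gamma)
            state = ModelState(0.0, 0.0, 0.0, p.G_b, p.I_b)
            assert model_rhs(p, 0.0, state)[4] == pytest.approx(0.0, abs=1e-14)

    def test_term_wise_oracle(self, params):
        # independent re-coding of every printed term
        p = params
        state = ModelState(S=3e4, J=1.2e4, L=4e3, G=130.0, I=22.0)
        t = 55.0
        got = model_rhs(p, t, state)
        gprod0 = (p.k_xg + p.k_xgi * p.I_b) * p.G_b
        gprod = p.k_lambda / (p.k_lambda / gprod0 + (state.G - p.G_b))
        a = p.k_gj + p.k_jl
        J_shift = p.D * p.k_js * (
            np.exp(-p.k_js * (t - p.tau)) - np.exp(-a * (t - p.tau))) / (a - p.k_js)
        phi = J_shift if t >= p.tau else 0.0
        g_tilde = state.G + p.f_gj * (p.k_gj * state.J + p.k_gl * state.L)
        sigma = (p.beta ** p.gamma + 1) / (
            p.beta ** p.gamma * (p.G_b / g_tilde) ** p.gamma + 1)
        expected = np.array([
            -p.k_js * state.S,
            p.k_js * state.S - a * state.J,
            p.k_jl * phi - p.k_gl * state.L,
            -(p.k_xg + p.k_xgi * state.I) * state.G + gprod
            + p.eta * (p.k_gj * state.J + p.k_gl * state.L),
            p.k_xi * p.I_b * (sigma - state.I / p.I_b),
        ])
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_non_finite_state_rejected(self, params):
        with pytest.raises(ValueError):
            model_rhs(params, 0.0, ModelState(np.nan, 0, 0, 90, 8))


class TestBasalProductionAndSensitivity:
    def test_insulin_independent_balance(self, params):
        p = params.replace(k_xgi=1e-300)
        assert derive_basal_production(p) == pytest.approx(p.k_xg * p.G_b)

    def test_arithmetic_example(self):
        p = default_parameters(G_b=90.0, I_b=10.0).replace(k_xg=0.01, k_xgi=1e-4)
        assert derive_basal_production(p) == pytest.approx(0.99)

    def test_sensitivity_is_k_xgi(self, params):
        assert insulin_sensitivity(params) == params.k_xgi

    def test_sensitivity_finite_difference_oracle(self, params):
        # S_I = dE/dI with E = -d(dG/dt)/dG, central differences at basal
        p = params

        def E(I):
            hG = 1e-4
            up = model_rhs(p, 0.0, ModelState(0, 0, 0, p.G_b + hG, I))[3]
            dn = model_rhs(p, 0.0, ModelState(0, 0, 0, p.G_b - hG, I))[3]
            return -(up - dn) / (2 * hG)

        hI = 1e-4
        S_I = (E(p.I_b + hI) - E(p.I_b - hI)) / (2 * hI)
        assert S_I == pytest.approx(p.k_xgi, rel=1e-6)
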