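"""Sliding surface, reaching laws, adaptive gain, hybrid control."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import glucoreg as g
from glucoreg.smc import SlidingConfig, init_surface, surface_step, surface_rate


@st.composite
def state_vectors(draw):
    f = st.floats(-500, 500, allow_nan=False)
    return np.array([draw(f) for _ in range(4)])


class TestConfig:
    def test_published_modulation_gain(self, sliding):
        # m * beta = 1.59 * 4.48, printed as 7.12
        assert sliding.Mo == pytest.approx(1.59 * 4.48, abs=1e-15)
        assert sliding.Mo == pytest.approx(7.12, abs=0.005)

    def test_mo_consistency_enforced(self):
        with pytest.raises(ValueError, match="Mo"):
            SlidingConfig(Mo=9.99)

    def test_strict_mode_recomputes_m_with_warning(self, sliding):
        with pytest.warns(UserWarning, match="g1/g3"):
            strict = sliding.strict()
        assert strict.m == pytest.approx(0.0088 / 0.0052)
        assert strict.Mo == pytest.approx(strict.m * strict.beta, abs=1e-15)

    def test_beta_outside_admissible_range_warns(self):
        with pytest.warns(UserWarning, match="admissible range"):
            SlidingConfig(beta=10.1)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            SlidingConfig(g1=0.0)


class TestSurface:
    @given(x0=state_vectors())
    @settings(max_examples=50, deadline=None)
    def test_initial_surface_is_zero(self, x0):
        cfg = SlidingConfig()
        assert init_surface(cfg, x0).s == 0.0

    def test_initial_z_hand_value(self, sliding):
        # z(0) = -(0.0088*200 + 0.0052*50) = -2.02
        surf = init_surface(sliding, [200.0, 0.0, 50.0, 0.0])
        assert surf.z == pytest.approx(-2.02)

    def test_zero_state_zero_input_rate_is_affine_term(self, sliding, patient1):
        for affine in ("printed", "setpoint"):
            model = g.linearize(patient1, affine=affine)
            zdot = surface_rate(sliding, np.zeros(4), 0.0, model)
            assert zdot == pytest.approx(-float(sliding.G @ model.affine()), rel=1e-12)
        printed = g.linearize(patient1, affine="printed")
        assert surface_rate(sliding, np.zeros(4), 0.0, printed) == pytest.approx(
            -(0.0088 * 80 + 3.65e-4 * 80)
        )

    def test_surface_stays_zero_on_model_trajectory(self, sliding, model1, gains):
        """Along a trajectory of dx/dt = A x + B u_lq + H Gss the surface
        must remain ~0 (the z-dynamics replicate the model exactly; the
        residual is the trapezoid quadrature error at the 60-s step)."""
        K = gains.as_array()
        def f(t, x):
            return model1.A @ x - model1.B * (K @ x) + model1.affine()
        x0 = np.array([200.0, 0.0, 50.0, 0.0])
        dt = 1.0
        sol = solve_ivp(f, (0, 60), x0, rtol=1e-11, atol=1e-11,
                        t_eval=np.arange(0, 61, dt))
        surf = init_surface(sliding, x0, u_lq0=float(-K @ x0), model=model1)
        smax = 0.0
        for x in sol.y.T[1:]:
            surf = surface_step(surf, x, float(-K @ x), model1, dt, sliding)
            smax = max(smax, abs(surf.s))
        assert smax < 5e-3

    def test_trapezoid_beats_euler_at_second_order(self, sliding, model1):
        """Halving dt shrinks the Euler-vs-trapezoid discrepancy ~4x."""
        x_old = np.array([150.0, 1e-3, 20.0, -50.0])
        x_new = np.array([140.0, 2e-3, 25.0, -60.0])
        diffs = []
        for dt in (1.0, 0.5):
            surf0 = init_surface(sliding, x_old, u_lq0=1.0, model=model1)
            trap = surface_step(surf0, x_new, 2.0, model1, dt, sliding).z
            eul = surface_step(surf0, x_new, 2.0, model1, dt, sliding, rule="euler").z
            diffs.append(abs(trap - eul))
        assert diffs[0] / diffs[1] == pytest.approx(2.0, rel=1e-9)  # dt/2 * delta-rate
        # the discrepancy itself is O(dt^2) relative to the rate change
        assert diffs[1] < diffs[0]

    def test_dt_must_be_positive(self, sliding, model1):
        surf = init_surface(sliding, np.zeros(4))
        with pytest.raises(ValueError):
            surface_step(surf, np.zeros(4), 0.0, model1, 0.0, sliding)


class TestReachingLaw:
    @pytest.mark.parametrize("mode", ["sgn", "tanh"])
    def test_zero_surface_gives_zero(self, mode):
        assert g.reaching_law(0.0, 4.48, mode) == 0.0

    def test_sign_flip(self):
        assert g.reaching_law(-2.0, 4.48, "sgn") == 4.48

    def test_tanh_value(self):
        assert g.reaching_law(0.5, 4.48, "tanh") == pytest.approx(-2.0705, abs=5e-4)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            g.reaching_law(1.0, -1.0)
        with pytest.raises(ValueError):
            g.reaching_law(1.0, 1.0, "square")


class TestAdaptiveGain:
    def test_closed_form_limits(self, sliding):
        assert g.adaptive_gain(sliding.Mo, 0.06, 0.0) == 0.0
        assert g.adaptive_gain(sliding.Mo, 0.06, 1e6) == pytest.approx(sliding.Mo, rel=1e-12)

    def test_printed_worked_value(self):
        # Mo=7.12, gamma=0.06, err=120 -> 7.12 * (1 - sech(7.2)) ~ 7.109
        assert g.adaptive_gain(7.12, 0.06, 120.0) == pytest.approx(7.109, abs=5e-4)

    @given(
        Mo=st.floats(0.1, 50, allow_nan=False),
        gamma=st.floats(1e-3, 2.0, allow_nan=False),
        err=st.floats(-400, 400, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_even_bounded_monotone(self, Mo, gamma, err):
        M = g.adaptive_gain(Mo, gamma, err)
        assert 0.0 <= M <= Mo
        assert M == pytest.approx(g.adaptive_gain(Mo, gamma, -err), rel=1e-12)
        if gamma * abs(err) < 20:  # below floating-point saturation of sech
            assert M < Mo
            if abs(err) > 1e-6:
                assert g.adaptive_gain(Mo, gamma, 1.2 * err) > M


class TestHybridControl:
    def test_surface_zero_reduces_to_lqir(self, gains, sliding):
        x = [150.0, 0.0, 30.0, -10.0]
        surf = g.SurfaceState(z=0.0, s=0.0)
        u = g.hybrid_control(gains, x, surf, sliding, err=-70.0)
        assert u == g.lqir_control(gains, x)

    def test_zero_error_disables_adaptive_term(self, gains, sliding):
        x = [150.0, 0.0, 30.0, -10.0]
        surf = g.SurfaceState(z=0.0, s=5.0)
        assert g.hybrid_control(gains, x, surf, sliding, err=0.0) == g.lqir_control(gains, x)

    def test_published_composition(self, gains, sliding):
        # u = u_lq - M(120) * tanh(1) with the published configuration
        x = [200.0, 0.0, 50.0, 0.0]
        surf = g.SurfaceState(z=0.0, s=1.0)
        u = g.hybrid_control(gains, x, surf, sliding, err=120.0)
        expected = g.lqir_control(gains, x) - g.adaptive_gain(
            sliding.Mo, sliding.gamma, 120.0
        ) * np.tanh(1.0)
        assert u == pytest.approx(expected, rel=1e-12)

    def test_nonadaptive_uses_fixed_gain_and_mode(self, gains):
        cfg = SlidingConfig(adaptive=False, mode="sgn")
        x = np.zeros(4)
        surf = g.SurfaceState(z=0.0, s=-0.3)
        assert g.hybrid_control(gains, x, surf, cfg) == pytest.approx(cfg.Mo)

    def test_adaptive_requires_error(self, gains, sliding):
        with pytest.raises(ValueError):
            g.hybrid_control(gains, np.zeros(4), g.SurfaceState(0.0, 1.0), sliding)


class TestStabilityCondition:
    def test_published_beta_exceeds_bound(self, sliding):
        assert g.stability_condition(sliding, d_max=4.0)

    def test_strict_inequality(self):
        cfg = SlidingConfig(beta=4.0, m=1.59)
        assert not g.stability_condition(cfg, d_max=4.0)

    def test_channel_gain_identity(self, patient1):
        """With m = g1/g3: (G B) m = (G F) = g1/V1 exactly."""
        with pytest.warns(UserWarning):
            cfg = SlidingConfig().strict()
        model = g.linearize(patient1)
        GBm = float(cfg.G @ model.B) * cfg.m
        GF = float(cfg.G @ model.F)
        assert GBm == pytest.approx(GF, rel=1e-14)
        assert GF == pytest.approx(cfg.g1 / patient1.V1, rel=1e-14)

    def test_reduced_sliding_descent(self, patient1):
        """On the reduced dynamics ds/dt = (GB)m u_s + (GF)d with
        beta > sup|d|, the surface reaches 0 and Y = s^2/2 decreases
        between switching instants."""
        with pytest.warns(UserWarning):
            cfg = SlidingConfig().strict()
        model = g.linearize(patient1)
        dt = 0.05
        s = 0.5
        Y_prev = 0.5 * s * s
        reached = False
        for k in range(60000):
            d = 4.0 * np.sin(0.3 * k * dt)  # bounded |d| <= 4 < beta
            s = s + dt * g.reduced_surface_rate(cfg, model, s, d, mode="sgn")
            Y = 0.5 * s * s
            if not reached and abs(s) < 0.02:
                reached = True
            if not reached:
                assert Y < Y_prev  # strict Lyapunov descent before reaching
            Y_prev = Y
        assert reached
        assert abs(s) < 0.02  # stays in the chattering band around 0
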