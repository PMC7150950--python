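"""Fiber descriptors, forces, Jeffery rotation and the state integrator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fiberdep.fibers import (AIR, AirProperties, FiberSpec, FiberState,
                             advance_state, drag_force, fiber_axes,
                             jeffery_rotation_rate, lift_force,
                             oberbeck_resistance, relaxation_time,
                             saffman_lift, stokes_diameter, stokes_number)
from fiberdep.flow import simple_shear_field


class StillAir:
    """Quiescent unbounded flow fixture."""

    domain = None

    def velocity(self, x, t):
        return np.zeros(3)

    def gradient(self, x, t):
        return np.zeros((3, 3))


class TestFiberAxes:
    @pytest.mark.parametrize("d_um,ar,a_um,b_um", [
        (2.0, 1.0, 1.0, 1.0),
        (2.0, 8.0, 0.5, 4.0),       # 8**(1/3) = 2 exactly
        (5.0, 30.0, 0.80457449, 24.13723462),
    ])
    def test_semi_axes(self, d_um, ar, a_um, b_um):
        a, b = fiber_axes(d_um * 1e-6, ar)
        assert a == pytest.approx(a_um * 1e-6, rel=1e-7)
        assert b == pytest.approx(b_um * 1e-6, rel=1e-7)

    @given(d=st.floats(0.5, 50), ar=st.floats(1, 100))
    @settings(max_examples=50, deadline=None)
    def test_volume_equivalence(self, d, ar):
        a, b = fiber_axes(d * 1e-6, ar)
        vol = (4 / 3) * math.pi * a * a * b
        sphere = (4 / 3) * math.pi * (d * 1e-6 / 2) ** 3
        assert vol == pytest.approx(sphere, rel=1e-12)

    def test_oblate_rejected(self):
        with pytest.raises(ValueError, match="oblate"):
            fiber_axes(2e-6, 0.5)


class TestStokesDiameter:
    def test_sphere_limit_equals_dp(self):
        assert stokes_diameter(1e-6, 1.0) == pytest.approx(2e-6, rel=1e-12)
        spec = FiberSpec(3e-6, 1.0)
        assert spec.d_stk == pytest.approx(spec.d_p, rel=1e-12)

    def test_printed_formula_at_ar_ten(self):
        # a_p = 0.46416 um for d_p = 2 um: factor sqrt(10 ln(10+sqrt99)/sqrt99)
        a, _ = fiber_axes(2e-6, 10.0)
        assert a == pytest.approx(0.46415888e-6, rel=1e-7)
        assert stokes_diameter(a, 10.0) == pytest.approx(1.610117e-6,
                                                         rel=1e-6)

    def test_strictly_decreasing_in_ar(self):
        ars = np.linspace(1.0, 30.0, 120)
        vals = [FiberSpec(2e-6, ar).d_stk for ar in ars]
        assert np.all(np.diff(vals) < 0)
        assert all(v <= 2e-6 for v in vals)


class TestRelaxationAndStokesNumber:
    def test_hand_evaluated_relaxation_time(self):
        assert relaxation_time(2e-6, 1000.0, 1.81e-5) == pytest.approx(
            1.2277e-5, rel=1e-4)

    def test_quadratic_scaling(self):
        t1 = relaxation_time(2e-6, 1000.0, 1.81e-5)
        t2 = relaxation_time(4e-6, 1000.0, 1.81e-5)
        assert t2 / t1 == pytest.approx(4.0, rel=1e-12)

    def test_stokes_number_arithmetic(self):
        assert stokes_number(1.2277e-5, 3.0, 0.02) == pytest.approx(
            1.842e-3, rel=1e-3)
        assert stokes_number(1.2277e-5, 0.0, 0.02) == 0.0

    def test_elongation_reduces_stokes_number(self):
        # at fixed d_p, larger AR means smaller d_Stk, t0 and Stk
        stks = [FiberSpec(5e-6, ar).stokes_number(3.0, 0.02)
                for ar in (1, 3, 10, 30)]
        assert np.all(np.diff(stks) < 0)


class TestDrag:
    def test_sphere_limit_is_stokes_law(self):
        spec = FiberSpec(2e-6, 1.0)
        F = drag_force(spec, [0, 0, 1], [1e-3, 0, 0])
        expected = 3 * math.pi * 1.81e-5 * 2e-6 * 1e-3
        assert np.linalg.norm(F) == pytest.approx(expected, rel=1e-9)

    def test_zero_slip_zero_force(self):
        spec = FiberSpec(2e-6, 10.0)
        assert np.allclose(drag_force(spec, [0, 0, 1], [0, 0, 0]), 0.0)

    @pytest.mark.parametrize("ar", [1.0, 3.0, 10.0, 30.0])
    def test_resistance_tensor_spd(self, ar):
        spec = FiberSpec(2e-6, ar)
        p = np.array([0.36, 0.48, 0.8])
        p /= np.linalg.norm(p)
        K = (spec.k_par * np.outer(p, p)
             + spec.k_perp * (np.eye(3) - np.outer(p, p)))
        assert np.allclose(K, K.T)
        assert np.all(np.linalg.eigvalsh(K) > 0)

    def test_anisotropy_grows_towards_two(self):
        ratios = [FiberSpec(2e-6, ar).k_perp / FiberSpec(2e-6, ar).k_par
                  for ar in (1, 3, 10, 30, 100, 1000)]
        assert ratios[0] == pytest.approx(1.0, rel=1e-9)
        assert np.all(np.diff(ratios) > 0)
        assert all(r < 2.0 for r in ratios)

    def test_resistances_reduce_to_sphere(self):
        kp, kt = oberbeck_resistance(1e-6, 1e-6 * (1 + 1e-9))
        assert kp == pytest.approx(6 * math.pi * 1e-6, rel=1e-6)
        assert kt == pytest.approx(6 * math.pi * 1e-6, rel=1e-6)


class TestJeffery:
    def test_zero_gradient_zero_rate(self):
        spec = FiberSpec(2e-6, 10.0)
        rate = jeffery_rotation_rate(spec, [1, 0, 0], np.zeros((3, 3)))
        assert np.allclose(rate, 0.0)

    def test_sphere_rotates_at_half_vorticity(self):
        spec = FiberSpec(2e-6, 1.0)
        G = simple_shear_field(10.0).gradient(np.zeros(3))
        rate = jeffery_rotation_rate(spec, [1, 0, 0], G)
        np.testing.assert_allclose(rate, [0, -5.0, 0], atol=1e-12)

    @given(st.floats(1.0, 50.0), st.integers(0, 10 ** 6))
    @settings(max_examples=40, deadline=None)
    def test_rate_orthogonal_to_axis(self, ar, seed):
        rng = np.random.default_rng(seed)
        spec = FiberSpec(2e-6, ar)
        p = rng.normal(size=3)
        p /= np.linalg.norm(p)
        G = rng.normal(size=(3, 3)) * 10
        rate = jeffery_rotation_rate(spec, p, G)
        assert abs(np.dot(rate, p)) < 1e-9 * max(np.linalg.norm(rate), 1)

    @pytest.mark.parametrize("ar", [3.0, 10.0, 30.0])
    def test_orbit_period_closed_form(self, ar):
        gd = 10.0
        spec = FiberSpec(2e-6, ar)
        G = simple_shear_field(gd).gradient(np.zeros(3))
        p = np.array([1.0, 0.0, 0.0])
        dt = 2e-4 / gd * 10
        t, unwrapped, prev = 0.0, 0.0, 0.0
        while abs(unwrapped) < 2 * math.pi:
            k1 = jeffery_rotation_rate(spec, p, G)
            ph = p + 0.5 * dt * k1
            ph /= np.linalg.norm(ph)
            p = p + dt * jeffery_rotation_rate(spec, ph, G)
            p /= np.linalg.norm(p)
            ang = math.atan2(p[1], p[0])
            d = ang - prev
            d -= 2 * math.pi * round(d / (2 * math.pi))
            unwrapped += d
            prev = ang
            t += dt
        T = 2 * math.pi * (ar + 1 / ar) / gd
        assert t == pytest.approx(T, rel=0.01)


class TestLift:
    def test_uniform_flow_no_lift(self):
        spec = FiberSpec(2e-6, 1.0)
        F = lift_force(spec, [0.01, 0, 0], np.zeros((3, 3)))
        assert np.allclose(F, 0.0)

    def test_zero_slip_no_lift(self):
        G = np.zeros((3, 3))
        G[0, 1] = 100.0
        spec = FiberSpec(2e-6, 1.0)
        assert np.allclose(lift_force(spec, [0, 0, 0], G), 0.0)

    def test_saffman_magnitude(self):
        # 1.615 mu d^2 |u_rel| sqrt(gd / nu) at nu = 1.5e-5
        G = np.zeros((3, 3))
        G[0, 1] = 100.0
        air = AirProperties(viscosity=1.81e-5, density=1.81e-5 / 1.5e-5)
        spec = FiberSpec(2e-6, 1.0, air=air)
        F = saffman_lift(spec, np.array([0.01, 0, 0]), G, air)
        expected = 1.615 * 1.81e-5 * (2e-6) ** 2 * 0.01 \
            * math.sqrt(100.0 / 1.5e-5)
        assert np.linalg.norm(F) == pytest.approx(expected, rel=1e-9)

    def test_lagging_particle_pushed_to_fast_side(self):
        G = np.zeros((3, 3))
        G[0, 1] = 100.0   # u_x grows with +y
        spec = FiberSpec(2e-6, 1.0)
        F = saffman_lift(spec, np.array([0.01, 0, 0]), G)  # fluid faster
        assert F[1] > 0

    def test_pluggable_none_disables_lift(self):
        G = np.zeros((3, 3))
        G[0, 1] = 100.0
        spec = FiberSpec(2e-6, 1.0)
        assert np.allclose(lift_force(spec, [0.01, 0, 0], G, model=None), 0.0)


class TestAdvanceState:
    def test_settling_relaxation_closed_form(self):
        spec = FiberSpec(2e-6, 1.0)
        state = FiberState(np.zeros(3), np.zeros(3), [0, 0, 1])
        t0 = spec.t0
        out = advance_state(state, spec, StillAir(), dt=5 * t0,
                            gravity_vector=[0, -1, 0])
        vt = t0 * spec.air.gravity
        assert out.velocity[1] == pytest.approx(-vt * (1 - math.exp(-5)),
                                                rel=1e-9)
        assert abs(out.velocity[1] + vt) / vt < 0.01  # within 1% of terminal

    def test_terminal_speed_equals_t0_g(self):
        for d_um in (1.0, 5.0, 10.0):
            spec = FiberSpec(d_um * 1e-6, 1.0)
            state = FiberState(np.zeros(3), np.zeros(3), [0, 0, 1])
            for _ in range(12):
                state = advance_state(state, spec, StillAir(),
                                      dt=3 * spec.t0,
                                      gravity_vector=[0, -1, 0])
            assert abs(-state.velocity[1] - spec.settling_speed()) \
                / spec.settling_speed() < 0.005

    def test_perfect_tracer_keeps_flow_velocity(self):
        class Uniform(StillAir):
            def velocity(self, x, t):
                return np.array([0.3, 0.0, 0.0])

        spec = FiberSpec(2e-6, 1.0)
        state = FiberState(np.zeros(3), [0.3, 0, 0], [0, 0, 1])
        out = advance_state(state, spec, Uniform(), dt=1e-4,
                            gravity_vector=[0, 0, 0],
                            air=AirProperties(gravity=1e-30))
        np.testing.assert_allclose(out.velocity, [0.3, 0, 0], rtol=1e-12)

    def test_fiber_orbit_period_via_integrator(self):
        # low-inertia fiber in simple shear follows the Jeffery orbit
        gd = 50.0
        spec = FiberSpec(1e-6, 10.0)
        assert spec.t0 * gd < 0.01
        flow = simple_shear_field(gd)
        state = FiberState(np.zeros(3), np.zeros(3), [1, 0, 0])
        dt = 5e-5
        t, unwrapped, prev = 0.0, 0.0, 0.0
        air = AirProperties(gravity=1e-30)
        while abs(unwrapped) < 2 * math.pi and t < 30:
            state = advance_state(state, spec, flow, air=air, dt=dt,
                                  gravity_vector=[0, 0, 0])
            ang = math.atan2(state.orientation[1], state.orientation[0])
            d = ang - prev
            d -= 2 * math.pi * round(d / (2 * math.pi))
            unwrapped += d
            prev = ang
            t += dt
        T = 2 * math.pi * (10 + 0.1) / gd
        assert t == pytest.approx(T, rel=0.01)

    def test_orientation_norm_preserved(self):
        spec = FiberSpec(2e-6, 10.0)
        flow = simple_shear_field(100.0)
        state = FiberState(np.zeros(3), np.zeros(3), [0.6, 0.8, 0.0])
        for _ in range(200):
            state = advance_state(state, spec, flow, dt=1e-4,
                                  gravity_vector=[0, 0, 0])
            assert abs(np.linalg.norm(state.orientation) - 1.0) < 1e-9

    def test_settling_anisotropy_of_fibers(self):
        # lengthwise settling is faster; the ratio tends to 2 for slender
        for ar, lo in ((10.0, 1.35), (1000.0, 1.69)):
            spec = FiberSpec(2e-6, ar)
            ratio = spec.k_perp / spec.k_par  # v_par/v_perp at equal weight
            assert lo < ratio < 2.0

    def test_non_airborne_state_rejected(self):
        spec = FiberSpec(2e-6, 1.0)
        state = FiberState(np.zeros(3), np.zeros(3), [0, 0, 1],
                           status="deposited")
        with pytest.raises(ValueError):
            advance_state(state, spec, StillAir(), dt=1e-4)
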