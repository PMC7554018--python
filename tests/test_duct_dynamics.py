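import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from vestiflow import (MotionCoefficients, RegimeError, RotationStop,
                       coupled_modes, elasticity_for_T1, loop_system_matrices,
                       max_excursion, motion_coefficients,
                       solve_initial_velocities, step_response,
                       time_constants)
from vestiflow.geometry import DuctSection, EndolymphProps


@pytest.fixture(scope="module")
def duct_015():
    """Straight duct, r = 0.2 mm, l = 15 mm, water-like endolymph."""
    sec = DuctSection("d", "A", "B", ((0, 0, 0), (0.015, 0, 0)), radius=2e-4)
    return sec, EndolymphProps(rho=1000.0, eta=1e-3)


class TestMotionCoefficients:
    def test_mass_and_friction_arithmetic(self, duct_015):
        sec, props = duct_015
        c = motion_coefficients(sec, props, S=0.0)
        assert c.M == pytest.approx(1000 * math.pi * 4e-8 * 0.015, rel=1e-12)
        assert c.M == pytest.approx(1.885e-6, rel=1e-3)
        assert c.F == pytest.approx(8 * math.pi * 1e-3 * 0.015, rel=1e-12)
        assert c.F == pytest.approx(3.770e-4, rel=1e-3)

    def test_springless_section_has_no_slow_constant(self, duct_015):
        sec, props = duct_015
        tc = time_constants(motion_coefficients(sec, props, S=0.0))
        assert tc.T1 is None and tc.zeta is None and tc.T2 > 0


class TestTimeConstants:
    def test_fast_constant_equals_radius_form(self, duct_015):
        sec, props = duct_015
        c = motion_coefficients(sec, props, S=1e-5)
        tc = time_constants(c, r=sec.radius, nu=props.nu)
        assert tc.T2 == pytest.approx((2e-4) ** 2 / 8e-6, rel=1e-12)
        assert tc.T2 == pytest.approx(5e-3, rel=1e-12)

    def test_radius_cross_check_rejects_inconsistent_input(self, duct_015):
        sec, props = duct_015
        c = motion_coefficients(sec, props, S=1e-5)
        with pytest.raises(ValueError):
            time_constants(c, r=2 * sec.radius, nu=props.nu)

    def test_damping_ratio_of_human_duct_is_order_30(self):
        c = MotionCoefficients(M=1.0, F=1.0 / 5e-3, S=1.0 / (20.0 * 5e-3))
        tc = time_constants(c)
        assert tc.T1 == pytest.approx(20.0)
        assert tc.zeta == pytest.approx(0.5 * math.sqrt(4000.0), rel=1e-12)
        assert round(tc.zeta, -1) == 30.0

    def test_equal_constants_give_half_damping(self):
        c = MotionCoefficients(M=1.0, F=1.0, S=1.0)
        assert time_constants(c).zeta == pytest.approx(0.5)


class TestStepResponse:
    def make(self, T1=20.0, T2=5e-3):
        # M/F = T2 and F/S = T1 with F = 1
        return MotionCoefficients(M=T2, F=1.0, S=1.0 / T1)

    def test_peak_matches_v0_T2_approximation(self):
        c = self.make()
        v0 = 2e-3
        exact = max_excursion(c, v0)
        approx = max_excursion(c, v0, approximate=True)
        assert approx == pytest.approx(1.0e-5, rel=1e-12)
        T1, T2 = 20.0, 5e-3
        assert abs(exact - approx) / approx < (T2 / T1) * math.log(T1 / T2)

    def test_time_series_peak_agrees_with_closed_form(self):
        c = self.make()
        t = np.linspace(0.0, 0.1, 20001)
        x = step_response(c, x0=0.0, v0=2e-3, t_grid=t)
        assert x[0] == pytest.approx(0.0, abs=1e-18)
        assert x.max() == pytest.approx(max_excursion(c, 2e-3), rel=1e-6)

    def test_pure_relaxation_decays_monotonically(self):
        c = self.make()
        t = np.linspace(0.0, 100.0, 500)
        x = step_response(c, x0=1e-6, v0=0.0, t_grid=t)
        assert np.all(np.diff(x) <= 1e-24)
        assert np.all(x >= -1e-24)
        assert x[-1] < 1e-2 * x[0]

    def test_underdamped_parameters_rejected(self):
        with pytest.raises(RegimeError):
            step_response(MotionCoefficients(M=1.0, F=0.1, S=1.0),
                          0.0, 1.0, [0.0])


@pytest.fixture(scope="module")
def decomposition(three_duct_net, three_duct_S):
    stim = RotationStop(omega=(0.0, 0.0, 1.0))
    init = solve_initial_velocities(three_duct_net, stim)
    return coupled_modes(three_duct_net, three_duct_S, init), init


class TestCoupledModes:
    def test_six_positive_time_constants(self, decomposition):
        dec, _ = decomposition
        assert len(dec.time_constants) == 6
        assert np.all(dec.time_constants > 0)

    def test_three_fast_constants_nearly_equal(self, decomposition):
        dec, _ = decomposition
        fast = np.sort(dec.time_constants)[:3]
        assert fast.max() / fast.min() < 1.05

    def test_slow_constants_two_equal_one_about_half(self, decomposition):
        dec, _ = decomposition
        slow = np.sort(dec.time_constants)[3:][::-1]
        assert slow[0] / slow[1] < 1.05
        half_ratio = slow[2] / (0.5 * (slow[0] + slow[1]))
        assert 0.5 * 0.8 < half_ratio < 0.5 * 1.2

    def test_reconstruction_matches_stiff_ode_integration(
            self, three_duct_net, three_duct_S, decomposition):
        dec, init = decomposition
        Lt, Rt, Ct, B = loop_system_matrices(three_duct_net, three_duct_S)
        k = B.shape[1]
        areas = np.array([s.area for s in three_duct_net.sections])
        v0 = init.velocity_vector(three_duct_net.section_names) * areas
        zdot0, *_ = np.linalg.lstsq(B, v0, rcond=None)
        A = np.block([
            [np.zeros((k, k)), np.eye(k)],
            [-np.linalg.solve(Lt, Ct), -np.linalg.solve(Lt, Rt)],
        ])
        T_slow = dec.time_constants.max()
        t = np.linspace(0.0, 5.0 * T_slow, 200)
        sol = solve_ivp(lambda _, y: A @ y, (0.0, t[-1]),
                        np.concatenate([np.zeros(k), zdot0]),
                        method="Radau", t_eval=t, rtol=1e-10, atol=1e-24)
        x_ode = (B @ sol.y[:k]) / areas[:, None]
        x_modes = dec.evaluate(t).to_numpy().T
        scale = np.abs(x_ode).max()
        assert np.max(np.abs(x_modes - x_ode)) / scale < 1e-6

    def test_volume_continuity_holds_along_solution(self, three_duct_net,
                                                    decomposition):
        dec, _ = decomposition
        D = three_duct_net.incidence_matrix()
        areas = np.array([s.area for s in three_duct_net.sections])
        t = np.linspace(0.0, 60.0, 50)
        x = dec.evaluate(t).to_numpy()          # displacements
        vel = -(dec.amplitudes.to_numpy() / dec.time_constants[None, :]) @ \
            np.exp(-t[None, :] / dec.time_constants[:, None])
        for arr in (x.T, vel):
            flux = D @ (areas[:, None] * arr)
            assert np.abs(flux).max() < 1e-10 * np.abs(
                areas[:, None] * arr).max()

    def test_pressure_difference_consistency(self, three_duct_net,
                                             three_duct_S, decomposition):
        """Both parallel sections C->A (duct p, crus c) report the same
        confluence pressure difference along the solution."""
        dec, _ = decomposition
        net = three_duct_net
        t = np.linspace(1e-4, 40.0, 300)
        T = dec.time_constants
        amp = dec.amplitudes
        sides = {}
        for name in ("p", "c"):
            sec = net[name]
            c = motion_coefficients(sec, net.props,
                                    three_duct_S if sec.elastic else 0.0)
            a = amp.loc[name].to_numpy()
            x = (np.exp(-t[:, None] / T) * a).sum(axis=1)
            v = (np.exp(-t[:, None] / T) * (-a / T)).sum(axis=1)
            acc = (np.exp(-t[:, None] / T) * (a / T**2)).sum(axis=1)
            sides[name] = (c.M * acc + c.F * v + c.S * x) / sec.area
        scale = max(np.abs(sides["p"]).max(), np.abs(sides["c"]).max())
        assert np.max(np.abs(sides["p"] - sides["c"])) / scale < 1e-8

    def test_large_stiffness_limit_recovers_single_duct_T1(
            self, three_duct_net, three_duct_S):
        stim = RotationStop(omega=(0.0, 0.0, 1.0))
        init = solve_initial_velocities(three_duct_net, stim)
        base = coupled_modes(three_duct_net, three_duct_S, init)
        stiff = coupled_modes(three_duct_net, 10.0 * three_duct_S, init)
        slow_b = np.sort(base.time_constants)[3:]
        slow_s = np.sort(stiff.time_constants)[3:]
        # slow constants scale as 1/S up to the O(T2/T1) inertia correction
        T2 = np.sort(stiff.time_constants)[:3].max()
        np.testing.assert_allclose(slow_s, slow_b / 10.0,
                                   rtol=2.0 * T2 / slow_s.min())
        # ... and approach the per-duct F/S values (common parts are a small
        # correction in this geometry)
        props = three_duct_net.props
        f_over_s = sorted(
            8 * math.pi * props.eta * three_duct_net[n].length / three_duct_S
            for n in ("a", "p", "h"))
        np.testing.assert_allclose(np.sort(slow_b), f_over_s, rtol=0.05)

    def test_nonpositive_stiffness_rejected(self, three_duct_net):
        init = solve_initial_velocities(three_duct_net, impulses={"a": 1e-9})
        with pytest.raises(ValueError):
            coupled_modes(three_duct_net, 0.0, init)

    def test_elasticity_for_T1_round_trip(self, three_duct_net):
        sec = three_duct_net["a"]
        S = elasticity_for_T1(sec, three_duct_net.props, 20.0)
        c = motion_coefficients(sec, three_duct_net.props, S)
        assert time_constants(c).T1 == pytest.approx(20.0, rel=1e-12)
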