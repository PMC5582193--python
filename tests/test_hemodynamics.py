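import numpy as np
import pytest
from scipy.optimize import brentq

from vffr import (
    AorticWaveformParams,
    CMVParameters,
    IntramyocardialParams,
    LesionCharacteristic,
    ParameterError,
    SimulationConfig,
    lesion_dp,
    pseudotransient_step,
    simulate_pseudotransient,
    steady_vffr,
    synthesize_aortic_pressure,
)


def constant_pa(value=100.0):
    return synthesize_aortic_pressure(
        AorticWaveformParams(60, value, value, 1 / 3), dt=1e-3
    )


class TestSteadySolver:
    def test_no_lesion_gives_unity(self):
        res = steady_vffr(100.0, LesionCharacteristic(0, 0), 20.0)
        assert res.vffr == pytest.approx(1.0)

    def test_equal_series_resistances_half(self):
        res = steady_vffr(100.0, LesionCharacteristic(25, 0), 25.0)
        assert res.vffr == pytest.approx(0.5)

    def test_worked_quadratic_case(self):
        # oracle: positive root of 5Q^2 + 30Q - 100 = 0
        q_ref = brentq(lambda q: 5 * q ** 2 + 30 * q - 100, 0, 10, xtol=1e-14)
        assert abs(5 * q_ref ** 2 + 30 * q_ref - 100) < 1e-10
        res = steady_vffr(100.0, LesionCharacteristic(5, 5), 25.0)
        assert res.q_trace[0] == pytest.approx(q_ref, rel=1e-10)
        assert res.vffr == pytest.approx(25 * q_ref / 100, rel=1e-10)

    def test_governing_residual_random_parameters(self, rng):
        for _ in range(200):
            pa = rng.uniform(60, 140)
            les = LesionCharacteristic(rng.uniform(0, 20), rng.uniform(0, 10))
            r = rng.uniform(5, 80)
            pv = rng.uniform(0, 10)
            res = steady_vffr(pa, les, r, pv)
            q = (res.mean_pd - pv) / r
            resid = abs(pa - pv - lesion_dp(les, q) - r * q)
            assert resid < 1e-9 * pa
            assert res.vffr == pytest.approx(res.mean_pd / res.mean_pa, abs=1e-12)

    def test_monotonic_in_lesion_and_resistance(self, rng):
        for _ in range(50):
            pa = rng.uniform(70, 120)
            z1, z2, r = rng.uniform(0, 10), rng.uniform(0, 5), rng.uniform(5, 60)
            base = steady_vffr(pa, LesionCharacteristic(z1, z2), r).vffr
            assert steady_vffr(pa, LesionCharacteristic(z1 * 1.3 + 0.1, z2), r).vffr <= base
            assert steady_vffr(pa, LesionCharacteristic(z1, z2 * 1.3 + 0.1), r).vffr <= base
            assert steady_vffr(pa, LesionCharacteristic(z1, z2), r * 1.3).vffr >= base

    def test_invalid_inputs_raise(self):
        with pytest.raises(ParameterError):
            steady_vffr(50.0, LesionCharacteristic(1, 1), 10.0, P_v=60.0)
        with pytest.raises(ParameterError):
            steady_vffr(100.0, LesionCharacteristic(1, 1), -5.0)


class TestPseudotransientStep:
    def test_single_rk4_step_matches_independent_oracle(self):
        les = LesionCharacteristic(5, 5)
        cmv = CMVParameters(R=25, C=0.01)
        pa = lambda t: 100.0

        # independent scalar RK4 coded from the RHS formula
        def rhs(pc):
            dp = 100.0 - pc
            q = np.sign(dp) * 2 * abs(dp) / (5 + np.sqrt(25 + 20 * abs(dp)))
            return (q - pc / 25.0) / 0.01

        dt = 1e-3
        pc0 = 60.0
        k1 = rhs(pc0)
        k2 = rhs(pc0 + dt / 2 * k1)
        k3 = rhs(pc0 + dt / 2 * k2)
        k4 = rhs(pc0 + dt * k3)
        expected = pc0 + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)

        new_pc, pd, q = pseudotransient_step(pc0, 0.0, pa, les, cmv, dt, period=1.0)
        assert new_pc == pytest.approx(expected, abs=1e-9)
        assert pd == pytest.approx(60.0)  # Z_c = 0: Pd equals the node pressure

    def test_equilibrium_state_stays_fixed(self):
        les = LesionCharacteristic(5, 5)
        cmv = CMVParameters(R=25, C=0.01)
        # steady fixed point: flow through lesion equals drainage through R
        pc_star = steady_vffr(100.0, les, 25.0).mean_pd
        pa = lambda t: 100.0
        pc = pc_star
        for i in range(10):
            pc, _, _ = pseudotransient_step(pc, i * 1e-3, pa, les, cmv, 1e-3, 1.0)
        assert pc == pytest.approx(pc_star, abs=1e-8)

    def test_heun_consistent_with_rk4(self):
        les = LesionCharacteristic(5, 5)
        cmv = CMVParameters(R=25, C=0.01)
        pa = lambda t: 100.0
        rk4, _, _ = pseudotransient_step(60.0, 0.0, pa, les, cmv, 1e-3, 1.0)
        heun, _, _ = pseudotransient_step(60.0, 0.0, pa, les, cmv, 1e-3, 1.0,
                                          integrator="heun")
        assert heun == pytest.approx(rk4, abs=1e-4)


class TestPseudotransientSimulation:
    def test_no_lesion_unity_and_afterload_identity(self, pulsatile_pa):
        cmv = CMVParameters(R=25, C=0.01)
        res = simulate_pseudotransient(
            pulsatile_pa, LesionCharacteristic(0, 0), cmv)
        assert res.vffr == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(res.pd_trace.values,
                           pulsatile_pa.interp(res.pd_trace.times))
        # Q = C dPa/dt + Pa/R (pim amplitude 0): check at interior nodes
        pa_vals = res.pd_trace.values
        dpa = np.gradient(pa_vals, res.pd_trace.dt)
        expected_q = 0.01 * dpa + pa_vals / 25.0
        assert np.allclose(res.q_trace[1:-1], expected_q[1:-1], atol=1e-9)

    def test_constant_pa_matches_steady_solution(self):
        les = LesionCharacteristic(5, 5)
        cmv = CMVParameters(R=25, C=0.01)
        res = simulate_pseudotransient(constant_pa(100.0), les, cmv)
        ref = steady_vffr(100.0, les, 25.0)
        assert res.converged
        assert abs(res.vffr - ref.vffr) < 1e-3

    def test_timestep_refinement(self, pulsatile_pa, moderate_lesion, typical_cmv):
        coarse = simulate_pseudotransient(
            pulsatile_pa, moderate_lesion, typical_cmv,
            SimulationConfig(dt=1e-3, max_cycles=30, convergence_tol=1e-5))
        fine = simulate_pseudotransient(
            pulsatile_pa, moderate_lesion, typical_cmv,
            SimulationConfig(dt=1e-4, max_cycles=30, convergence_tol=1e-5))
        assert coarse.converged and fine.converged
        assert abs(coarse.vffr - fine.vffr) < 1e-3

    def test_energy_dissipation(self, pulsatile_pa, moderate_lesion, typical_cmv):
        res = simulate_pseudotransient(pulsatile_pa, moderate_lesion, typical_cmv)
        pa_vals = pulsatile_pa.interp(res.pd_trace.times)
        power_in = np.trapezoid(pa_vals * res.q_trace, res.pd_trace.times)
        power_out = np.trapezoid(res.pd_trace.values * res.q_trace,
                                 res.pd_trace.times)
        assert power_in >= power_out

    def test_cycle_means_settle_monotonically(self, pulsatile_pa, moderate_lesion,
                                              typical_cmv):
        means = []
        for n in range(2, 7):
            res = simulate_pseudotransient(
                pulsatile_pa, moderate_lesion, typical_cmv,
                SimulationConfig(dt=1e-3, max_cycles=n, convergence_tol=0.0))
            means.append(res.mean_pd)
        deltas = np.abs(np.diff(means))
        assert np.all(np.diff(deltas) <= 1e-12)

    def test_nonconvergence_reported_not_raised(self, pulsatile_pa, moderate_lesion):
        sluggish = CMVParameters(R=60, C=5.0)  # huge compliance: slow settling
        res = simulate_pseudotransient(
            pulsatile_pa, moderate_lesion, sluggish,
            SimulationConfig(dt=1e-3, max_cycles=2, convergence_tol=1e-8))
        assert not res.converged
        assert res.cycles_run == 2

    def test_heun_integrator_agrees(self, pulsatile_pa, moderate_lesion, typical_cmv):
        rk4 = simulate_pseudotransient(pulsatile_pa, moderate_lesion, typical_cmv)
        heun = simulate_pseudotransient(
            pulsatile_pa, moderate_lesion, typical_cmv,
            SimulationConfig(dt=1e-3, integrator="heun"))
        assert abs(rk4.vffr - heun.vffr) < 1e-3

    def test_vffr_is_ratio_of_means(self, pulsatile_pa, moderate_lesion, typical_cmv):
        res = simulate_pseudotransient(pulsatile_pa, moderate_lesion, typical_cmv)
        assert res.vffr == pytest.approx(res.mean_pd / res.mean_pa, abs=1e-12)
        assert 0 < res.vffr <= 1.0001
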