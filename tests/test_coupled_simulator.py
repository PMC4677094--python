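"""Junction surrogate, Euler integration, periodic regime, derived quantities."""

import numpy as np
import pytest

from mockloop.coupled_simulator import (
    NetworkState,
    NotConvergedError,
    SimulationResult,
    SolverInstabilityError,
    SolverSettings,
    junction_solve,
    power_dissipation,
    run_to_periodic,
    stability_dt_bound,
    steady_state_pressure,
    step_euler,
    wss_poiseuille,
)
from mockloop.lpn_model import MMHG_TO_PA
from mockloop.synthetic_waveform import FlowWaveform, generate_pump_waveform, PumpSettings

Q_CONST = 9.133e-5


def _state(p_branch, p_common, t=0.0):
    return NetworkState(p_branch=np.asarray(p_branch, float), p_common=p_common, t=t)


class TestJunction:
    def test_symmetric_split(self, network):
        state = _state([9000.0] * 4, 8000.0)
        p_a, q = junction_solve(network, state, Q_CONST)
        # equal node pressures and equal internal resistances: p_a = P + q·R/4
        assert p_a == pytest.approx(9000.0 + Q_CONST * 1e6 / 4)
        np.testing.assert_allclose(q, Q_CONST / 4)

    def test_zero_inflow_equal_pressures(self, network):
        p_a, q = junction_solve(network, _state([9000.0] * 4, 8000.0), 0.0)
        assert p_a == pytest.approx(9000.0)
        np.testing.assert_allclose(q, 0.0, atol=1e-18)

    def test_matches_dense_linear_system(self, network):
        """Oracle: direct solve of the 5-equation system in (p_a, q_1..q_4)."""
        p = np.array([9100.0, 8900.0, 9350.0, 8700.0])
        state = _state(p, 8000.0)
        r = np.asarray(network.r_internal)
        A = np.zeros((5, 5))
        b = np.zeros(5)
        for j in range(4):  # q_j·r_j − p_a = −p_j
            A[j, 0] = -1.0
            A[j, 1 + j] = r[j]
            b[j] = -p[j]
        A[4, 1:] = 1.0  # Σ q_j = q_in
        b[4] = Q_CONST
        expected = np.linalg.solve(A, b)
        p_a, q = junction_solve(network, state, Q_CONST)
        assert p_a == pytest.approx(expected[0], rel=1e-10)
        np.testing.assert_allclose(q, expected[1:], rtol=1e-10)

    def test_flows_always_sum_to_inflow(self, network):
        rng = np.random.default_rng(0)
        for _ in range(20):
            state = _state(rng.uniform(5e3, 1.5e4, 4), rng.uniform(1e3, 9e3))
            q_in = rng.uniform(0, 3e-4)
            _, q = junction_solve(network, state, q_in)
            assert q.sum() == pytest.approx(q_in, rel=1e-12, abs=1e-16)


class TestEulerStep:
    def test_equilibrium_is_fixed_point(self, network):
        p0 = network.p_atrium
        state = _state([p0] * 4, p0)
        new = step_euler(network, state, 0.0, 1e-4)
        np.testing.assert_allclose(new.p_branch, state.p_branch, atol=1e-9)
        assert new.p_common == pytest.approx(p0, abs=1e-9)

    def test_update_scales_linearly_with_dt(self, network):
        state = _state([11000.0, 10900.0, 11100.0, 10800.0], 8300.0)
        d1 = step_euler(network, state, Q_CONST, 1e-6).p_branch - state.p_branch
        d2 = step_euler(network, state, Q_CONST, 2e-6).p_branch - state.p_branch
        # roundoff floor: the increment is ~1e-2 Pa on a ~1e4 Pa state
        np.testing.assert_allclose(d2, 2 * d1, rtol=1e-8, atol=1e-10)

    def test_signals_instability(self, network):
        state = _state([9.999e5] * 4, 9.999e5)
        with pytest.raises(SolverInstabilityError):
            step_euler(network, state, 1.0, 1.0)


class TestSteadyState:
    def test_oracle_reproduces_operating_point(self, network):
        """Bisection solution of the algebraic network at the TGA mean flow."""
        p_a, q = steady_state_pressure(network, Q_CONST)
        assert p_a == pytest.approx(1.12e4, rel=0.01)  # ≈ 84 mmHg
        split = 100 * q / Q_CONST
        np.testing.assert_allclose(split, [16.2, 10.6, 18.2, 55.0], atol=0.15)
        # common drop across taps+tubes ≈ 2.8 kPa
        drop = p_a - (network.p_atrium + network.terminal.r_t * Q_CONST)
        assert drop == pytest.approx(2.78e3, rel=0.05)

    def test_time_march_matches_oracle(self, network, steady_result):
        p_a, q = steady_state_pressure(network, Q_CONST)
        dp = abs(steady_result.p_aorta.mean() - p_a) / MMHG_TO_PA
        assert dp < 0.1
        q_march = steady_result.q_junction.mean(axis=1)
        np.testing.assert_allclose(q_march, q, rtol=5e-3)

    def test_pressure_ordering_at_steady_forward_flow(self, network, steady_result):
        i = -1  # any instant once periodic
        p_a = steady_result.p_aorta[i]
        p_b = steady_result.p_branch[:, i]
        p_c = steady_result.p_common[i]
        assert np.all(p_a > p_b)
        assert np.all(p_b > p_c)
        assert p_c > network.p_atrium

    def test_zero_inflow_relaxes_to_atrium(self, network):
        n = 4000
        w = FlowWaveform(times=np.arange(n) * 1e-4, flows=np.zeros(n), period=0.4)
        res = run_to_periodic(network, w, SolverSettings(periodicity_tol=1.0))
        assert res.converged
        assert abs(res.p_common[-1] - network.p_atrium) < 2.0
        np.testing.assert_allclose(res.p_branch[:, -1], network.p_atrium, atol=2.0)
        assert np.max(np.abs(res.q_out[:, -1])) < 1e-8


class TestPeriodicRun:
    def test_grid_mismatch_rejected(self, network):
        w = generate_pump_waveform(PumpSettings(cardiac_output=Q_CONST), 100)
        with pytest.raises(ValueError, match="solver dt"):
            run_to_periodic(network, w, SolverSettings(dt=1e-4))

    def test_dt_guard_without_substepping(self, network, steady_waveform):
        bound = stability_dt_bound(network, Q_CONST)
        assert 1e-4 < 0.8 * bound  # the standard step is admissible
        with pytest.raises(ValueError, match="stability bound"):
            run_to_periodic(
                network,
                FlowWaveform(times=np.arange(800) * 1e-3,
                             flows=np.full(800, Q_CONST), period=0.8),
                SolverSettings(dt=1e-3, auto_substep=False),
            )

    def test_outlet_mean_matches_inlet_mean(self, tga_tight_result):
        """At a well-relaxed periodic regime the compliances store no net
        volume, so mean total outflow equals mean inflow to 0.1%."""
        q_out_mean = tga_tight_result.q_out.mean(axis=1).sum()
        assert q_out_mean == pytest.approx(tga_tight_result.q_in.mean(), rel=1e-3)

    def test_monotone_loading(self, network, tga_result):
        """10% more cardiac output strictly raises cycle-mean junction pressure."""
        pump = PumpSettings(cardiac_output=1.1 * tga_result.q_in.mean())
        res = run_to_periodic(network, generate_pump_waveform(pump, 8000))
        assert res.p_aorta.mean() > tga_result.p_aorta.mean()

    def test_initial_condition_does_not_matter(self, network, tga_waveform, tga_result):
        other = run_to_periodic(
            network,
            tga_waveform,
            SolverSettings(initial_pressure=40.0 * MMHG_TO_PA),
        )
        assert other.converged
        assert abs(other.p_aorta.mean() - tga_result.p_aorta.mean()) < 0.3 * MMHG_TO_PA

    def test_nonconvergence_is_reported_not_raised(self, network, tga_waveform):
        res = run_to_periodic(
            network, tga_waveform, SolverSettings(max_cycles=2, periodicity_tol=1e-6)
        )
        assert not res.converged
        assert res.cycles_run == 2
        assert res.final_delta > 1e-6


class TestWSS:
    def test_hand_value(self):
        assert wss_poiseuille(9.133e-5, 0.006, 1e-3) == pytest.approx(0.538, rel=1e-2)

    def test_zero_linearity_and_sign(self):
        assert wss_poiseuille(0.0, 0.01, 1e-3) == 0.0
        assert wss_poiseuille(2e-5, 0.006, 1e-3) == pytest.approx(
            2 * wss_poiseuille(1e-5, 0.006, 1e-3)
        )
        assert wss_poiseuille(-1e-5, 0.006, 1e-3) < 0


class TestPowerDissipation:
    def test_energy_bookkeeping_oracle(self, network, tga_result):
        """Boundary flux equals the per-element ΔP·Q sum plus boundary kinetic
        fluxes once compliance storage vanishes at periodicity."""
        r = tga_result
        diss_rint = np.mean(((r.p_aorta - r.p_branch) * r.q_junction).sum(axis=0))
        diss_series = np.mean(((r.p_branch - r.p_common) * r.q_out).sum(axis=0))
        q_t = (r.p_common - network.p_atrium) / network.terminal.r_t
        diss_rt = np.mean((r.p_common - network.p_atrium) * q_t)
        area_in = np.pi * (network.inlet_diameter / 2) ** 2
        frac = r.q_junction.mean(axis=1) / r.q_in.mean()
        ke_in = np.mean(0.5 * 1000.0 * (r.q_in / area_in) ** 2 * r.q_in)
        v_out = r.q_out / (area_in * frac)[:, None]
        ke_out = np.mean((0.5 * 1000.0 * v_out**2 * r.q_out).sum(axis=0))
        oracle = diss_rint + diss_series + diss_rt + ke_in - ke_out
        value = power_dissipation(tga_result)
        assert value == pytest.approx(oracle, rel=0.01)
        assert value > 0

    def test_steady_flow_closed_form(self, network, steady_result):
        """At constant flow the kinetic fluxes nearly cancel and the index is
        the resistive drop times the flow."""
        r = steady_result
        q = r.q_in.mean()
        expected = (r.p_aorta.mean() - network.p_atrium) * q
        assert power_dissipation(r) == pytest.approx(expected, rel=0.02)

    def test_refuses_nonconverged(self, network, tga_waveform):
        res = run_to_periodic(
            network, tga_waveform, SolverSettings(max_cycles=2, periodicity_tol=1e-6)
        )
        with pytest.raises(NotConvergedError):
            power_dissipation(res)
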