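"""Solver oracles: analytic and closed-form checks of the 1D-0D scheme."""

import math

import numpy as np
import pytest

from renalpulse import (BloodProperties, InletWaveform, NumericsConfig,
                        VesselEndState, generate_inlet_waveform,
                        run_simulation, solve_junction, tube_law_beta,
                        wave_speed, windkessel_step)
from renalpulse.network import WindkesselOutlet
from renalpulse.units import lmin_to_m3s

from conftest import (constant_inflow, make_bifurcation_network,
                      make_single_vessel_network)


class TestRestState:
    def test_zero_inflow_is_exact_fixed_point(self, baseline_net):
        res = run_simulation(baseline_net, InletWaveform(0.857, np.zeros(32), 0.0),
                             numerics=NumericsConfig(max_cycles=2))
        assert max(np.abs(p).max() for p in res.pressure.values()) == 0.0
        assert max(np.abs(q).max() for q in res.flow.values()) == 0.0


class TestPoiseuille:
    def test_steady_mean_pressure_is_series_resistance(self):
        # Q0 through tube + R-C-R bed: P_in = Q0 (R_bed + R_visc) with
        # R_visc = 8 mu L / (pi r^4), the gamma_v = 2 friction limit
        q0, R, L, r = 5e-6, 1.6e9, 0.3, 4e-3
        mu = 4.0e-3
        net = make_single_vessel_network(length=L, radius=r, R_total=R,
                                         C=1e-10, probes=(0.0,))
        res = run_simulation(net, constant_inflow(q0),
                             BloodProperties(viscosity=mu))
        assert res.converged
        r_visc = 8 * mu * L / (math.pi * r ** 4)
        expected = q0 * (R + r_visc)
        p_in = res.pressure["p0"].mean()
        assert p_in == pytest.approx(expected, rel=0.02)


class TestPulsePropagation:
    def test_transit_speed_and_damping(self):
        # small pulse in a long uniform vessel: foot speed matches the
        # closed-form wave speed within 2%, peak decay < 5% per 10 diameters
        r, L = 5e-3, 2.0
        net = make_single_vessel_network(
            length=L, radius=r, h=1.5e-3, E=4.0e5, R_total=1.6e9, C=1e-10,
            probes=(0.2, 0.3, 0.35))
        rho = 1060.0
        A0 = math.pi * r * r
        beta = tube_law_beta(4.0e5, 1.5e-3, 0.5, A0)
        c0 = wave_speed(A0, A0, beta, rho)

        T = 1.0
        t = np.arange(4096) / 4096 * T
        q = 1e-6 * np.exp(-0.5 * ((t - 0.05) / 0.01) ** 2)
        inlet = InletWaveform(T, q, float(q.mean()))
        res = run_simulation(net, inlet,
                             BloodProperties(viscosity=1e-6),
                             NumericsConfig(max_cycles=1,
                                            samples_per_cycle=2000))

        def foot_time(p):
            p = p - p[0]  # remove the uniform start-up offset
            thresh = 0.05 * p.max()
            i = int(np.argmax(p > thresh))
            # linear interpolation of the threshold crossing
            f = (thresh - p[i - 1]) / (p[i] - p[i - 1])
            return (i - 1 + f) * (T / len(p))

        t1 = foot_time(res.pressure["p0"])
        t2 = foot_time(res.pressure["p1"])
        c_measured = (0.3 - 0.2) * L / (t2 - t1)
        assert c_measured == pytest.approx(float(c0), rel=0.02)
        # amplitude over 10 diameters (0.1 m, probes p1 -> p2)
        a1 = res.pressure["p1"].max()
        a2 = res.pressure["p2"].max()
        assert a2 / a1 > 0.95


class TestJunctions:
    def _end(self, r, A_over_A0=1.05, u=0.3, parent=True, E=4e5, h=1e-3):
        A0 = math.pi * r * r
        return VesselEndState(tube_law_beta(E, h, 0.5, A0), A0,
                              A_over_A0 * A0, u, parent)

    def test_series_junction_is_transparent(self):
        ends = [self._end(4e-3, 1.04, 0.25, True),
                self._end(4e-3, 1.04, 0.25, False)]
        states, residuals = solve_junction(ends)
        assert states[0]["area"] == pytest.approx(states[1]["area"], rel=1e-8)
        assert states[0]["velocity"] == pytest.approx(states[1]["velocity"],
                                                      rel=1e-8)
        assert max(residuals.values()) < 1e-10

    def test_pentafurcation_splits_equally(self):
        parent = self._end(2.71e-3, 1.03, 0.4, True)
        children = [self._end(1.585e-3, 1.0, 0.0, False) for _ in range(5)]
        states, residuals = solve_junction([parent] + children)
        qp = states[0]["flow"]
        for s in states[1:]:
            assert s["flow"] == pytest.approx(qp / 5, rel=1e-8)
        assert max(residuals.values()) < 1e-10

    def test_asymmetric_bifurcation_residuals(self):
        ends = [self._end(5e-3, 1.06, 0.5, True),
                self._end(3.5e-3, 1.01, 0.1, False),
                self._end(2.0e-3, 0.99, -0.05, False, E=6e5, h=0.6e-3)]
        _, residuals = solve_junction(ends)
        assert residuals["mass"] < 1e-10
        assert residuals["total_pressure"] < 1e-10
        assert residuals["characteristic"] < 1e-10

    def test_symmetric_bifurcation_in_simulation(self):
        net = make_bifurcation_network()
        res = run_simulation(net, constant_inflow(1e-5, period=0.8))
        q1, q2 = res.flow["c1_mid"], res.flow["c2_mid"]
        scale = np.abs(q1).max()
        assert np.max(np.abs(q1 - q2)) / scale < 1e-6
        assert res.diagnostics["junction_residual_max"] < 1e-10

    def test_junction_residuals_on_baseline(self, baseline_sim):
        assert baseline_sim.diagnostics["junction_residual_max"] < 1e-10


class TestWindkessel:
    def test_ohmic_steady_state(self):
        # Q = 5 ml/s through R1 + R2 = 1.6e9 -> 8 kPa interface pressure
        out = WindkesselOutlet("x", 1.6e9, 1.0e-9,
                               proximal_resistance_fraction=0.2)
        pc, q = 0.0, 5e-6
        for _ in range(20000):
            step = windkessel_step(out, q, 1e-3, stored_pressure=pc)
            pc = step["stored_pressure"]
        assert step["interface_pressure"] == pytest.approx(8e3, rel=1e-4)

    def test_rc_decay(self):
        # flow cut to zero: Pc decays exp(-t / R2 C) within 1% over 2 tau
        out = WindkesselOutlet("x", 1.0e9, 1.0e-9,
                               proximal_resistance_fraction=0.1)
        r2 = 0.9e9
        tau = r2 * out.compliance
        pc0 = 1.0e4
        dt = tau / 2000
        pc = pc0
        n = int(round(2 * tau / dt))
        for _ in range(n):
            pc = windkessel_step(out, 0.0, dt, stored_pressure=pc)["stored_pressure"]
        assert pc == pytest.approx(pc0 * math.exp(-2.0), rel=0.01)

    def test_large_compliance_clamps_interface_pressure(self):
        out = WindkesselOutlet("x", 1.6e9, 1.0e-3,
                               proximal_resistance_fraction=0.25,
                               outflow_pressure=500.0)
        r1 = 0.25 * 1.6e9
        step = windkessel_step(out, 5e-6, 1e-3, stored_pressure=500.0)
        assert step["interface_pressure"] == pytest.approx(500.0 + r1 * 5e-6,
                                                           rel=1e-6)

    def test_characteristic_coupling_consistent_with_prescribed(self):
        # at rest the characteristic solve returns zero flow
        A0 = math.pi * (3e-3) ** 2
        end = VesselEndState(tube_law_beta(4e5, 0.6e-3, 0.5, A0), A0, A0, 0.0)
        out = WindkesselOutlet("x", 2e9, 1e-10)
        step = windkessel_step(out, end, 1e-4)
        assert step["flow"] == pytest.approx(0.0, abs=1e-15)


class TestConservationAndConvergence:
    def test_global_mass_balance(self, baseline_sim):
        d = baseline_sim.diagnostics
        err = abs(d["cycle_volume_in"] - d["cycle_volume_out"]
                  - d["cycle_volume_stored_change"]) / d["cycle_volume_in"]
        assert err < 0.005

    def test_grid_convergence_on_baseline(self, baseline_net, baseline_sim):
        inlet = generate_inlet_waveform(lmin_to_m3s(5.74), 70.0)
        fine = run_simulation(baseline_net, inlet,
                              numerics=NumericsConfig(target_cell_size=3.75e-3))
        sbp = baseline_sim.pressure["brachial"].max()
        sbp_fine = fine.pressure["brachial"].max()
        assert abs(sbp - sbp_fine) / sbp_fine < 0.01

    def test_determinism(self, baseline_net):
        inlet = generate_inlet_waveform(lmin_to_m3s(5.74), 70.0)
        r1 = run_simulation(baseline_net, inlet)
        r2 = run_simulation(baseline_net, inlet)
        for k in r1.pressure:
            assert np.array_equal(r1.pressure[k], r2.pressure[k])
            assert np.array_equal(r1.flow[k], r2.flow[k])

    def test_velocity_is_flow_over_area(self, baseline_sim):
        v = baseline_sim.velocity["renal_seg_l1"]
        q = baseline_sim.flow["renal_seg_l1"]
        a = baseline_sim.area["renal_seg_l1"]
        assert np.array_equal(v, q / a)

    def test_convergence_flag_and_cycles(self, baseline_sim):
        assert baseline_sim.converged
        assert 2 <= baseline_sim.cycles_to_convergence <= 50
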