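"""Time integrator: closed-form transients, impedance oracle, valve logic,
conservation laws."""

import numpy as np
import pytest

from shuntloop.circuit import ComponentSpec, Netlist, WindkesselParams, make_windkessel
from shuntloop.errors import SolverError, ValidationError
from shuntloop.simulate import (
    TransientSolver,
    assemble_residual,
    initial_state,
    run_to_periodic,
    step,
    update_valve_states,
)


def windkessel_impedance(omega, rp, rd, c):
    """Analytic input impedance Z(w) = Rp + Rd/(1 + i w Rd C)."""
    return rp + rd / (1.0 + 1j * omega * rd * c)


def _run_steps(netlist, n_steps, dt, drivers=None, **init_kwargs):
    solver = TransientSolver(netlist, dt, drivers)
    state = initial_state(netlist, **init_kwargs)
    for _ in range(n_steps):
        state = solver.step(state)
    return state


class TestClosedFormTransients:
    def test_rc_discharge(self):
        netlist = Netlist(
            [
                ComponentSpec("capacitor", "C", "n", "ground", {"compliance": 1.0}),
                ComponentSpec("resistor", "R", "n", "ground", {"resistance": 1.0}),
            ]
        )
        state = _run_steps(netlist, 1000, 1e-3, pressure=1.0)
        assert state.pressures["n"] == pytest.approx(np.exp(-1.0), abs=1e-3)

    def test_lr_step_response(self):
        netlist = Netlist(
            [
                ComponentSpec("pressure_source", "src", "a", "ground", {"pressure": 1.0}),
                ComponentSpec("inductor", "L", "a", "b", {"inertance": 1.0}),
                ComponentSpec("resistor", "R", "b", "ground", {"resistance": 1.0}),
            ]
        )
        state = _run_steps(netlist, 1000, 1e-3, pressure=0.0)
        assert state.flows["L"] == pytest.approx(1.0 - np.exp(-1.0), abs=1e-3)

    def test_windkessel_constant_flow_steady_state(self):
        # P3D -> Pd + (Rp+Rd) Q within 0.1% after 10 RdC time constants
        params = WindkesselParams(rp=0.5, rd=2.5, c=0.75, pd=5.0)
        comps = make_windkessel("WK", params, closed_loop=False)
        comps.append(ComponentSpec("flow_source", "inflow", "ground", "WK_in", {"flow": 2.0}))
        dt = 1e-3
        n = int(round(10 * params.rd * params.c / dt))
        state = _run_steps(Netlist(comps), n, dt, pressure=0.0)
        assert state.pressures["WK_in"] == pytest.approx(11.0, rel=1e-3)

    def test_unit_windkessel_steady_state(self):
        comps = make_windkessel("WK", WindkesselParams(rp=1, rd=1, c=1, pd=0.0),
                                closed_loop=False)
        comps.append(ComponentSpec("flow_source", "inflow", "ground", "WK_in", {"flow": 1.0}))
        state = _run_steps(Netlist(comps), 10000, 1e-3, pressure=0.0)
        assert state.pressures["WK_in"] == pytest.approx(2.0, rel=1e-3)

    def test_zero_dt_rejected(self):
        netlist = Netlist(
            [ComponentSpec("resistor", "R", "a", "ground", {"resistance": 1.0})]
        )
        with pytest.raises(ValidationError):
            step(netlist, initial_state(netlist), dt=0.0)


class TestResidualContract:
    def test_single_resistor_flow_balances_nodes(self):
        netlist = Netlist(
            [
                ComponentSpec("flow_source", "src", "ground", "a", {"flow": 3.0}),
                ComponentSpec("resistor", "R", "a", "b", {"resistance": 2.0}),
                ComponentSpec("pressure_source", "pin", "b", "ground", {"pressure": 4.0}),
            ]
        )
        state = initial_state(netlist, pressure={"a": 10.0, "b": 4.0})
        state.flows["pin"] = 3.0  # the pinned node sinks the through-flow
        res, labels = assemble_residual(netlist, state, state, dt=1e-3)
        kcl = {lab: r for lab, r in zip(labels, res)}
        assert abs(kcl["kcl:a"]) < 1e-12  # (10-4)/2 = 3 ml/s balances the source
        assert abs(kcl["kcl:b"]) < 1e-12

    def test_capacitor_stored_flow_term(self):
        netlist = Netlist(
            [
                ComponentSpec("flow_source", "src", "ground", "a", {"flow": 3.0}),
                ComponentSpec("capacitor", "C", "a", "ground", {"compliance": 2.0}),
            ]
        )
        dt = 1e-3
        prev = initial_state(netlist, pressure=10.0)
        new = initial_state(netlist, pressure=10.0 + 1.5 * dt)  # dP/dt = 1.5
        new.time = dt
        res, labels = assemble_residual(netlist, new, prev, dt=dt)
        kcl = {lab: r for lab, r in zip(labels, res)}
        assert abs(kcl["kcl:a"]) < 1e-9  # C dP/dt = 3 ml/s cancels the source

    def test_windkessel_ode_residual_at_steady_state(self):
        # substitute the steady closed form into the Windkessel relation:
        # dP/dt C Rd + P - Pd - Q (Rp + Rd) - dQ/dt Rp Rd C = 0
        rp, rd, c, pd, q = 0.5, 2.5, 0.75, 5.0, 2.0
        p = pd + (rp + rd) * q
        residual = 0.0 * c * rd + p - pd - q * (rd + rp) - 0.0 * rp * rd * c
        assert abs(residual) < 1e-9
        # and the simulated subcircuit satisfies the discrete equations there
        comps = make_windkessel("WK", WindkesselParams(rp=rp, rd=rd, c=c, pd=pd),
                                closed_loop=False)
        comps.append(ComponentSpec("flow_source", "inflow", "ground", "WK_in", {"flow": q}))
        netlist = Netlist(comps)
        state = _run_steps(netlist, 40000, 1e-3, pressure=0.0)
        res, _ = assemble_residual(netlist, state, state, dt=1e-3)
        assert np.abs(res).max() < 1e-6


class TestValveSwitching:
    @staticmethod
    def _valve_rig(p_up, p_down):
        netlist = Netlist(
            [
                ComponentSpec("pressure_source", "up", "a", "ground", {"pressure": p_up}),
                ComponentSpec("diode_valve", "D", "a", "b",
                              {"resistance": 1e-2, "inertance": 1e-4}),
                ComponentSpec("pressure_source", "down", "b", "ground", {"pressure": p_down}),
            ]
        )
        return netlist

    def test_closed_valve_opens_under_forward_gradient(self):
        netlist = self._valve_rig(20.0, 5.0)
        state = step(netlist, initial_state(netlist, pressure=0.0), dt=1e-4)
        assert state.valve_open["D"]
        assert state.flows["D"] > 0

    def test_open_valve_closes_on_reverse_flow(self):
        netlist = self._valve_rig(5.0, 20.0)
        init = initial_state(netlist, pressure=0.0, valves_open=True)
        state = step(netlist, init, dt=1e-4)
        assert not state.valve_open["D"]
        assert state.flows["D"] == pytest.approx(0.0, abs=1e-9)

    def test_equal_pressures_keep_closed_valve_closed(self):
        netlist = self._valve_rig(10.0, 10.0)
        state = step(netlist, initial_state(netlist, pressure=10.0), dt=1e-4)
        assert not state.valve_open["D"]

    def test_update_valve_states_rules(self):
        netlist = self._valve_rig(20.0, 5.0)
        state = initial_state(netlist, pressure={"a": 20.0, "b": 5.0})
        assert update_valve_states(netlist, state).valve_open["D"]
        open_state = initial_state(netlist, pressure={"a": 5.0, "b": 20.0}, valves_open=True)
        open_state.flows["D"] = -0.3
        updated = update_valve_states(netlist, open_state)
        assert not updated.valve_open["D"]
        assert updated.flows["D"] == 0.0


class TestPeriodicConvergence:
    def test_windkessel_harmonics_match_analytic_impedance(self):
        """Pulsatile flow into a Windkessel: every driven harmonic of the
        converged pressure matches Z(w) Q(w) within 0.5%."""
        rp, rd, c = 3.277e-2, 0.1361, 1.76235
        period, dt = 0.46, 5e-5
        harmonics = (1, 2, 3, 4, 5, 6)
        rng = np.random.default_rng(7)
        amps = 2.0 + rng.random(len(harmonics))
        phases = rng.random(len(harmonics)) * 2 * np.pi

        def q_of_t(t):
            w0 = 2 * np.pi / period
            return 30.0 + sum(
                a * np.cos(k * w0 * t + ph) for k, a, ph in zip(harmonics, amps, phases)
            )

        comps = make_windkessel("WK", WindkesselParams(rp=rp, rd=rd, c=c, pd=0.0),
                                closed_loop=False)
        comps.append(ComponentSpec("flow_source", "inflow", "ground", "WK_in", {"flow": 0.0}))
        result = run_to_periodic(
            Netlist(comps), dt=dt, max_cycles=12, tol=1e-6, period=period,
            drivers={"inflow": q_of_t},
        )
        assert result.converged
        p = result.node_pressure("WK_in")[1:]
        q = q_of_t(result.time[1:])
        p_hat, q_hat = np.fft.rfft(p), np.fft.rfft(q)
        w0 = 2 * np.pi / period
        # mean: P = (Rp+Rd) Q
        assert p_hat[0].real / q_hat[0].real == pytest.approx(rp + rd, rel=5e-3)
        for k in harmonics:
            z_sim = p_hat[k] / q_hat[k]
            z_true = windkessel_impedance(k * w0, rp, rd, c)
            assert abs(z_sim - z_true) / abs(z_true) < 5e-3

    def test_impedance_frequency_limits(self):
        """|Z| -> Rp+Rd at low frequency and -> Rp at high frequency,
        each within 1% on a simulated two-tone sweep."""
        rp, rd, c = 1.0, 1.0, 0.011
        period, dt = 0.46, 5e-5
        w0 = 2 * np.pi / period
        k_lo, k_hi = 1, 150

        def q_of_t(t):
            return 10.0 + np.cos(k_lo * w0 * t) + np.cos(k_hi * w0 * t)

        comps = make_windkessel("WK", WindkesselParams(rp=rp, rd=rd, c=c, pd=0.0),
                                closed_loop=False)
        comps.append(ComponentSpec("flow_source", "inflow", "ground", "WK_in", {"flow": 0.0}))
        result = run_to_periodic(
            Netlist(comps), dt=dt, max_cycles=8, tol=1e-6, period=period,
            drivers={"inflow": q_of_t},
        )
        p_hat = np.fft.rfft(result.node_pressure("WK_in")[1:])
        q_hat = np.fft.rfft(q_of_t(result.time[1:]))
        assert abs(p_hat[k_lo] / q_hat[k_lo]) == pytest.approx(rp + rd, rel=1e-2)
        assert abs(p_hat[k_hi] / q_hat[k_hi]) == pytest.approx(rp, rel=1e-2)

    def test_infinite_tolerance_returns_after_one_cycle(self):
        comps = make_windkessel("WK", WindkesselParams(rp=1, rd=1, c=1, pd=0.0),
                                closed_loop=False)
        comps.append(ComponentSpec("flow_source", "inflow", "ground", "WK_in", {"flow": 1.0}))
        result = run_to_periodic(Netlist(comps), dt=1e-3, max_cycles=10,
                                 tol=float("inf"), period=0.46)
        assert result.n_cycles == 1 and result.converged


class TestClosedLoopInvariants:
    def test_kirchhoff_residual(self, baseline_result):
        assert baseline_result.kcl_residual_max() < 1e-6

    def test_volume_conservation(self, baseline_result):
        v = baseline_result.total_stored_volume()
        drift = abs(v[-1] - v[1]) / v[1]
        assert drift < 1e-3  # < 0.1% per cycle (machine-level in practice)

    def test_diode_flow_nonnegative(self, baseline_result):
        for valve in ("NAV", "RAV"):
            assert baseline_result.branch_flow(valve).min() >= -1e-9

    def test_converged_and_periodic(self, baseline_result):
        assert baseline_result.converged
        assert baseline_result.periodicity_residuals[-1] < 1e-3

    def test_step_halving_changes_cycle_means_below_half_percent(self):
        from shuntloop.config import RunConfig, build_model, initial_model_state

        means = {}
        for dt in (2e-4, 1e-4):
            cfg = RunConfig(model="figure1_baseline", dt=dt, max_cycles=12, tol=1e-9)
            netlist, drivers = build_model(cfg.model, heart_cfg=cfg.heart, period=cfg.period)
            result = run_to_periodic(
                netlist, dt=dt, max_cycles=12, tol=1e-9, period=cfg.period,
                drivers=drivers, init=initial_model_state(netlist, cfg),
                raise_on_divergence=True,
            )
            means[dt] = dict(zip(result.node_names, result.cycle_means[-1]))
        for node in means[2e-4]:
            a, b = means[2e-4][node], means[1e-4][node]
            assert abs(a - b) / max(abs(b), 1e-2) < 5e-3

    def test_divergence_guard_raises_with_diagnostics(self):
        # an unphysiological inflow drives the Windkessel past the bound
        comps = make_windkessel("WK", WindkesselParams(rp=1, rd=1, c=1, pd=0.0),
                                closed_loop=False)
        comps.append(ComponentSpec("flow_source", "inflow", "ground", "WK_in",
                                   {"flow": 1e4}))
        with pytest.raises(SolverError, match="diverged"):
            run_to_periodic(Netlist(comps), dt=1e-3, max_cycles=5, tol=1e-3,
                            period=0.46, pressure_bound=500.0)
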