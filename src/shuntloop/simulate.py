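"""Implicit time integration of the circuit's differential-algebraic system.

Unknowns are the non-reference node pressures, the flows through inertial
and source branches (inductors, diode valves, pressure sources), and the
chamber volumes. Discretization is first-order implicit (backward Euler);
with frozen valve states every element law is linear, so each step is a
single direct linear solve — the Newton iteration of the nonlinear system
collapses to one step per valve configuration. Diode valves switch by
step rejection and re-solve: a closed valve opens when its upstream minus
downstream pressure becomes positive, an open valve closes when its flow
becomes non-positive, ties keep the current state, and each valve may
switch at most once per step (chattering guard).

Units: pressure mmHg, flow ml/s, volume ml, time s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .circuit import Netlist, validate_netlist
from .errors import SolverError, ValidationError

Driver = Callable[[float], float]

DEFAULT_DT = 1e-4
DEFAULT_PERIOD = 0.46  # s; typical infant cycle length, a package assumption
DEFAULT_INITIAL_PRESSURE = 10.0  # mmHg, erased by periodic convergence
PRESSURE_BOUND = 1000.0  # mmHg, divergence guard


@dataclass
class SimState:
    """Instantaneous circuit state."""

    time: float
    pressures: dict[str, float]
    flows: dict[str, float]
    volumes: dict[str, float]
    valve_open: dict[str, bool]


class _Assembly:
    """Index maps and constant matrix stamps for one netlist at one dt.

    The step equation is ``A(t, valves) x_new = C x_prev + s(t)`` where A
    carries the backward-Euler element laws and Kirchhoff current balance
    (one equation per unknown), C the history terms, and s the
    time-dependent source/elastance terms.
    """

    def __init__(self, netlist: Netlist, dt: float, drivers: Mapping[str, Driver | float]):
        if not dt > 0:
            raise ValidationError(f"dt={dt} must be > 0")
        validate_netlist(netlist)
        self.netlist = netlist
        self.dt = dt
        self.drivers = dict(drivers or {})

        nodes = sorted(netlist.nodes - {netlist.ground})
        self.node_index = {n: i for i, n in enumerate(nodes)}
        self.nodes = nodes
        self.flow_comps = [
            c for c in netlist.components
            if c.kind in ("inductor", "diode_valve", "pressure_source")
        ]
        self.valves = [c for c in netlist.components if c.kind == "diode_valve"]
        self.chambers = [c for c in netlist.components if c.kind == "elastance_chamber"]
        nn = len(nodes)
        self.flow_index = {c.name: nn + j for j, c in enumerate(self.flow_comps)}
        self.volume_index = {
            c.name: nn + len(self.flow_comps) + k for k, c in enumerate(self.chambers)
        }
        self.n = nn + len(self.flow_comps) + len(self.chambers)

        for c in self.chambers:
            if c.name not in self.drivers:
                raise SolverError(f"elastance chamber {c.name!r} has no E(t) driver")
        self._driven_sources = [
            c
            for c in netlist.components
            if c.kind in ("pressure_source", "flow_source") and c.name in self.drivers
        ]

        self._build_stamps()

    def _col(self, node: str) -> int | None:
        return self.node_index.get(node)

    def _build_stamps(self):
        n, dt = self.n, self.dt
        A = np.zeros((n, n))
        C = np.zeros((n, n))
        s = np.zeros(n)
        gnd = self.netlist.ground

        def kcl(node, col, coeff, into_A=True):
            row = self._col(node)
            if row is not None:
                (A if into_A else C)[row, col] += coeff

        for comp in self.netlist.components:
            f, t = self._col(comp.node_from), self._col(comp.node_to)
            if comp.kind == "resistor":
                g = 1.0 / comp.p("resistance")
                for row, sign in ((f, +1.0), (t, -1.0)):
                    if row is None:
                        continue
                    if f is not None:
                        A[row, f] += sign * g
                    if t is not None:
                        A[row, t] -= sign * g
            elif comp.kind == "capacitor":
                cdt = comp.p("compliance") / dt
                for row, sign in ((f, +1.0), (t, -1.0)):
                    if row is None:
                        continue
                    if f is not None:
                        A[row, f] += sign * cdt
                        C[row, f] += sign * cdt
                    if t is not None:
                        A[row, t] -= sign * cdt
                        C[row, t] -= sign * cdt
            elif comp.kind in ("inductor", "diode_valve", "pressure_source"):
                col = self.flow_index[comp.name]
                if f is not None:
                    A[f, col] += 1.0
                if t is not None:
                    A[t, col] -= 1.0
                row = col  # one element equation per flow unknown
                if comp.kind == "inductor":
                    ldt = comp.p("inertance") / dt
                    if f is not None:
                        A[row, f] += 1.0
                    if t is not None:
                        A[row, t] -= 1.0
                    A[row, col] -= ldt
                    C[row, col] -= ldt
                elif comp.kind == "pressure_source":
                    if f is not None:
                        A[row, f] += 1.0
                    if t is not None:
                        A[row, t] -= 1.0
                    # s[row] set per step (driver) or statically below
                    if comp.name not in self.drivers:
                        s[row] = comp.p("pressure")
                # diode rows are written per step according to valve state
            elif comp.kind == "elastance_chamber":
                vcol = self.volume_index[comp.name]
                if f is not None:
                    A[f, vcol] += 1.0 / dt
                    C[f, vcol] += 1.0 / dt
                if t is not None:
                    A[t, vcol] -= 1.0 / dt
                    C[t, vcol] -= 1.0 / dt
                # pressure row: P_f - P_t - E(t)(V - V0) = 0; E entry per step
                row = vcol
                if f is not None:
                    A[row, f] += 1.0
                if t is not None:
                    A[row, t] -= 1.0
            elif comp.kind == "flow_source":
                if comp.name not in self.drivers:
                    q = comp.p("flow")
                    if f is not None:
                        s[f] -= q
                    if t is not None:
                        s[t] += q
            else:  # pragma: no cover
                raise SolverError(f"unhandled kind {comp.kind}")

        # precomputed per-valve open-row stamps
        self._valve_rows = {}
        for comp in self.valves:
            f, t = self._col(comp.node_from), self._col(comp.node_to)
            col = self.flow_index[comp.name]
            ldt = comp.p("inertance") / dt
            self._valve_rows[comp.name] = (f, t, col, comp.p("resistance"), ldt)
            C[col, col] -= ldt  # open-form history term; zeroed in rhs when closed

        self._A_base = A
        self._C = C
        self._s_base = s
        del gnd

        # singularity check at a reference configuration (all valves open)
        probe = A.copy()
        for name in self._valve_rows:
            self._write_valve_row(probe, name, True)
        for comp in self.chambers:
            row = self.volume_index[comp.name]
            probe[row, row] -= 1.0  # placeholder elastance
        if np.linalg.matrix_rank(probe) < self.n:
            bad = self._diagnose_singular(probe)
            raise SolverError(f"singular circuit equations{bad}")

    def _diagnose_singular(self, mat) -> str:
        # name a pressure node with no resistive/capacitive path to reference
        _, _, vh = np.linalg.svd(mat)
        null = np.abs(vh[-1])
        worst = int(np.argmax(null[: len(self.nodes)])) if len(self.nodes) else 0
        if null[worst] > 1e-8:
            return f" (check node {self.nodes[worst]!r}: no path to reference?)"
        return ""

    def _write_valve_row(self, A, name, is_open):
        f, t, col, r, ldt = self._valve_rows[name]
        A[col, :] = 0.0
        if is_open:
            if f is not None:
                A[col, f] = 1.0
            if t is not None:
                A[col, t] = -1.0
            A[col, col] = -(r + ldt)
        else:
            A[col, col] = 1.0

    def _eval_driver(self, name, t):
        d = self.drivers[name]
        return d(t) if callable(d) else float(d)

    def matrices(self, t_new: float, valve_open: Mapping[str, bool]):
        """A and s at time t_new under the given valve configuration."""
        A = self._A_base.copy()
        s = self._s_base.copy()
        for name in self._valve_rows:
            self._write_valve_row(A, name, valve_open[name])
        for comp in self.chambers:
            row = self.volume_index[comp.name]
            e = self._eval_driver(comp.name, t_new)
            if not e > 0:
                raise SolverError(f"elastance driver {comp.name!r} returned E={e} <= 0")
            A[row, row] = -e
            s[row] = -e * comp.parameters.get("v0", 0.0)
        for comp in self._driven_sources:
            if comp.kind == "pressure_source":
                s[self.flow_index[comp.name]] = self._eval_driver(comp.name, t_new)
            else:  # flow_source
                q = self._eval_driver(comp.name, t_new)
                f, t = self._col(comp.node_from), self._col(comp.node_to)
                if f is not None:
                    s[f] -= q
                if t is not None:
                    s[t] += q
        return A, s

    def rhs(self, x_prev: np.ndarray, s: np.ndarray, valve_open: Mapping[str, bool]):
        b = self._C @ x_prev + s
        for name, (f, t, col, r, ldt) in self._valve_rows.items():
            if not valve_open[name]:
                b[col] = 0.0
        return b

    # -- state packing ----------------------------------------------------
    def pack(self, state: SimState) -> np.ndarray:
        x = np.zeros(self.n)
        for node, i in self.node_index.items():
            x[i] = state.pressures.get(node, 0.0)
        for name, j in self.flow_index.items():
            x[j] = state.flows.get(name, 0.0)
        for name, k in self.volume_index.items():
            x[k] = state.volumes.get(name, 0.0)
        return x

    def unpack(self, t, x, valve_open) -> SimState:
        return SimState(
            time=t,
            pressures={n: float(x[i]) for n, i in self.node_index.items()},
            flows={n: float(x[j]) for n, j in self.flow_index.items()},
            volumes={n: float(x[k]) for n, k in self.volume_index.items()},
            valve_open=dict(valve_open),
        )


def initial_state(
    netlist: Netlist,
    pressure: float | Mapping[str, float] = DEFAULT_INITIAL_PRESSURE,
    volumes: Mapping[str, float] | None = None,
    valves_open: bool = False,
) -> SimState:
    """Uniform-pressure initial condition with valves closed (defaults);
    chamber volumes must be supplied for elastance chambers."""
    nodes = netlist.nodes - {netlist.ground}
    if isinstance(pressure, Mapping):
        pressures = {n: float(pressure.get(n, DEFAULT_INITIAL_PRESSURE)) for n in nodes}
    else:
        pressures = {n: float(pressure) for n in nodes}
    chambers = [c for c in netlist.components if c.kind == "elastance_chamber"]
    vols = {c.name: float((volumes or {}).get(c.name, 0.0)) for c in chambers}
    for c in chambers:
        if vols[c.name] < 0:
            raise ValidationError(f"chamber {c.name} volume {vols[c.name]} must be >= 0")
    flows = {
        c.name: 0.0
        for c in netlist.components
        if c.kind in ("inductor", "diode_valve", "pressure_source")
    }
    valve_state = {c.name: valves_open for c in netlist.components if c.kind == "diode_valve"}
    return SimState(0.0, pressures, flows, vols, valve_state)


@dataclass
class SimulationResult:
    """Uniformly sampled final-cycle trajectory plus convergence diagnostics."""

    netlist: Netlist
    dt: float
    period: float
    time: np.ndarray  # final-cycle sample times
    node_names: list[str]
    pressures: np.ndarray  # (steps, nodes)
    flow_names: list[str]
    flows: np.ndarray  # (steps, flow unknowns)
    volume_names: list[str]
    volumes: np.ndarray  # (steps, chambers)
    converged: bool
    n_cycles: int
    periodicity_residuals: list[float]
    cycle_means: "np.ndarray"  # (cycles, nodes)
    chatter_events: int = 0
    final_state: SimState | None = None
    metadata: dict = field(default_factory=dict)

    def node_pressure(self, node: str) -> np.ndarray:
        return self.pressures[:, self.node_names.index(node)]

    def chamber_volume(self, name: str) -> np.ndarray:
        return self.volumes[:, self.volume_names.index(name)]

    def branch_flow(self, name: str) -> np.ndarray:
        """Flow through any branch (positive node_from -> node_to)."""
        if name in self.flow_names:
            return self.flows[:, self.flow_names.index(name)]
        comp = self.netlist.component(name)

        def node_p(node):
            if node == self.netlist.ground:
                return np.zeros(len(self.time))
            return self.node_pressure(node)

        dp = node_p(comp.node_from) - node_p(comp.node_to)
        if comp.kind == "resistor":
            return dp / comp.p("resistance")
        if comp.kind == "capacitor":
            ddp = np.empty_like(dp)
            ddp[1:] = np.diff(dp) / self.dt
            ddp[0] = ddp[1] if len(dp) > 1 else 0.0
            return comp.p("compliance") * ddp
        raise KeyError(f"no flow record for component {name!r}")

    def total_stored_volume(self) -> np.ndarray:
        """Chamber volumes plus capacitive stored volume, per sample."""
        total = self.volumes.sum(axis=1) if self.volumes.size else np.zeros(len(self.time))
        for comp in self.netlist.components:
            if comp.kind != "capacitor":
                continue
            pf = (
                self.node_pressure(comp.node_from)
                if comp.node_from != self.netlist.ground
                else 0.0
            )
            pt = (
                self.node_pressure(comp.node_to)
                if comp.node_to != self.netlist.ground
                else 0.0
            )
            total = total + comp.p("compliance") * (pf - pt)
        return total

    def kcl_residual_max(self) -> float:
        """Largest node flow-balance residual |sum of flows| over the final
        cycle, recomputed from the stored trajectory (ml/s)."""
        steps = len(self.time)
        residual = {n: np.zeros(steps) for n in self.node_names}

        def add(node, q):
            if node in residual:
                residual[node] += q

        for comp in self.netlist.components:
            if comp.kind in ("inductor", "diode_valve", "pressure_source"):
                q = self.branch_flow(comp.name)
            elif comp.kind in ("resistor", "capacitor"):
                q = self.branch_flow(comp.name)
            elif comp.kind == "elastance_chamber":
                v = self.chamber_volume(comp.name)
                q = np.empty(len(v))
                q[1:] = np.diff(v) / self.dt
                q[0] = q[1] if len(v) > 1 else 0.0
            elif comp.kind == "flow_source":
                q = np.full(steps, comp.parameters.get("flow", 0.0))
            add(comp.node_from, q)
            add(comp.node_to, -q)
        # first sample joins the previous cycle's discretization; exclude it
        return max(np.abs(v[1:]).max() if steps > 1 else 0.0 for v in residual.values())


class TransientSolver:
    """Backward-Euler stepper with diode-valve event handling."""

    def __init__(
        self,
        netlist: Netlist,
        dt: float = DEFAULT_DT,
        drivers: Mapping[str, Driver | float] | None = None,
    ):
        self.assembly = _Assembly(netlist, dt, drivers or {})
        self.dt = dt
        self.netlist = netlist
        self.chatter_events = 0

    def step_x(self, t: float, x_prev: np.ndarray, valve_open: dict[str, bool]):
        """Advance one step from time t; returns (x_new, valve_open_new)."""
        asm = self.assembly
        t_new = t + self.dt
        switched: set[str] = set()
        for _ in range(len(asm.valves) + 1):
            A, s = asm.matrices(t_new, valve_open)
            b = asm.rhs(x_prev, s, valve_open)
            try:
                x = np.linalg.solve(A, b)
            except np.linalg.LinAlgError as exc:
                raise SolverError(f"singular step system at t={t_new:.6g}: {exc}") from exc
            changes = []
            for comp in asm.valves:
                name = comp.name
                if name in switched:
                    continue
                f, tt, col, _, _ = asm._valve_rows[name]
                pf = x[f] if f is not None else 0.0
                pt = x[tt] if tt is not None else 0.0
                if valve_open[name]:
                    if x[col] <= 0.0:
                        changes.append((name, False))
                else:
                    if pf - pt > 0.0:  # strict: equal pressures keep it closed
                        changes.append((name, True))
            if not changes:
                return x, valve_open
            for name, new_state in changes:
                valve_open = {**valve_open, name: new_state}
                switched.add(name)
        self.chatter_events += 1
        return x, valve_open

    def step(self, state: SimState) -> SimState:
        x = self.assembly.pack(state)
        x_new, valves = self.step_x(state.time, x, dict(state.valve_open))
        new = self.assembly.unpack(state.time + self.dt, x_new, valves)
        for name, v in new.volumes.items():
            if v < 0:
                raise SolverError(f"chamber {name} volume went negative ({v:.3g} ml)")
        return new


def assemble_residual(
    netlist: Netlist,
    state_new: SimState,
    state_prev: SimState,
    dt: float,
    drivers: Mapping[str, Driver | float] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Backward-Euler residual F = A x_new - (C x_prev + s) of the step
    equations, with one labelled entry per unknown. Zero iff ``state_new``
    satisfies every node flow balance and element law."""
    asm = _Assembly(netlist, dt, drivers or {})
    A, s = asm.matrices(state_new.time, state_new.valve_open)
    b = asm.rhs(asm.pack(state_prev), s, state_new.valve_open)
    res = A @ asm.pack(state_new) - b
    labels = (
        [f"kcl:{n}" for n in asm.nodes]
        + [f"law:{c.name}" for c in asm.flow_comps]
        + [f"chamber:{c.name}" for c in asm.chambers]
    )
    return res, labels


def step(
    netlist: Netlist,
    state: SimState,
    dt: float,
    drivers: Mapping[str, Driver | float] | None = None,
) -> SimState:
    """Single implicit step (convenience wrapper; builds the assembly each
    call — use :class:`TransientSolver` for long integrations)."""
    return TransientSolver(netlist, dt, drivers).step(state)


def update_valve_states(
    netlist: Netlist,
    state: SimState,
    drivers: Mapping[str, Driver | float] | None = None,
) -> SimState:
    """Apply the switching rules to a solved state without advancing time:
    closed valves open on positive upstream-minus-downstream pressure, open
    valves close on non-positive flow; ties keep the current state."""
    new_valves = dict(state.valve_open)
    for comp in netlist.components:
        if comp.kind != "diode_valve":
            continue
        pf = state.pressures.get(comp.node_from, 0.0)
        pt = state.pressures.get(comp.node_to, 0.0)
        q = state.flows.get(comp.name, 0.0)
        if state.valve_open[comp.name]:
            if q <= 0.0:
                new_valves[comp.name] = False
        elif pf - pt > 0.0:
            new_valves[comp.name] = True
    flows = dict(state.flows)
    for name, is_open in new_valves.items():
        if not is_open:
            flows[name] = 0.0
    return SimState(state.time, dict(state.pressures), flows, dict(state.volumes), new_valves)


def run_to_periodic(
    netlist: Netlist,
    dt: float = DEFAULT_DT,
    max_cycles: int = 50,
    tol: float = 1e-3,
    *,
    period: float = DEFAULT_PERIOD,
    drivers: Mapping[str, Driver | float] | None = None,
    init: SimState | None = None,
    pressure_bound: float = PRESSURE_BOUND,
    raise_on_divergence: bool = True,
) -> SimulationResult:
    """Integrate cycle by cycle until the largest relative change of any
    cycle-mean node pressure between consecutive cycles falls below
    ``tol`` (with ``tol=inf`` the first cycle is returned). Divergent
    pressures abort with diagnostics."""
    if not dt > 0:
        raise ValidationError(f"dt={dt} must be > 0")
    if not period > 0:
        raise ValidationError(f"period={period} must be > 0")
    steps = int(round(period / dt))
    if abs(steps * dt - period) > 1e-9 * max(1.0, period):
        raise ValidationError(f"period {period} is not an integer multiple of dt {dt}")

    solver = TransientSolver(netlist, dt, drivers)
    asm = solver.assembly
    state = init or initial_state(netlist)
    x = asm.pack(state)
    valves = dict(state.valve_open)
    t = state.time

    nn = len(asm.nodes)
    traj_x = np.zeros((steps + 1, asm.n))
    times = np.zeros(steps + 1)
    means_history: list[np.ndarray] = []
    residuals: list[float] = []
    converged = False
    cycles_run = 0

    for cycle in range(max_cycles):
        traj_x[0] = x
        times[0] = t
        acc = np.zeros(nn)
        for i in range(steps):
            x, valves = solver.step_x(t, x, valves)
            t += dt
            traj_x[i + 1] = x
            times[i + 1] = t
            acc += x[:nn]
        cycles_run += 1
        pmax = np.abs(x[:nn]).max()
        if not np.isfinite(pmax) or pmax > pressure_bound:
            msg = (
                f"pressures diverged (max |P| = {pmax:.3g} mmHg > {pressure_bound}) "
                f"in cycle {cycles_run}"
            )
            if raise_on_divergence:
                raise SolverError(msg)
            break
        means = acc / steps
        means_history.append(means)
        if math.isinf(tol):
            residuals.append(0.0)
            converged = True
            break
        if cycle > 0:
            prev = means_history[-2]
            denom = np.maximum(np.abs(prev), 1e-2)
            change = float((np.abs(means - prev) / denom).max())
            residuals.append(change)
            if change < tol:
                converged = True
                break
        else:
            residuals.append(float("nan"))

    final = asm.unpack(t, x, valves)
    nflow = len(asm.flow_comps)
    return SimulationResult(
        netlist=netlist,
        dt=dt,
        period=period,
        time=times.copy(),
        node_names=list(asm.nodes),
        pressures=traj_x[:, :nn].copy(),
        flow_names=[c.name for c in asm.flow_comps],
        flows=traj_x[:, nn : nn + nflow].copy(),
        volume_names=[c.name for c in asm.chambers],
        volumes=traj_x[:, nn + nflow :].copy(),
        converged=converged,
        n_cycles=cycles_run,
        periodicity_residuals=residuals,
        cycle_means=np.array(means_history) if means_history else np.zeros((0, nn)),
        chatter_events=solver.chatter_events,
        final_state=final,
        metadata={"steps_per_cycle": steps, "tol": tol, "max_cycles": max_cycles},
    )
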