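"""Closed-loop lumped-parameter circulation circuits.

A circulation is described as a netlist: an ordered list of two-terminal
components (resistors, capacitors, inductors, diode valves, time-varying
elastance chambers, flow/pressure sources) over named pressure nodes, with
a single zero-pressure reference node for all capacitive elements.

Units: pressure mmHg, flow ml/s, volume ml, time s, resistance mmHg*s/ml,
compliance ml/mmHg, inertance mmHg*s^2/ml.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import networkx as nx

from .errors import ConfigurationError, ValidationError

GROUND = "ground"

COMPONENT_KINDS = frozenset(
    {
        "resistor",
        "capacitor",
        "inductor",
        "diode_valve",
        "elastance_chamber",
        "flow_source",
        "pressure_source",
    }
)

# parameter keys that must be strictly positive, per kind
_POSITIVE_KEYS = {
    "resistor": ("resistance",),
    "capacitor": ("compliance",),
    "inductor": ("inertance",),
    "diode_valve": ("resistance", "inertance"),
    "elastance_chamber": (),
    "flow_source": (),
    "pressure_source": (),
}

_REQUIRED_KEYS = {
    "resistor": ("resistance",),
    "capacitor": ("compliance",),
    "inductor": ("inertance",),
    "diode_valve": ("resistance", "inertance"),
    "elastance_chamber": (),
    "flow_source": (),
    "pressure_source": (),
}


@dataclass(frozen=True)
class ComponentSpec:
    """One two-terminal circuit element.

    ``parameters`` holds named scalars (see module units). Elastance
    chambers optionally carry ``v0`` (unstressed volume, ml); their E(t)
    waveform is supplied to the simulator as a driver, not a scalar.
    Positive flow is defined from ``node_from`` to ``node_to``.
    """

    kind: str
    name: str
    node_from: str
    node_to: str
    parameters: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in COMPONENT_KINDS:
            raise ValidationError(f"unknown component kind {self.kind!r}")
        if not self.name:
            raise ValidationError("component name must be nonempty")
        if not self.node_from or not self.node_to:
            raise ValidationError(f"{self.name}: node identifiers must be nonempty")
        if self.node_from == self.node_to:
            raise ValidationError(f"{self.name}: node_from and node_to must differ")
        for key in _REQUIRED_KEYS[self.kind]:
            if key not in self.parameters:
                raise ValidationError(f"{self.name}: {self.kind} requires parameter {key!r}")
        for key in _POSITIVE_KEYS[self.kind]:
            if not self.parameters[key] > 0:
                raise ValidationError(
                    f"{self.name}: parameter {key}={self.parameters[key]} must be > 0"
                )

    def p(self, key: str) -> float:
        return float(self.parameters[key])


@dataclass(frozen=True)
class WindkesselParams:
    """Three-element Windkessel: proximal resistance Rp in series with a
    parallel distal-resistance Rd / compliance C pair, draining toward a
    distal pressure Pd.

    In stand-alone use Pd is a fixed reference pressure; in a closed loop
    the distal node is wired into the venous circuit and Pd is ignored.
    """

    rp: float
    rd: float
    c: float
    pd: float | None = None

    def __post_init__(self):
        for label, value in (("Rp", self.rp), ("Rd", self.rd), ("C", self.c)):
            if not value > 0:
                raise ValidationError(f"Windkessel {label}={value} must be > 0")


#: outlets whose Windkessel parameters attach directly to the arterial domain
WINDKESSEL_OUTLETS = ("RC", "LC", "RS", "LS", "DAo", "RPA", "LPA")
#: venous loop-closing sections
VENOUS_SECTIONS = ("SVC", "IVC", "RPV", "LPV")
#: scalar heart/shunt parameters
HEART_SHUNT_KEYS = (
    "RA_valve_resistance",
    "RA_valve_inertance",
    "NAV_resistance",
    "NAV_inertance",
    "collateral_1_resistance",
    "collateral_2_resistance",
    "ASD_resistance",
)


@dataclass(frozen=True)
class ParameterTables:
    """The full scalar parameterization of the closed loop: one Windkessel
    per arterial outlet, one Windkessel-like section per venous segment,
    and the heart-valve / collateral / septal-defect scalars."""

    windkessel_outlets: Mapping[str, WindkesselParams]
    venous_sections: Mapping[str, WindkesselParams]
    heart_and_shunts: Mapping[str, float]

    def __post_init__(self):
        missing = [k for k in WINDKESSEL_OUTLETS if k not in self.windkessel_outlets]
        missing += [k for k in VENOUS_SECTIONS if k not in self.venous_sections]
        missing += [k for k in HEART_SHUNT_KEYS if k not in self.heart_and_shunts]
        if missing:
            raise ConfigurationError(f"parameter tables incomplete; missing {missing}")


@dataclass(frozen=True)
class HeartSpec:
    """Heart-side structure of the closed loop.

    The atria are constant-compliance chambers (the source publication for
    the parameter tables gives no atrial constants; these defaults are
    package assumptions, see docs/methods.md). The ventricular E(t) is a
    simulator driver keyed on the chamber name.
    """

    ventricle_name: str = "ventricle"
    v0: float = 0.0
    atrial_compliance_right: float = 2.0
    atrial_compliance_left: float = 2.0


@dataclass
class Netlist:
    """An ordered component list plus the global zero-pressure reference."""

    components: list[ComponentSpec]
    ground: str = GROUND

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for c in self.components:
            out.add(c.node_from)
            out.add(c.node_to)
        return out

    def component(self, name: str) -> ComponentSpec:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def replace_component(self, name: str, **param_updates: float) -> "Netlist":
        """Return a copy with one component's parameters updated."""
        comps = []
        found = False
        for c in self.components:
            if c.name == name:
                comps.append(replace(c, parameters={**c.parameters, **param_updates}))
                found = True
            else:
                comps.append(c)
        if not found:
            raise KeyError(name)
        return Netlist(comps, ground=self.ground)


@dataclass(frozen=True)
class NetlistDiagnostics:
    n_components: int
    n_nodes: int
    connected: bool
    has_reference: bool
    closed_loop: bool
    issues: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_netlist(netlist: Netlist, raise_on_error: bool = True) -> NetlistDiagnostics:
    """Structural checks: connectivity, reference presence, name uniqueness.

    ``closed_loop`` reports whether the circuit contains no flow or
    pressure sources (a self-contained circulation whose only exchange
    with the reference is capacitive storage).
    """
    issues: list[str] = []
    names = [c.name for c in netlist.components]
    for name in sorted({n for n in names if names.count(n) > 1}):
        issues.append(f"duplicate component name {name!r}")

    graph = nx.Graph()
    graph.add_nodes_from(netlist.nodes)
    for c in netlist.components:
        graph.add_edge(c.node_from, c.node_to)
    connected = graph.number_of_nodes() > 0 and nx.is_connected(graph)
    if not connected and graph.number_of_nodes() > 0:
        for part in nx.connected_components(graph):
            if netlist.ground not in part:
                issues.append(f"disconnected node(s): {sorted(part)}")

    has_reference = netlist.ground in netlist.nodes
    if not has_reference:
        issues.append(f"reference node {netlist.ground!r} does not appear in the circuit")

    closed_loop = not any(c.kind in ("flow_source", "pressure_source") for c in netlist.components)

    diag = NetlistDiagnostics(
        n_components=len(netlist.components),
        n_nodes=len(netlist.nodes),
        connected=connected,
        has_reference=has_reference,
        closed_loop=closed_loop,
        issues=tuple(issues),
    )
    if raise_on_error and issues:
        raise ValidationError("; ".join(issues))
    return diag


def make_windkessel(
    name: str,
    params: WindkesselParams,
    closed_loop: bool = True,
    node_in: str | None = None,
    node_out: str | None = None,
    ground: str = GROUND,
) -> list[ComponentSpec]:
    """Build the three-element Windkessel subcircuit for one outlet.

    Topology: entry --Rp--> mid --Rd--> distal, with C from mid to the
    reference. With ``closed_loop=False`` a pressure source pins the
    distal node at Pd (stand-alone boundary-condition use); with
    ``closed_loop=True`` the distal node is left open for connection to
    the downstream venous circuit.
    """
    node_in = node_in or f"{name}_in"
    node_mid = f"{name}_mid"
    node_out = node_out or f"{name}_out"
    comps = [
        ComponentSpec("resistor", f"{name}_Rp", node_in, node_mid, {"resistance": params.rp}),
        ComponentSpec("capacitor", f"{name}_C", node_mid, ground, {"compliance": params.c}),
        ComponentSpec("resistor", f"{name}_Rd", node_mid, node_out, {"resistance": params.rd}),
    ]
    if not closed_loop:
        pd = params.pd if params.pd is not None else 0.0
        comps.append(
            ComponentSpec("pressure_source", f"{name}_Pd", node_out, ground, {"pressure": pd})
        )
    return comps


# drain node of each arterial outlet's Windkessel inside the closed loop
_OUTLET_DRAIN = {
    "RC": "SVC_in",
    "LC": "SVC_in",
    "RS": "SVC_in",
    "LS": "SVC_in",
    "DAo": "IVC_in",
    "RPA": "RPV_in",
    "LPA": "LPV_in",
}
_VENOUS_DRAIN = {"SVC": "RA", "IVC": "RA", "RPV": "LA", "LPV": "LA"}

#: default aortopulmonary collateral attachment (venous-side endpoints of the
#: named beds; see docs/methods.md for the rationale)
DEFAULT_COLLATERAL_ENDPOINTS = {
    "collateral_1": ("IVC_in", "RPV_in"),  # descending-aorta drain -> right pulmonary venous
    "collateral_2": ("SVC_in", "RPA_in"),  # arch-branch drain -> right pulmonary arterial
}


def build_patient_circuit(
    tables: ParameterTables,
    surrogate,
    heart: HeartSpec | None = None,
    collateral_endpoints: Mapping[str, tuple[str, str]] | None = None,
) -> Netlist:
    """Assemble the full closed-loop single-ventricle circulation.

    Path: elastance ventricle -> neo-aortic valve -> aortic root ->
    reduced-order arterial network (five systemic branches, shunt, two
    pulmonary branches; see :mod:`shuntloop.surrogate`) -> outlet
    Windkessels -> venous sections -> atria -> atrioventricular valve ->
    ventricle, with an atrial septal defect joining the atria and two
    aortopulmonary collateral resistors.
    """
    from .surrogate import build_surrogate_network  # local import: avoid cycle

    heart = heart or HeartSpec()
    hs = tables.heart_and_shunts
    endpoints = dict(DEFAULT_COLLATERAL_ENDPOINTS)
    if collateral_endpoints:
        endpoints.update(collateral_endpoints)

    comps: list[ComponentSpec] = []
    # heart
    comps.append(
        ComponentSpec(
            "elastance_chamber",
            heart.ventricle_name,
            "V",
            GROUND,
            {"v0": heart.v0},
        )
    )
    comps.append(
        ComponentSpec(
            "diode_valve",
            "NAV",
            "V",
            "AoR",
            {"resistance": hs["NAV_resistance"], "inertance": hs["NAV_inertance"]},
        )
    )
    comps.append(
        ComponentSpec(
            "diode_valve",
            "RAV",
            "RA",
            "V",
            {"resistance": hs["RA_valve_resistance"], "inertance": hs["RA_valve_inertance"]},
        )
    )
    comps.append(
        ComponentSpec(
            "capacitor", "RA_C", "RA", GROUND, {"compliance": heart.atrial_compliance_right}
        )
    )
    comps.append(
        ComponentSpec(
            "capacitor", "LA_C", "LA", GROUND, {"compliance": heart.atrial_compliance_left}
        )
    )
    comps.append(ComponentSpec("resistor", "ASD", "LA", "RA", {"resistance": hs["ASD_resistance"]}))

    # reduced-order arterial domain (aortic root to outlet entries)
    comps.extend(build_surrogate_network(surrogate))

    # arterial outlet Windkessels
    for name in WINDKESSEL_OUTLETS:
        comps.extend(
            make_windkessel(
                name,
                tables.windkessel_outlets[name],
                closed_loop=True,
                node_out=_OUTLET_DRAIN[name],
            )
        )
    # venous loop-closing sections
    for name in VENOUS_SECTIONS:
        comps.extend(
            make_windkessel(
                name,
                tables.venous_sections[name],
                closed_loop=True,
                node_out=_VENOUS_DRAIN[name],
            )
        )

    # aortopulmonary collaterals
    for cname, key in (
        ("collateral_1", "collateral_1_resistance"),
        ("collateral_2", "collateral_2_resistance"),
    ):
        nf, nt = endpoints[cname]
        comps.append(ComponentSpec("resistor", cname, nf, nt, {"resistance": hs[key]}))

    netlist = Netlist(comps)
    validate_netlist(netlist)
    return netlist


def iter_parameter_values(tables: ParameterTables) -> Iterable[tuple[str, float]]:
    """Flat (label, value) view of every table entry, for audit logging."""
    for name, wk in tables.windkessel_outlets.items():
        yield from ((f"{name}.Rp", wk.rp), (f"{name}.Rd", wk.rd), (f"{name}.C", wk.c))
    for name, wk in tables.venous_sections.items():
        yield from ((f"{name}.Rp", wk.rp), (f"{name}.Rd", wk.rd), (f"{name}.C", wk.c))
    for key, value in tables.heart_and_shunts.items():
        yield key, float(value)
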