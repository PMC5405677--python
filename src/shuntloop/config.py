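"""Run configuration and builtin closed-loop models.

Builtin model names select the empirical shunt resistance:
``figure1_baseline`` 3.5 mmHg*s/ml (the occluded shunt that reproduces
the patient data), ``figure1_flared`` 3.3 (the long-wide flared design),
``figure1_implant_time`` 2.1 (the as-implanted tube).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from typing import Mapping

from .circuit import (
    HeartSpec,
    Netlist,
    ParameterTables,
    WindkesselParams,
    build_patient_circuit,
)
from .elastance import periodic_gaussian
from .errors import ConfigurationError
from .simulate import SimState, SimulationResult, initial_state, run_to_periodic
from .surrogate import ShuntSpec, SurrogateSpec, shunt_resistance

BUILTIN_SHUNT_RESISTANCE = {
    "figure1_baseline": 3.5,
    "figure1_flared": 3.3,
    "figure1_implant_time": 2.1,
}


def default_tables() -> ParameterTables:
    """The packaged closed-loop parameterization, loaded bit-exactly."""
    raw = json.loads(
        resources.files("shuntloop.data").joinpath("figure1_params.json").read_text()
    )
    return tables_from_dict(raw)


def tables_from_dict(raw: Mapping) -> ParameterTables:
    def wk(entry):
        return WindkesselParams(
            rp=entry["Rp"], rd=entry["Rd"], c=entry["C"], pd=entry.get("Pd")
        )

    try:
        return ParameterTables(
            windkessel_outlets={k: wk(v) for k, v in raw["windkessel_outlets"].items()},
            venous_sections={k: wk(v) for k, v in raw["venous_sections"].items()},
            heart_and_shunts=dict(raw["heart_and_shunts"]),
        )
    except KeyError as exc:
        raise ConfigurationError(f"parameter config missing key {exc}") from exc


@dataclass(frozen=True)
class HeartModelConfig:
    """Ventricular elastance (Gaussian-over-floor form) and initial volume.

    The cycle period and these elastance constants are package
    assumptions chosen to give infant-scale hemodynamics (no printed
    patient values exist for them); see docs/methods.md.
    """

    e_min: float = 0.2
    e_max: float = 3.0
    peak_time: float = 0.15
    sigma: float = 0.05
    v0: float = 0.0
    edv: float = 38.0


@dataclass
class RunConfig:
    """One simulation run: model selection plus solver settings."""

    model: str = "figure1_baseline"
    dt: float = 1e-4
    period: float = 0.46
    max_cycles: int = 50
    tol: float = 1e-3
    initial_pressure: float = 10.0
    seed: int = 0
    heart: HeartModelConfig = field(default_factory=HeartModelConfig)

    def __post_init__(self):
        if not self.dt > 0:
            raise ConfigurationError(f"dt={self.dt} must be > 0")
        if not self.tol > 0:
            raise ConfigurationError(f"tol={self.tol} must be > 0")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        heart = HeartModelConfig(**raw.pop("heart", {}))
        known = {"model", "dt", "period", "max_cycles", "tol", "initial_pressure", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config keys {sorted(unknown)}; valid keys: {sorted(known | {'heart'})}"
            )
        return cls(heart=heart, **raw)

    def to_dict(self) -> dict:
        return asdict(self)


def build_model(
    model: str = "figure1_baseline",
    tables: ParameterTables | None = None,
    heart_cfg: HeartModelConfig | None = None,
    period: float = 0.46,
    shunt_scale: float | None = None,
    shunt_reference_resistance: float | None = None,
    surrogate: SurrogateSpec | None = None,
) -> tuple[Netlist, dict]:
    """Assemble a builtin closed-loop model; returns (netlist, drivers).

    ``shunt_scale`` narrows the shunt by the d^-4 law relative to the
    model's reference resistance (``shunt_reference_resistance`` overrides
    the builtin value, e.g. 2.1 for occlusion studies starting from the
    as-implanted tube).
    """
    if model not in BUILTIN_SHUNT_RESISTANCE:
        raise ConfigurationError(
            f"unknown builtin model {model!r}; choose from {sorted(BUILTIN_SHUNT_RESISTANCE)}"
        )
    tables = tables or default_tables()
    heart_cfg = heart_cfg or HeartModelConfig()
    if surrogate is None:
        r_ref = (
            shunt_reference_resistance
            if shunt_reference_resistance is not None
            else BUILTIN_SHUNT_RESISTANCE[model]
        )
        shunt = ShuntSpec(mode="empirical", resistance=r_ref,
                          scale=shunt_scale if shunt_scale is not None else 1.0)
        surrogate = SurrogateSpec(shunt=shunt)
    netlist = build_patient_circuit(
        tables, surrogate, HeartSpec(v0=heart_cfg.v0)
    )
    elastance = lambda t: periodic_gaussian(  # noqa: E731
        t, heart_cfg.e_min, heart_cfg.e_max - heart_cfg.e_min,
        heart_cfg.peak_time, heart_cfg.sigma, period,
    )
    return netlist, {"ventricle": elastance}


def initial_model_state(netlist: Netlist, config: RunConfig) -> SimState:
    return initial_state(
        netlist,
        pressure=config.initial_pressure,
        volumes={"ventricle": config.heart.edv},
    )


def run_model(config: RunConfig, **build_kwargs) -> SimulationResult:
    """Build and integrate a builtin model to periodic steady state."""
    netlist, drivers = build_model(
        config.model, heart_cfg=config.heart, period=config.period, **build_kwargs
    )
    init = initial_model_state(netlist, config)
    return run_to_periodic(
        netlist,
        dt=config.dt,
        max_cycles=config.max_cycles,
        tol=config.tol,
        period=config.period,
        drivers=drivers,
        init=init,
    )


def shunt_gradient_and_flow(result: SimulationResult) -> tuple[float, float]:
    """Cycle-mean trans-shunt pressure gradient (mmHg) and shunt flow
    (ml/s) of a converged closed-loop result."""
    dp = (result.node_pressure("AoR") - result.node_pressure("PA_jct"))[1:]
    q = result.branch_flow("shunt")[1:]
    return float(dp.mean()), float(q.mean())


def make_occlusion_simulator(
    config: RunConfig | None = None,
    reference_resistance: float = 2.1,
    **build_kwargs,
):
    """Closure ``scale -> (gradient, flow)`` for occlusion inference,
    warm-starting each simulation from the previous converged state."""
    config = config or RunConfig(model="figure1_implant_time", dt=2e-4, max_cycles=60)
    state_cache: dict = {}

    def simulate(scale: float) -> tuple[float, float]:
        netlist, drivers = build_model(
            config.model,
            heart_cfg=config.heart,
            period=config.period,
            shunt_scale=scale,
            shunt_reference_resistance=reference_resistance,
            **build_kwargs,
        )
        init = state_cache.get("state") or initial_model_state(netlist, config)
        init = SimState(0.0, init.pressures, init.flows, init.volumes, init.valve_open)
        result = run_to_periodic(
            netlist, dt=config.dt, max_cycles=config.max_cycles, tol=config.tol,
            period=config.period, drivers=drivers, init=init,
        )
        state_cache["state"] = result.final_state
        return shunt_gradient_and_flow(result)

    return simulate


def scaled_shunt_resistance(scale: float, reference: float = 2.1) -> float:
    """Shunt branch resistance at a diameter scale, d^-4 law."""
    return shunt_resistance(ShuntSpec(mode="empirical", resistance=reference), scale=scale)
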