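"""Reduced-order surrogate for the image-based arterial domain.

The spatially resolved arterial segment (aortic root, arch branches,
descending aorta, BT shunt, pulmonary arteries) is replaced by a resistive
branch network. Branch resistances of the great vessels are negligible
against the outlet Windkessels; the shunt branch carries either an
empirical effective resistance (mean trans-shunt gradient / mean flow) or
a Hagen-Poiseuille resistance derived from its geometry.

The Poiseuille resistance of the bare 3.5 mm x 14 mm tube (~0.11
mmHg*s/ml) is far below the measured effective resistances (2.1-4.3
mmHg*s/ml): most of the real pressure loss arises from anastomosis,
entrance and inertial effects that a 0D tube law cannot capture. The
surrogate therefore defaults to the empirical values, with Poiseuille mode
available for diameter-scaling studies. This is the central fidelity
compromise of the desk-scale model (docs/methods.md).

Units: resistance mmHg*s/ml; geometry mm; viscosity Pa*s; density g/mm^3;
flow for the Reynolds number mm^3/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .circuit import ComponentSpec
from .errors import ConfigurationError, ValidationError

MMHG_PER_PA = 1.0 / 133.322

#: great-vessel branches fed directly from the aortic root
SYSTEMIC_BRANCHES = ("RC", "LC", "RS", "LS", "DAo")
#: pulmonary branches fed from the shunt / pulmonary-artery junction
PULMONARY_BRANCHES = ("LPA", "RPA")


@dataclass(frozen=True)
class FluidProperties:
    """Blood properties used for the Reynolds number and Poiseuille law."""

    viscosity_pa_s: float = 0.004
    density_g_mm3: float = 0.00106


@dataclass(frozen=True)
class ShuntSpec:
    """BT shunt branch description.

    mode='empirical': branch resistance = ``resistance`` (measured
    gradient/flow ratio), rescaled by the fourth power of the diameter
    scale relative to ``reference_scale``.
    mode='poiseuille': branch resistance = Hagen-Poiseuille resistance of
    the scaled tube plus ``anastomosis_loss``.
    """

    mode: str = "empirical"
    diameter_mm: float = 3.5
    length_mm: float = 14.0
    scale: float = 1.0
    resistance: float = 3.5
    reference_scale: float = 1.0
    anastomosis_loss: float = 0.0

    def __post_init__(self):
        if self.mode not in ("empirical", "poiseuille"):
            raise ConfigurationError(f"unknown shunt mode {self.mode!r}")
        if not (0 < self.scale <= 1):
            raise ValidationError(f"shunt diameter scale {self.scale} must lie in (0, 1]")
        for label, v in (
            ("diameter_mm", self.diameter_mm),
            ("length_mm", self.length_mm),
            ("resistance", self.resistance),
            ("reference_scale", self.reference_scale),
        ):
            if not v > 0:
                raise ValidationError(f"shunt {label}={v} must be > 0")

    @property
    def effective_diameter_mm(self) -> float:
        return self.diameter_mm * self.scale


@dataclass(frozen=True)
class SurrogateSpec:
    """Resistive stand-in for the 3D arterial domain."""

    branch_resistances: dict[str, float] = field(
        default_factory=lambda: {name: 1e-3 for name in SYSTEMIC_BRANCHES + PULMONARY_BRANCHES}
    )
    shunt: ShuntSpec = field(default_factory=ShuntSpec)
    fluid: FluidProperties = field(default_factory=FluidProperties)

    def __post_init__(self):
        for name, r in self.branch_resistances.items():
            if name not in SYSTEMIC_BRANCHES + PULMONARY_BRANCHES:
                raise ConfigurationError(f"unknown surrogate branch {name!r}")
            if r < 0:
                raise ValidationError(f"branch {name} resistance {r} must be >= 0")
        missing = [b for b in SYSTEMIC_BRANCHES + PULMONARY_BRANCHES
                   if b not in self.branch_resistances]
        if missing:
            raise ConfigurationError(f"surrogate spec missing branches {missing}")

    def with_shunt(self, **updates) -> "SurrogateSpec":
        return replace(self, shunt=replace(self.shunt, **updates))


def poiseuille_resistance(diameter_mm: float, length_mm: float, viscosity_pa_s: float) -> float:
    """Hagen-Poiseuille resistance R = 128*mu*L/(pi*d^4) of a straight tube,
    converted to mmHg*s/ml."""
    for label, v in (
        ("diameter", diameter_mm),
        ("length", length_mm),
        ("viscosity", viscosity_pa_s),
    ):
        if not v > 0:
            raise ValidationError(f"poiseuille_resistance: {label}={v} must be > 0")
    d = diameter_mm * 1e-3  # m
    length = length_mm * 1e-3  # m
    r_si = 128.0 * viscosity_pa_s * length / (math.pi * d**4)  # Pa*s/m^3
    return r_si * 1e-6 * MMHG_PER_PA  # -> mmHg*s/ml


def pressure_gradient(mean_aortic_mmhg: float, mean_pulmonary_mmhg: float) -> float:
    """Mean trans-shunt pressure gradient: aortic minus pulmonary."""
    return mean_aortic_mmhg - mean_pulmonary_mmhg


def effective_resistance(mean_gradient_mmhg: float, mean_flow_ml_s: float) -> float:
    """Equivalent lumped resistance of the shunt path, gradient over flow."""
    if not mean_flow_ml_s > 0:
        raise ValidationError(f"effective_resistance: flow {mean_flow_ml_s} must be > 0")
    return mean_gradient_mmhg / mean_flow_ml_s


def reynolds_number(
    peak_flow_mm3_s: float,
    diameter_mm: float,
    density_g_mm3: float = 0.00106,
    viscosity_pa_s: float = 0.004,
) -> float:
    """Reynolds number Re = rho*v*d/mu with v the cross-section mean
    velocity Q/(pi d^2/4).

    Inputs in mm-g-s units; g/(mm*s) is numerically equal to Pa*s, so the
    ratio is dimensionless without further conversion.
    """
    for label, v in (("diameter", diameter_mm), ("density", density_g_mm3),
                     ("viscosity", viscosity_pa_s)):
        if not v > 0:
            raise ValidationError(f"reynolds_number: {label}={v} must be > 0")
    if peak_flow_mm3_s < 0:
        raise ValidationError(f"reynolds_number: flow {peak_flow_mm3_s} must be >= 0")
    area = math.pi * diameter_mm**2 / 4.0
    velocity = peak_flow_mm3_s / area  # mm/s
    return density_g_mm3 * velocity * diameter_mm / viscosity_pa_s


def shunt_resistance(spec: ShuntSpec, fluid: FluidProperties | None = None,
                     scale: float | None = None) -> float:
    """Resistance of the shunt branch at a given diameter scale.

    Both modes obey the d^-4 Poiseuille scaling in the diameter scale
    factor, so occlusion inference can treat resistance as a monotone
    function of scale in either mode.
    """
    fluid = fluid or FluidProperties()
    s = spec.scale if scale is None else scale
    if not (0 < s <= 1):
        raise ValidationError(f"diameter scale {s} must lie in (0, 1]")
    if spec.mode == "poiseuille":
        return (
            poiseuille_resistance(spec.diameter_mm * s, spec.length_mm, fluid.viscosity_pa_s)
            + spec.anastomosis_loss
        )
    return spec.resistance * (spec.reference_scale / s) ** 4


def build_surrogate_network(spec: SurrogateSpec) -> list[ComponentSpec]:
    """Resistor branches of the surrogate arterial domain.

    Aortic root node ``AoR`` feeds the five systemic branches and the
    shunt; the shunt drains into the pulmonary-artery junction ``PA_jct``
    which feeds the two pulmonary branches. Eight resistors total; branch
    entry nodes are named ``<branch>_in``.
    """
    comps = [
        ComponentSpec(
            "resistor",
            f"branch_{name}",
            "AoR",
            f"{name}_in",
            {"resistance": max(spec.branch_resistances[name], 1e-9)},
        )
        for name in SYSTEMIC_BRANCHES
    ]
    comps.append(
        ComponentSpec("resistor", "shunt", "AoR", "PA_jct",
                      {"resistance": shunt_resistance(spec.shunt, spec.fluid)})
    )
    for name in PULMONARY_BRANCHES:
        comps.append(
            ComponentSpec(
                "resistor",
                f"branch_{name}",
                "PA_jct",
                f"{name}_in",
                {"resistance": max(spec.branch_resistances[name], 1e-9)},
            )
        )
    return comps
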