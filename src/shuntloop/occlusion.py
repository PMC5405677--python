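"""Shunt-occlusion inference.

The degree of shunt narrowing is expressed as an effective diameter scale
factor s (new diameter / nominal diameter). Two routes estimate s:

* a closed form from the Hagen-Poiseuille d^-4 law applied to the
  resistance that must change, s = (R_ref/R_target)^(1/4);
* an iterative route that bisects on s in a closed-loop simulation until
  the simulated mean trans-shunt gradient and flow match measured targets
  within tolerance. The simulation route is the authoritative one: the
  closed form ignores every non-Poiseuille loss in the path, and the
  result depends on which resistances are taken as reference and target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

from .errors import SolverError, ValidationError


@dataclass(frozen=True)
class OcclusionEstimate:
    """Effective narrowing of the shunt expressed several equivalent ways."""

    scale: float  # effective diameter / nominal diameter, in (0, 1]
    method: str  # 'poiseuille_scaling' | 'iterative_simulation'
    reference_resistance: float | None = None
    target_resistance: float | None = None
    achieved: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.scale <= 1):
            raise ValidationError(f"diameter scale {self.scale} must lie in (0, 1]")

    @property
    def diameter_reduction_pct(self) -> float:
        return 100.0 * (1.0 - self.scale)

    @property
    def area_occlusion_pct(self) -> float:
        return 100.0 * (1.0 - self.scale**2)


def scale_from_resistance_ratio(r_ref: float, r_target: float) -> OcclusionEstimate:
    """Diameter scale from the d^-4 Poiseuille law: the factor by which the
    diameter must shrink for the resistance to rise from r_ref to r_target."""
    if not (r_ref > 0 and r_target > 0):
        raise ValidationError("resistances must be > 0")
    scale = (r_ref / r_target) ** 0.25
    if scale > 1:
        raise ValidationError(
            f"target resistance {r_target} below reference {r_ref}: no narrowing to infer"
        )
    return OcclusionEstimate(
        scale=scale,
        method="poiseuille_scaling",
        reference_resistance=r_ref,
        target_resistance=r_target,
    )


def occlusion_metrics(d_nominal_mm: float, d_effective_mm: float) -> OcclusionEstimate:
    """Diameter-reduction and area-occlusion percentages from the nominal
    and effective shunt diameters."""
    if not (d_nominal_mm > 0 and d_effective_mm > 0):
        raise ValidationError("diameters must be > 0")
    if d_effective_mm > d_nominal_mm:
        raise ValidationError(
            f"effective diameter {d_effective_mm} exceeds nominal {d_nominal_mm}"
        )
    return OcclusionEstimate(scale=d_effective_mm / d_nominal_mm, method="poiseuille_scaling")


def infer_occlusion_by_simulation(
    simulate_fn: Callable[[float], tuple[float, float]],
    target_gradient: float,
    target_flow: float,
    tol: float = 0.10,
    bracket: tuple[float, float] = (0.3, 1.0),
    max_iter: int = 30,
    min_bracket: float = 1e-3,
) -> OcclusionEstimate:
    """Bisect on the diameter scale until the simulated mean trans-shunt
    gradient AND mean shunt flow are both within relative ``tol`` of the
    targets.

    ``simulate_fn(scale)`` must run the closed loop with the shunt
    narrowed to ``scale`` and return (mean gradient mmHg, mean flow ml/s).
    The bisection direction is steered by the simulated *effective
    resistance* gradient/flow, which is strictly decreasing in scale (the
    d^-4 law; asserted at the bracket ends) and remains well conditioned
    when the closed loop makes the gradient itself nearly flat in scale.
    ``tol=0`` cannot be satisfied in floating point and yields a
    non-convergence report once the bracket collapses.
    """
    if not (target_gradient > 0 and target_flow > 0):
        raise ValidationError("targets must be > 0")
    lo, hi = bracket
    if not (0 < lo < hi <= 1):
        raise ValidationError(f"bracket {bracket} must satisfy 0 < lo < hi <= 1")
    r_target = target_gradient / target_flow

    evaluations: list[tuple[float, float, float]] = []

    def within(gradient, flow):
        return (
            abs(gradient - target_gradient) <= tol * target_gradient
            and abs(flow - target_flow) <= tol * target_flow
        )

    def run(scale):
        gradient, flow = simulate_fn(scale)
        evaluations.append((scale, gradient, flow))
        return gradient, flow

    g_hi, q_hi = run(hi)
    if within(g_hi, q_hi):
        return OcclusionEstimate(
            scale=hi,
            method="iterative_simulation",
            achieved={"gradient": g_hi, "flow": q_hi, "n_simulations": len(evaluations)},
        )
    g_lo, q_lo = run(lo)
    r_lo, r_hi = g_lo / q_lo, g_hi / q_hi
    if r_lo <= r_hi:
        raise SolverError(
            "effective shunt resistance is not decreasing in the diameter scale "
            "over the bracket"
        )
    if not (r_hi <= r_target <= r_lo):
        raise SolverError(
            f"target effective resistance {r_target:.3g} mmHg*s/ml unreachable for "
            f"scale in [{lo}, {hi}] (simulated range {r_hi:.3g}..{r_lo:.3g})"
        )

    best = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        gradient, flow = run(mid)
        best = (mid, gradient, flow)
        if within(gradient, flow):
            return OcclusionEstimate(
                scale=mid,
                method="iterative_simulation",
                achieved={
                    "gradient": gradient,
                    "flow": flow,
                    "n_simulations": len(evaluations),
                    "bracket": (lo, hi),
                },
            )
        if gradient / flow > r_target:
            lo = mid
        else:
            hi = mid
        if hi - lo < min_bracket:
            break
    scale, gradient, flow = best if best else (hi, g_hi, q_hi)
    raise SolverError(
        f"occlusion inference did not reach tol={tol} (best scale {scale:.4f}, "
        f"gradient {gradient:.3g} vs {target_gradient}, flow {flow:.3g} vs {target_flow}; "
        f"gradient error {abs(gradient - target_gradient) / target_gradient:.2%}, "
        f"{len(evaluations)} simulations)"
    )


def poiseuille_consistency(scale: float, r_ref: float) -> float:
    """Resistance implied by a diameter scale under the d^-4 law (inverse
    of :func:`scale_from_resistance_ratio`)."""
    if not (0 < scale <= 1 and r_ref > 0):
        raise ValidationError("need 0 < scale <= 1 and r_ref > 0")
    return r_ref / math.pow(scale, 4)
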