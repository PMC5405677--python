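"""Virtual-patient generation.

Ground-truth inputs for every stage of the analysis are produced by
forward simulation, so the elastance-construction and occlusion-inference
pipelines can be tested as parameter-recovery problems with no external
data. A virtual patient is an elastance ventricle with known E(t)
ejecting through a valve into a three-element Windkessel afterload and
refilling from a constant-pressure venous reservoir; its "recordings" are
the valve flow and ventricular pressure of the converged cycle, optionally
corrupted by multiplicative Gaussian noise on the pressure (catheter
traces being the noisier signal in practice).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .circuit import ComponentSpec, Netlist, WindkesselParams, make_windkessel
from .elastance import ElastanceCurve, periodic_gaussian
from .errors import ValidationError
from .simulate import initial_state, run_to_periodic

DEFAULT_PERIOD = 0.46
DATA_DT = 1e-3  # s, sampling interval of the emulated clinical recordings


@dataclass(frozen=True)
class ElastanceTruthParams:
    """Generating parameters of a ground-truth elastance curve."""

    e_min: float = 0.2  # mmHg/ml
    e_max: float = 3.0  # mmHg/ml
    peak_time: float = 0.15  # s
    sigma: float = 0.05  # s
    v0: float = 0.0  # ml

    def __post_init__(self):
        if not (self.e_max > self.e_min > 0):
            raise ValidationError("need E_max > E_min > 0")
        if not (self.sigma > 0 and self.peak_time >= 0):
            raise ValidationError("need sigma > 0 and peak_time >= 0")

    def __call__(self, t):
        return periodic_gaussian(
            t, self.e_min, self.e_max - self.e_min, self.peak_time, self.sigma,
            getattr(self, "_period", DEFAULT_PERIOD),
        )


def gen_elastance_truth(
    params: ElastanceTruthParams, period: float = DEFAULT_PERIOD, n_samples: int = 460
) -> ElastanceCurve:
    """Sampled ground-truth curve: Gaussian bump over a diastolic floor,
    periodized in circular time."""
    t = np.arange(n_samples) * period / n_samples
    values = periodic_gaussian(
        t, params.e_min, params.e_max - params.e_min, params.peak_time, params.sigma, period
    )
    return ElastanceCurve(
        period=period,
        values=values,
        labels=np.full(n_samples, "synthetic"),
        v0=params.v0,
    )


@dataclass
class VirtualPatient:
    """Simulated recordings plus the ground truth that generated them."""

    seed: int
    period: float
    truth_params: ElastanceTruthParams
    truth_curve: ElastanceCurve
    edv: float  # ml, end-diastolic volume of the converged cycle
    v0: float
    time: np.ndarray  # one cycle, uniform DATA_DT grid
    flow: np.ndarray  # valve (outflow) flow, ml/s
    pressure: np.ndarray  # ventricular pressure, mmHg (noise applied)
    pressure_clean: np.ndarray
    noise_sigma: float
    stroke_volume: float = 0.0
    metadata: dict = field(default_factory=dict)


def _ejection_loop(
    truth: ElastanceTruthParams,
    period: float,
    afterload: WindkesselParams,
    preload_mmhg: float,
) -> tuple[Netlist, dict]:
    comps = [
        ComponentSpec("elastance_chamber", "ventricle", "V", "ground", {"v0": truth.v0}),
        ComponentSpec("diode_valve", "NAV", "V", "art_in",
                      {"resistance": 1.0e-3, "inertance": 1.0e-5}),
        ComponentSpec("pressure_source", "venous_return", "atrium", "ground",
                      {"pressure": preload_mmhg}),
        ComponentSpec("diode_valve", "AVV", "atrium", "V",
                      {"resistance": 3.3e-3, "inertance": 6.667e-5}),
    ]
    comps += make_windkessel("afterload", afterload, closed_loop=False, node_in="art_in")
    truth_driver = lambda t: periodic_gaussian(  # noqa: E731
        t, truth.e_min, truth.e_max - truth.e_min, truth.peak_time, truth.sigma, period
    )
    return Netlist(comps), {"ventricle": truth_driver}


def gen_patient_waveforms(
    truth: ElastanceTruthParams | None = None,
    period: float = DEFAULT_PERIOD,
    afterload: WindkesselParams | None = None,
    preload_mmhg: float = 7.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    dt: float = 1e-4,
    max_cycles: int = 60,
    tol: float = 1e-4,
) -> VirtualPatient:
    """Simulate the single-ventricle ejection loop and emit its
    "recordings" on the clinical sampling grid.

    Default afterload/preload put the arterial pressure in the 50-60 mmHg
    range and mean outflow near 10 ml/s, the magnitudes of the circulation
    this package models.
    """
    truth = truth or ElastanceTruthParams()
    afterload = afterload or WindkesselParams(rp=0.6, rd=4.5, c=1.2, pd=6.0)
    netlist, drivers = _ejection_loop(truth, period, afterload, preload_mmhg)
    v_init = preload_mmhg / truth.e_min + truth.v0
    init = initial_state(netlist, pressure=10.0, volumes={"ventricle": v_init})
    result = run_to_periodic(
        netlist, dt=dt, max_cycles=max_cycles, tol=tol, period=period,
        drivers=drivers, init=init,
    )

    stride = int(round(DATA_DT / dt))
    sl = slice(1, None, stride)  # drop the duplicated cycle-boundary sample
    time = result.time[sl] - result.time[1]
    flow = result.branch_flow("NAV")[sl]
    pressure_clean = result.node_pressure("V")[sl]
    volume = result.chamber_volume("ventricle")[sl]
    edv = float(volume.max())
    stroke = float(volume.max() - volume.min())

    patient = VirtualPatient(
        seed=seed,
        period=period,
        truth_params=truth,
        truth_curve=gen_elastance_truth(truth, period, n_samples=len(time)),
        edv=edv,
        v0=truth.v0,
        time=time,
        flow=flow,
        pressure=pressure_clean.copy(),
        pressure_clean=pressure_clean,
        noise_sigma=0.0,
        stroke_volume=stroke,
        metadata={"converged": result.converged, "n_cycles": result.n_cycles, "dt": dt},
    )
    if noise_sigma > 0:
        patient = apply_measurement_noise(patient, noise_sigma, seed)
    return patient


def apply_measurement_noise(
    patient: VirtualPatient, sigma: float, seed: int
) -> VirtualPatient:
    """Multiplicative Gaussian noise on the pressure trace (the flow is
    left clean; PC-MRI flow curves are already cycle-averaged)."""
    rng = np.random.default_rng(seed)
    noisy = patient.pressure_clean * (1.0 + sigma * rng.standard_normal(len(patient.pressure_clean)))
    return replace(patient, pressure=noisy, noise_sigma=sigma, seed=seed)


def gen_targets_from_simulation(
    scale: float = 1.0,
    seed: int = 0,
    dt: float = 2e-4,
    max_cycles: int = 60,
    tol: float = 1e-3,
    shunt_reference_resistance: float = 2.1,
    **model_kwargs,
):
    """Run the packaged closed loop with a known shunt diameter scale and
    return its 16-index summary as a synthetic patient-recording target
    table (plus the summary itself). Deterministic: the closed loop has no
    stochastic elements, so the seed only tags the output."""
    from .compare import ClinicalTargets, TargetRule, summarize
    from .config import build_model

    netlist, drivers = build_model(
        "figure1_implant_time", shunt_scale=scale,
        shunt_reference_resistance=shunt_reference_resistance, **model_kwargs,
    )
    result = run_to_periodic(
        netlist, dt=dt, max_cycles=max_cycles, tol=tol, drivers=drivers
    )
    summary = summarize(result)
    targets = ClinicalTargets(
        {name: TargetRule(value=value, rule="rel10")
         for name, value in summary.indices().items()}
    )
    targets_meta = {"seed": seed, "scale": scale, "converged": result.converged}
    return targets, summary, targets_meta
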