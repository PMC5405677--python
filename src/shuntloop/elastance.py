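"""Patient-specific time-varying ventricular elastance construction.

The ventricle is modelled as a time-varying elastance chamber,
P(t) = E(t) * (V(t) - V0). During systole E(t) is measured directly: the
outflow-valve flow waveform is integrated and subtracted from the
end-diastolic volume to give the ejection-phase volume curve, and the
ventricular pressure recording is divided pointwise by (V - V0) over the
window in which the valve is open. The diastolic remainder of the cycle,
for which no data exist, is filled by least-squares extrapolation with a
single (periodized) Gaussian plus a constant diastolic offset. The
stitched curve is smoothed by truncating its Fourier series (C-infinity,
hence C1) and finally rescaled so the peak elastance is unchanged.

Units: E mmHg/ml, volumes ml, flow ml/s, time s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit

from .errors import AlignmentError, DataError, FittingError, ValidationError

DEFAULT_N_HARMONICS = 10
DEFAULT_EMIN_FLOOR = 0.05  # mmHg/ml; a pure Gaussian would give zero diastolic pressure
EJECTION_FLOW_FRACTION = 0.01  # ejection window: Q > 1% of peak Q


@dataclass
class ElastanceCurve:
    """Periodic E(t) on a uniform grid over one cycle (endpoint excluded).

    ``labels`` marks each sample's provenance: 'measured' (systolic,
    data-derived) or 'extrapolated' (Gaussian-filled); synthetic ground
    truths use 'synthetic'.
    """

    period: float
    values: np.ndarray
    labels: np.ndarray
    v0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 1 or len(self.values) < 4:
            raise ValidationError("ElastanceCurve needs a 1D grid of at least 4 samples")
        if len(self.labels) != len(self.values):
            raise ValidationError("labels and values must have equal length")
        if not np.all(self.values > 0):
            raise ValidationError("E(t) must be strictly positive everywhere")
        if not self.period > 0:
            raise ValidationError("period must be > 0")

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.period / len(self.values)

    @property
    def peak(self) -> float:
        return float(self.values.max())

    @property
    def peak_time(self) -> float:
        return float(self.time[int(np.argmax(self.values))])

    def __call__(self, t):
        """Periodic linear interpolation."""
        tt = np.asarray(t, dtype=float) % self.period
        grid = np.concatenate([self.time, [self.period]])
        vals = np.concatenate([self.values, [self.values[0]]])
        return np.interp(tt, grid, vals)


def periodic_gaussian(t, e_min, amplitude, t0, sigma, period):
    """Gaussian bump in circular time: the distance to t0 is wrapped so the
    curve is exactly periodic."""
    d = np.abs((np.asarray(t, dtype=float) - t0) % period)
    d = np.minimum(d, period - d)
    return e_min + amplitude * np.exp(-(d**2) / (2.0 * sigma**2))


def volume_from_flow(time: np.ndarray, flow: np.ndarray, edv: float) -> np.ndarray:
    """Ejection-phase ventricular volume V(t) = EDV - integral of the
    outflow (trapezoidal)."""
    time = np.asarray(time, dtype=float)
    flow = np.asarray(flow, dtype=float)
    if not edv > 0:
        raise DataError(f"EDV={edv} must be > 0")
    if len(time) != len(flow) or len(time) < 2:
        raise DataError("time and flow must be equal-length with >= 2 samples")
    if np.any(np.diff(time) <= 0):
        raise DataError("time grid must be strictly increasing")
    volume = edv - cumulative_trapezoid(flow, time, initial=0.0)
    if np.any(volume <= 0):
        raise DataError(
            f"integrated outflow ({edv - volume.min():.3g} ml) exceeds EDV ({edv} ml)"
        )
    return volume


def ejection_window(flow: np.ndarray, threshold_fraction: float = EJECTION_FLOW_FRACTION):
    """Boolean mask of the ejection window: Q above a fraction of peak Q,
    taken as the first contiguous run containing the flow peak."""
    flow = np.asarray(flow, dtype=float)
    peak = flow.max()
    if not peak > 0:
        raise DataError("flow waveform has no positive ejection phase")
    above = flow > threshold_fraction * peak
    ipeak = int(np.argmax(flow))
    lo = ipeak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = ipeak
    while hi < len(flow) - 1 and above[hi + 1]:
        hi += 1
    mask = np.zeros(len(flow), dtype=bool)
    mask[lo : hi + 1] = True
    return mask


def _upstroke_time(time, signal) -> float:
    """Landmark: time of maximum discrete derivative (steepest upstroke)."""
    signal = np.asarray(signal, dtype=float)
    if np.ptp(signal) <= 1e-12 * max(1.0, np.abs(signal).max()):
        raise AlignmentError("flat trace: no detectable upstroke")
    deriv = np.gradient(signal, time)
    return float(time[int(np.argmax(deriv))])


def align_pressure_volume(
    time: np.ndarray,
    pressure: np.ndarray,
    volume: np.ndarray,
    flow: np.ndarray,
    period: float,
):
    """Shift the volume/flow pair so ejection onset (first sample of the
    ejection window) coincides with the pressure upstroke landmark (time
    of peak dP/dt). Returns (pressure, volume_shifted, flow_shifted,
    shift_s); shifts are circular, all traces stay on the input grid.

    Intended for traces recorded on separate clocks; traces already on a
    shared acquisition clock need no alignment (see docs/methods.md).
    """
    time = np.asarray(time, dtype=float)
    pressure = np.asarray(pressure, dtype=float)
    t_p = _upstroke_time(time, pressure)
    mask = ejection_window(flow)
    t_q = float(time[np.flatnonzero(mask)[0]])
    shift = t_p - t_q
    dt = time[1] - time[0]
    n = int(round(shift / dt))
    return pressure, np.roll(volume, n), np.roll(flow, n), n * dt


def systolic_elastance(
    pressure: np.ndarray, volume: np.ndarray, v0: float, window: np.ndarray
) -> np.ndarray:
    """Pointwise E = P/(V - V0) over the valve-open window."""
    pressure = np.asarray(pressure, dtype=float)[window]
    volume = np.asarray(volume, dtype=float)[window]
    if np.any(volume <= v0):
        raise DataError(f"volume falls to or below V0={v0} ml inside the systolic window")
    return pressure / (volume - v0)


def gaussian_extrapolate(
    time_sys: np.ndarray,
    e_sys: np.ndarray,
    period: float,
    grid: np.ndarray,
    e_min_floor: float = DEFAULT_EMIN_FLOOR,
):
    """Fit a periodized Gaussian-plus-offset to the systolic segment and
    evaluate it on ``grid``; returns (values_on_grid, params dict)."""
    time_sys = np.asarray(time_sys, dtype=float)
    e_sys = np.asarray(e_sys, dtype=float)
    if len(time_sys) < 5:
        raise FittingError("systolic segment too short to fit a Gaussian")

    def model(t, e_min, amplitude, t0, sigma):
        return periodic_gaussian(t, e_min, amplitude, t0, sigma, period)

    t_guess = float(time_sys[int(np.argmax(e_sys))])
    span = float(time_sys[-1] - time_sys[0])
    p0 = [
        max(e_min_floor, float(e_sys.min()) * 0.5),
        max(float(e_sys.max() - e_sys.min()), 1e-3),
        t_guess,
        max(span / 4.0, 1e-3),
    ]
    bounds = (
        [e_min_floor, 1e-6, t_guess - period / 2, 1e-4],
        [max(e_sys.max(), e_min_floor * 2), 10 * e_sys.max(), t_guess + period / 2, period],
    )
    try:
        popt, _ = curve_fit(model, time_sys, e_sys, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        resid = np.abs(model(time_sys, *p0) - e_sys)
        raise FittingError(
            f"Gaussian extrapolation failed to converge "
            f"(initial residual max {resid.max():.3g}, rms {np.sqrt((resid**2).mean()):.3g})"
        ) from exc
    params = dict(zip(("e_min", "amplitude", "t0", "sigma"), (float(v) for v in popt)))
    return model(np.asarray(grid, dtype=float) % period, *popt), params


def fourier_smooth(values: np.ndarray, n_harmonics: int = DEFAULT_N_HARMONICS) -> np.ndarray:
    """Truncate the discrete Fourier series to ``n_harmonics`` and rescale
    so the peak is exactly preserved."""
    if n_harmonics < 1:
        raise ValidationError(f"n_harmonics={n_harmonics} must be >= 1")
    values = np.asarray(values, dtype=float)
    spectrum = np.fft.rfft(values)
    spectrum[n_harmonics + 1 :] = 0.0
    smoothed = np.fft.irfft(spectrum, n=len(values))
    old_peak, new_peak = values.max(), smoothed.max()
    if not new_peak > 0:
        raise DataError("smoothed curve lost positivity; increase n_harmonics")
    return smoothed * (old_peak / new_peak)


def c1_roughness(values: np.ndarray, dt: float) -> float:
    """Largest jump of the discrete derivative across consecutive samples
    (circular), a measure of C1 violation."""
    v = np.asarray(values, dtype=float)
    deriv = (np.roll(v, -1) - v) / dt
    return float(np.abs(np.diff(np.concatenate([deriv, deriv[:1]]))).max())


def build_elastance(
    time: np.ndarray,
    flow: np.ndarray,
    pressure: np.ndarray,
    edv: float,
    v0: float = 0.0,
    period: float | None = None,
    n_harmonics: int = DEFAULT_N_HARMONICS,
    e_min_floor: float = DEFAULT_EMIN_FLOOR,
    align: bool = False,
) -> ElastanceCurve:
    """Full pipeline: volume from flow, (optional) alignment, pointwise
    systolic elastance, Gaussian extrapolation, Fourier smoothing with
    peak rescaling.

    ``time`` must uniformly sample exactly one cycle (endpoint excluded);
    ``align=True`` applies the landmark alignment for traces recorded on
    separate clocks.
    """
    time = np.asarray(time, dtype=float)
    flow = np.asarray(flow, dtype=float)
    pressure = np.asarray(pressure, dtype=float)
    if not (len(time) == len(flow) == len(pressure)):
        raise DataError("time, flow and pressure must share one grid")
    dt = time[1] - time[0]
    if np.abs(np.diff(time) - dt).max() > 1e-9 * max(dt, 1.0):
        raise DataError("waveforms must be uniformly sampled")
    if period is None:
        period = float(len(time) * dt)

    volume = volume_from_flow(time, flow, edv)
    if align:
        pressure, volume, flow, _ = align_pressure_volume(time, pressure, volume, flow, period)
    window = ejection_window(flow)
    e_sys = systolic_elastance(pressure, volume, v0, window)
    t_sys = time[window]

    e_gauss, _ = gaussian_extrapolate(t_sys, e_sys, period, time, e_min_floor)
    stitched = e_gauss.copy()
    stitched[window] = e_sys
    smoothed = fourier_smooth(stitched, n_harmonics)
    if np.any(smoothed <= 0):
        raise DataError("smoothed elastance is not strictly positive")

    labels = np.where(window, "measured", "extrapolated")
    return ElastanceCurve(period=float(period), values=smoothed, labels=labels, v0=v0)
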