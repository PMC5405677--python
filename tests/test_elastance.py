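"""Elastance construction: closed-form stages, smoothing invariants,
round-trip recovery on simulator-generated virtual patients."""

import numpy as np
import pytest

from shuntloop.elastance import (
    ElastanceCurve,
    align_pressure_volume,
    build_elastance,
    c1_roughness,
    ejection_window,
    fourier_smooth,
    gaussian_extrapolate,
    periodic_gaussian,
    systolic_elastance,
    volume_from_flow,
)
from shuntloop.errors import AlignmentError, DataError, ValidationError


class TestVolumeFromFlow:
    def test_constant_flow(self):
        t = np.linspace(0, 0.2, 201)
        v = volume_from_flow(t, np.full_like(t, 10.0), edv=40.0)
        assert v[-1] == pytest.approx(38.0, abs=1e-9)
        assert np.all(np.diff(v) <= 0)

    def test_zero_flow_is_identity(self):
        t = np.linspace(0, 0.2, 51)
        assert np.allclose(volume_from_flow(t, np.zeros_like(t), 40.0), 40.0)

    def test_half_sine_ejection_closed_form(self):
        # Q = (pi SV / 2 tau) sin(pi t / tau) integrates to SV = 15
        tau, sv, edv = 0.2, 15.0, 38.0
        t = np.linspace(0, tau, 4001)
        q = (np.pi * sv / (2 * tau)) * np.sin(np.pi * t / tau)
        v = volume_from_flow(t, q, edv)
        assert v[-1] == pytest.approx(edv - sv, abs=1e-4)

    def test_flow_integral_exceeding_edv_is_data_error(self):
        t = np.linspace(0, 1.0, 101)
        with pytest.raises(DataError, match="exceeds EDV"):
            volume_from_flow(t, np.full_like(t, 50.0), edv=10.0)


class TestAlignment:
    @staticmethod
    def _traces(n=460, period=0.46, lag_samples=0):
        """Pressure whose steepest upstroke coincides with ejection onset
        by construction; the volume/flow pair optionally lags."""
        t = np.arange(n) * period / n
        onset, width = 0.10, 0.12
        ramp = np.clip((t - onset) / width, 0.0, 1.0)
        pressure = 10.0 + 60.0 * np.sin(ramp * np.pi / 2)  # max dP/dt at onset
        flow = np.where((t >= onset) & (t <= onset + width),
                        40.0 * np.sin((t - onset) / width * np.pi), 0.0)
        volume = 38.0 - np.cumsum(flow) * (period / n)
        return t, pressure, np.roll(volume, lag_samples), np.roll(flow, lag_samples)

    def test_zero_lag_gives_zero_shift(self):
        t, p, v, q = self._traces(lag_samples=0)
        *_, shift = align_pressure_volume(t, p, v, q, period=0.46)
        assert shift == pytest.approx(0.0, abs=1e-9)

    def test_known_lag_recovered_within_one_sample(self):
        t, p, v, q = self._traces(lag_samples=30)  # 30 ms at 1 ms sampling
        _, v_al, q_al, shift = align_pressure_volume(t, p, v, q, period=0.46)
        dt = t[1] - t[0]
        assert shift == pytest.approx(-30 * dt, abs=dt)
        assert np.argmax(q_al) == np.argmax(self._traces()[3])

    def test_flat_pressure_is_alignment_error(self):
        t, _, v, q = self._traces()
        with pytest.raises(AlignmentError, match="flat"):
            align_pressure_volume(t, np.full_like(t, 50.0), v, q, period=0.46)


class TestSystolicElastance:
    def test_pointwise_division(self):
        window = np.array([True, True])
        e = systolic_elastance(np.array([80.0, 60.0]), np.array([25.0, 35.0]),
                               v0=0.0, window=window)
        assert e[0] == pytest.approx(3.2)
        e2 = systolic_elastance(np.array([60.0]), np.array([35.0]), v0=15.0,
                                window=np.array([True]))
        assert e2[0] == pytest.approx(3.0)

    def test_volume_below_v0_is_domain_error(self):
        with pytest.raises(DataError, match="V0"):
            systolic_elastance(np.array([60.0]), np.array([10.0]), v0=15.0,
                               window=np.array([True]))


class TestGaussianExtrapolate:
    def test_exact_gaussian_segment_recovers_generators(self):
        period = 0.46
        grid = np.arange(460) * period / 460
        truth = dict(e_min=0.2, amplitude=2.8, t0=0.15, sigma=0.05)
        seg = (grid > 0.08) & (grid < 0.24)
        e_seg = periodic_gaussian(grid[seg], period=period, **truth)
        fitted, params = gaussian_extrapolate(grid[seg], e_seg, period, grid)
        for key, value in truth.items():
            assert params[key] == pytest.approx(value, rel=1e-3)
        assert np.allclose(fitted, periodic_gaussian(grid, period=period, **truth),
                           rtol=1e-3, atol=1e-6)

    def test_symmetric_segment_centers_on_its_max(self):
        period = 0.46
        grid = np.arange(460) * period / 460
        seg = (grid >= 0.10) & (grid <= 0.20)  # symmetric about t0 = 0.15
        e_seg = periodic_gaussian(grid[seg], 0.3, 2.0, 0.15, 0.04, period)
        _, params = gaussian_extrapolate(grid[seg], e_seg, period, grid)
        assert params["t0"] == pytest.approx(grid[seg][np.argmax(e_seg)], abs=0.002)


class TestFourierSmooth:
    def test_band_limited_input_is_fixed_point(self):
        t = np.arange(460) / 460
        e = 2.0 + 0.5 * np.cos(2 * np.pi * t + 0.3)
        assert np.allclose(fourier_smooth(e, 10), e, atol=1e-9)

    def test_peak_preserved_exactly(self, rng):
        e = 1.0 + np.abs(rng.standard_normal(460)).cumsum() / 100
        out = fourier_smooth(e, 10)
        assert abs(out.max() - e.max()) / e.max() < 1e-6

    def test_idempotent_after_first_pass(self, rng):
        e = 2.0 + rng.random(460)
        once = fourier_smooth(e, 10)
        twice = fourier_smooth(once, 10)
        assert np.abs(twice - once).max() / np.abs(once).max() < 1e-9

    def test_kink_roughness_reduced(self):
        period = 0.46
        t = np.arange(460) * period / 460
        e = np.where((t > 0.1) & (t < 0.25), 3.0, 0.3)  # C0 square-ish curve
        dt = period / 460
        assert c1_roughness(fourier_smooth(e, 10), dt) < 0.1 * c1_roughness(e, dt)

    def test_rejects_zero_harmonics(self):
        with pytest.raises(ValidationError):
            fourier_smooth(np.ones(32), 0)


class TestElastanceCurve:
    def test_positivity_enforced(self):
        with pytest.raises(ValidationError):
            ElastanceCurve(0.46, np.array([1.0, -0.1, 1.0, 1.0]), np.array(["x"] * 4))

    def test_periodic_evaluation_wraps(self):
        curve = ElastanceCurve(1.0, 1.0 + np.sin(2 * np.pi * np.arange(100) / 100) ** 2,
                               np.array(["synthetic"] * 100))
        assert curve(0.0) == pytest.approx(curve(1.0), abs=1e-12)
        assert curve(2.37) == pytest.approx(curve(0.37), abs=1e-12)


class TestPipelineRecovery:
    def test_noise_free_round_trip(self, virtual_patient):
        p = virtual_patient
        curve = build_elastance(p.time, p.flow, p.pressure_clean, edv=p.edv,
                                v0=p.v0, period=p.period)
        truth = p.truth_curve
        rel = (curve.values - truth.values) / truth.values
        assert np.sqrt((rel**2).mean()) < 0.02  # full-cycle RMS < 2%
        assert abs(curve.peak - truth.peak) / truth.peak < 0.02
        assert abs(int(np.argmax(curve.values)) - int(np.argmax(truth.values))) <= 2
        assert set(np.unique(curve.labels)) == {"measured", "extrapolated"}

    def test_c1_and_peak_invariants(self, virtual_patient):
        p = virtual_patient
        curve = build_elastance(p.time, p.flow, p.pressure_clean, edv=p.edv,
                                v0=p.v0, period=p.period)
        assert np.all(curve.values > 0)
        assert curve(0.0) == pytest.approx(curve(p.period), abs=1e-9)
        dt = p.period / len(curve.values)
        # band-limited to 10 harmonics: derivative jumps bounded by spectrum decay
        assert c1_roughness(curve.values, dt) < 50.0

    def test_edv_smaller_than_stroke_volume_is_data_error(self, virtual_patient):
        p = virtual_patient
        with pytest.raises(DataError):
            build_elastance(p.time, p.flow, p.pressure_clean,
                            edv=0.5 * p.stroke_volume, v0=p.v0, period=p.period)
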