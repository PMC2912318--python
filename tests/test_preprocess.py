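import numpy as np
import pytest

from gammapen.preprocess import (
    bandpass_filter,
    piecewise_detrend,
    preprocess,
    remove_stimulus_artifact,
    resample_signal,
)
from gammapen.signal_io import PipelineConfig
from gammapen.synthetic_lfp import SynthParams, generate_recording

from .conftest import make_recording


def _sine_recording(freq, fs, duration_ms, amplitude=1.0, stim_time_ms=10.0):
    n = round(duration_ms / 1000.0 * fs)
    t = np.arange(n) / fs
    return make_recording(amplitude * np.sin(2 * np.pi * freq * t), fs=fs,
                          stim_time_ms=stim_time_ms)


class TestRemoveStimulusArtifact:
    def test_blanked_window_bounded_by_neighbourhood(self):
        params = SynthParams(artifact_amp=10 * 100.0)
        rec = generate_recording(params, "control", "s01", seed=11)
        out = remove_stimulus_artifact(rec, (2.0, 10.0))
        fs = rec.fs
        i0 = round((rec.stim_time_ms - 2.0) / 1000.0 * fs)
        i1 = round((rec.stim_time_ms + 10.0) / 1000.0 * fs)
        inside = np.max(np.abs(out.samples[i0:i1]))
        adjacent = np.max(np.abs(np.concatenate([
            out.samples[i0 - round(0.010 * fs) : i0],
            out.samples[i1 : i1 + round(0.010 * fs)],
        ])))
        assert inside <= adjacent

    def test_locality_outside_window(self):
        rec = generate_recording(SynthParams(artifact_amp=0.0), "control", "s01", seed=3)
        out = remove_stimulus_artifact(rec, (2.0, 10.0))
        fs = rec.fs
        i0 = round((rec.stim_time_ms - 2.0) / 1000.0 * fs)
        i1 = round((rec.stim_time_ms + 10.0) / 1000.0 * fs)
        np.testing.assert_array_equal(out.samples[:i0], rec.samples[:i0])
        np.testing.assert_array_equal(out.samples[i1:], rec.samples[i1:])
        assert out.n_samples == rec.n_samples

    def test_window_past_trace_end_raises(self, rng):
        # trace ends 5 ms after the stimulus
        rec = make_recording(rng.normal(size=110), fs=2000.0, stim_time_ms=50.0)
        with pytest.raises(ValueError, match="past the trace"):
            remove_stimulus_artifact(rec, (2.0, 10.0))


class TestResampleSignal:
    def test_length_arithmetic_100k_to_2k(self, rng):
        rec = make_recording(rng.normal(size=50_000), fs=100_000.0, stim_time_ms=50.0)
        out = resample_signal(rec, 2000.0)
        assert out.n_samples == 1000
        assert out.fs == 2000.0
        assert out.stim_time_ms == rec.stim_time_ms

    def test_passband_tone_preserved(self):
        rec = _sine_recording(60.0, 100_000.0, 500.0)
        out = resample_signal(rec, 2000.0)
        # amplitude from central region, away from edge effects
        mid = out.samples[200:800]
        amplitude = np.sqrt(2.0) * np.sqrt(np.mean(mid**2))
        assert 0.98 <= amplitude <= 1.02

    def test_stopband_tone_suppressed(self):
        rec = _sine_recording(900.0, 100_000.0, 500.0)
        out = resample_signal(rec, 2000.0)
        in_rms = np.sqrt(np.mean(rec.samples**2))
        out_rms = np.sqrt(np.mean(out.samples[200:800] ** 2))
        assert out_rms < 0.05 * in_rms

    def test_non_integer_factor_rejected(self, rng):
        rec = make_recording(rng.normal(size=1000), fs=3000.0, stim_time_ms=10.0)
        with pytest.raises(ValueError, match="integer multiple"):
            resample_signal(rec, 2000.0)

    def test_factor_one_identity(self, rng):
        rec = make_recording(rng.normal(size=500), fs=2000.0, stim_time_ms=10.0)
        out = resample_signal(rec, 2000.0)
        np.testing.assert_array_equal(out.samples, rec.samples)


class TestPiecewiseDetrend:
    def test_linear_ramp_removed(self):
        fs = 2000.0
        t = np.arange(1000) / fs
        rec = make_recording(3.0 + 40.0 * t, fs=fs, stim_time_ms=10.0)
        out = piecewise_detrend(rec, 100.0)
        scale = np.max(np.abs(rec.samples))
        assert np.max(np.abs(out.samples)) < 1e-9 * scale

    def test_constant_removed(self):
        rec = make_recording(np.full(1000, 123.0), fs=2000.0, stim_time_ms=10.0)
        out = piecewise_detrend(rec, 100.0)
        assert np.max(np.abs(out.samples)) < 1e-9 * 123.0

    def test_each_piece_zero_mean_zero_slope(self, rng):
        fs = 2000.0
        rec = make_recording(rng.normal(0, 5, 1000) + 30 * np.arange(1000) / fs,
                             fs=fs, stim_time_ms=10.0)
        out = piecewise_detrend(rec, 100.0)
        step = round(0.1 * fs)
        scale = np.max(np.abs(rec.samples))
        for start in range(0, 1000, step):
            piece = out.samples[start : start + step]
            x = np.arange(piece.size)
            assert abs(piece.mean()) < 1e-9 * scale
            slope = np.polyfit(x, piece, 1)[0]
            assert abs(slope) < 1e-9 * scale

    def test_ramp_plus_sine_recovers_sine(self):
        fs = 2000.0
        t = np.arange(1000) / fs
        sine = np.sin(2 * np.pi * 60 * t)
        rec = make_recording(5.0 + 20.0 * t + sine, fs=fs, stim_time_ms=10.0)
        out = piecewise_detrend(rec, 100.0)
        r = np.corrcoef(out.samples, sine)[0, 1]
        assert r > 0.99

    def test_too_fine_knots_rejected(self, rng):
        rec = make_recording(rng.normal(size=100), fs=1000.0, stim_time_ms=10.0)
        with pytest.raises(ValueError, match="2 samples"):
            piecewise_detrend(rec, 0.5)


class TestBandpassFilter:
    def test_midband_gain(self):
        rec = _sine_recording(60.0, 2000.0, 1000.0)
        out = bandpass_filter(rec, 30.0, 300.0)
        mid = out.samples[400:1600]
        amplitude = np.sqrt(2.0) * np.sqrt(np.mean(mid**2))
        assert 0.95 <= amplitude <= 1.05

    def test_low_stopband(self):
        rec = _sine_recording(5.0, 2000.0, 2000.0)
        out = bandpass_filter(rec, 30.0, 300.0)
        assert np.sqrt(np.mean(out.samples**2)) < 0.1 * np.sqrt(np.mean(rec.samples**2))

    def test_dc_killed(self):
        rec = make_recording(np.full(2000, 100.0), fs=2000.0, stim_time_ms=10.0)
        out = bandpass_filter(rec, 30.0, 300.0)
        assert np.mean(np.abs(out.samples)) < 1.0

    def test_zero_phase(self):
        # a mid-band probe must come out with its cross-correlation peak at lag 0
        rec = _sine_recording(80.0, 2000.0, 1000.0)
        out = bandpass_filter(rec, 30.0, 300.0)
        xc = np.correlate(out.samples[200:1800], rec.samples[200:1800], mode="full")
        lag = int(np.argmax(xc)) - (len(xc) // 2)
        assert lag == 0

    def test_high_corner_above_nyquist_rejected(self, rng):
        rec = make_recording(rng.normal(size=1000), fs=2000.0, stim_time_ms=10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(rec, 30.0, 1000.0)


@pytest.fixture(scope="module")
def raw():
    return generate_recording(SynthParams(), "control", "s01", seed=5)


class TestPreprocessChain:
    def test_output_rate_and_report(self, raw, cfg):
        out, report = preprocess(raw, cfg)
        assert out.fs == 2000.0
        assert report.decimation_factor == 50
        assert "30" in report.filter_description
        assert "300" in report.filter_description
        assert report.blanked_interval_ms == (raw.stim_time_ms - 2.0,
                                              raw.stim_time_ms + 10.0)

    def test_approximate_idempotence(self, raw, cfg):
        out, _ = preprocess(raw, cfg)
        again, _ = preprocess(out, cfg)  # factor-1 resample on second pass
        rms = np.sqrt(np.mean(out.samples**2))
        rms2 = np.sqrt(np.mean(again.samples**2))
        assert abs(rms2 - rms) / rms < 0.02

    def test_detrend_preserves_band_energy(self, raw, cfg):
        from gammapen.preprocess import piecewise_detrend, remove_stimulus_artifact, \
            resample_signal
        from .conftest import band_rms

        stage = resample_signal(remove_stimulus_artifact(raw, cfg.artifact_blank_ms),
                                cfg.target_fs)
        detr = piecewise_detrend(stage, cfg.detrend_breakpoint_ms)
        window = (0.0, 450.0)
        before = band_rms(stage, cfg.band, window)
        after = band_rms(detr, cfg.band, window)
        assert abs(after**2 - before**2) / before**2 < 0.05

    def test_deterministic(self, raw, cfg):
        a, _ = preprocess(raw, cfg)
        b, _ = preprocess(raw, cfg)
        np.testing.assert_array_equal(a.samples, b.samples)
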