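import numpy as np
import pytest
from scipy import signal as sps

from gammapen.signal_io import PipelineConfig, Recording
from gammapen.synthetic_lfp import SynthParams


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_params() -> SynthParams:
    return SynthParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def band_rms(rec: Recording, band: tuple[float, float],
             window_ms: tuple[float, float]) -> float:
    """RMS of the band-filtered trace inside a post-stimulus window (test helper)."""
    sos = sps.butter(4, band, btype="bandpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples)
    t0, t1 = window_ms
    i0 = round((rec.stim_time_ms + t0) / 1000.0 * rec.fs)
    i1 = round((rec.stim_time_ms + t1) / 1000.0 * rec.fs)
    return float(np.sqrt(np.mean(filtered[i0:i1] ** 2)))


def windowed_band_rms(rec: Recording, band: tuple[float, float],
                      window_ms: tuple[float, float]) -> float:
    """Gamma-band RMS inside a window, immune to out-of-window leakage.

    Blanks the stimulus artifact, cuts the window *first*, then integrates
    the Hann periodogram over the band; a whole-trace zero-phase filter
    would smear burst energy backwards across the window edge.
    """
    from gammapen.preprocess import remove_stimulus_artifact

    blanked = remove_stimulus_artifact(rec, (2.0, 10.0))
    t0, t1 = window_ms
    i0 = round((rec.stim_time_ms + t0) / 1000.0 * rec.fs)
    i1 = round((rec.stim_time_ms + t1) / 1000.0 * rec.fs)
    seg = blanked.samples[i0:i1]
    freqs, power = sps.periodogram(seg, fs=rec.fs, window="hann", detrend="constant")
    mask = (freqs >= band[0]) & (freqs <= band[1])
    df = freqs[1] - freqs[0]
    return float(np.sqrt(np.sum(power[mask]) * df))


def make_recording(samples, fs=2000.0, stim_time_ms=10.0, condition="control",
                   slice_id="s01", **meta) -> Recording:
    return Recording(samples=np.asarray(samples, dtype=float), fs=fs,
                     stim_time_ms=stim_time_ms, condition=condition,
                     slice_id=slice_id, meta=meta)
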