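"""Preprocessing chain: artifact blanking, resampling, detrending, band-pass.

Stages are applied in a fixed order — artifact removal, resample to the
target rate, piecewise linear detrend, zero-phase band-pass — and each run
is summarised in a :class:`PreprocessReport`.

The stimulation artifact is removed by linear interpolation over a short
window rather than by deleting samples: deletion would shift every
post-stimulus timestamp and silently move the analysis windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .signal_io import PipelineConfig, Recording

__all__ = [
    "PreprocessReport",
    "remove_stimulus_artifact",
    "resample_signal",
    "piecewise_detrend",
    "bandpass_filter",
    "preprocess",
]


@dataclass
class PreprocessReport:
    """Provenance record of one preprocessing run."""

    blanked_interval_ms: tuple[float, float]
    decimation_factor: int
    detrend_knots_ms: list[float]
    filter_description: str

    def to_dict(self) -> dict:
        return {
            "blanked_interval_ms": list(self.blanked_interval_ms),
            "decimation_factor": self.decimation_factor,
            "detrend_knots_ms": list(self.detrend_knots_ms),
            "filter_description": self.filter_description,
        }


def remove_stimulus_artifact(rec: Recording, blank_ms: tuple[float, float]) -> Recording:
    """Replace samples in ``[stim - pre, stim + post)`` ms by linear interpolation.

    The interpolation runs between the last sample before the window and the
    first sample at/after it; all other samples are untouched and the length
    is unchanged.
    """
    pre, post = blank_ms
    if pre < 0 or post < 0:
        raise ValueError(f"blanking margins must be >= 0, got ({pre}, {post})")
    t0 = rec.stim_time_ms - pre
    t1 = rec.stim_time_ms + post
    i0 = round(t0 / 1000.0 * rec.fs)
    i1 = round(t1 / 1000.0 * rec.fs)
    if i0 < 1 or i1 > rec.n_samples - 1:
        raise ValueError(
            f"blanking window [{t0}, {t1}) ms extends past the trace "
            f"(0..{rec.duration_ms:.3f} ms, interpolation anchors required on both sides)"
        )
    out = rec.samples.copy()
    left, right = out[i0 - 1], out[i1]
    # anchors at i0-1 and i1; interior points linearly interpolated
    frac = (np.arange(i0, i1) - (i0 - 1)) / (i1 - (i0 - 1))
    out[i0:i1] = left + frac * (right - left)
    return rec.with_samples(out)


@lru_cache(maxsize=8)
def _antialias_fir(fs_in: float, target_fs: float) -> tuple[np.ndarray, str]:
    """Linear-phase Kaiser FIR low-pass used before decimation.

    Cut-off at 0.8x the target Nyquist; 65 dB stopband reached at the target
    Nyquist edge.
    """
    nyq_out = target_fs / 2.0
    cutoff = 0.8 * nyq_out
    width = 0.2 * nyq_out  # transition 0.7..0.9 x target Nyquist
    numtaps, beta = sps.kaiserord(65.0, width / (fs_in / 2.0))
    numtaps |= 1  # odd length -> integer group delay, exact zero-phase via mode="same"
    taps = sps.firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs_in)
    desc = (
        f"anti-alias: linear-phase Kaiser FIR low-pass, {numtaps} taps, "
        f"cutoff {cutoff:.0f} Hz (0.8 x target Nyquist), 65 dB stopband"
    )
    return taps, desc


def resample_signal(rec: Recording, target_fs: float) -> Recording:
    """Anti-alias low-pass then decimate by the integer factor ``fs / target_fs``.

    Only integer decimation factors are supported.  A factor of 1 returns
    the recording unchanged.
    """
    if target_fs <= 0:
        raise ValueError(f"target_fs must be > 0, got {target_fs}")
    factor = rec.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"fs {rec.fs} Hz is not an integer multiple of target {target_fs} Hz "
            f"(factor {factor:.6g}); rational resampling is out of scope"
        )
    q = int(round(factor))
    if q == 1:
        return rec.with_samples(rec.samples.copy())
    taps, _ = _antialias_fir(rec.fs, target_fs)
    filtered = sps.fftconvolve(rec.samples, taps, mode="same")
    return rec.with_samples(filtered[::q], fs=target_fs)


def detrend_knots(n_samples: int, fs: float, knot_spacing_ms: float) -> list[int]:
    """Breakpoint sample indices for piecewise detrending (pieces of given spacing)."""
    step = round(knot_spacing_ms / 1000.0 * fs)
    if step < 2:
        raise ValueError(
            f"knot spacing {knot_spacing_ms} ms is shorter than 2 samples at {fs} Hz"
        )
    bp = list(range(step, n_samples, step))
    # a trailing piece of < 2 samples cannot carry a line fit; merge it
    if bp and n_samples - bp[-1] < 2:
        bp.pop()
    return bp


def piecewise_detrend(rec: Recording, knot_spacing_ms: float) -> Recording:
    """Subtract the least-squares line from each contiguous piece of the trace.

    Pieces are ``knot_spacing_ms`` long (the last may be shorter); each output
    piece has zero mean and zero least-squares slope.
    """
    if knot_spacing_ms <= 0:
        raise ValueError(f"knot spacing must be > 0 ms, got {knot_spacing_ms}")
    bp = detrend_knots(rec.n_samples, rec.fs, knot_spacing_ms)
    out = sps.detrend(rec.samples, type="linear", bp=bp)
    return rec.with_samples(out)


def bandpass_filter(rec: Recording, low: float, high: float) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward)."""
    nyq = rec.fs / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(f"high corner {high} Hz must be below Nyquist {nyq} Hz")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.samples)
    return rec.with_samples(out)


def preprocess(rec: Recording, cfg: PipelineConfig) -> tuple[Recording, PreprocessReport]:
    """Full chain: artifact removal -> resample -> detrend -> band-pass."""
    pre, post = cfg.artifact_blank_ms
    blanked = remove_stimulus_artifact(rec, (pre, post))
    resampled = resample_signal(blanked, cfg.target_fs)
    factor = int(round(rec.fs / cfg.target_fs))
    detrended = piecewise_detrend(resampled, cfg.detrend_breakpoint_ms)
    low, high = cfg.band
    out = bandpass_filter(detrended, low, high)
    if factor > 1:
        _, aa_desc = _antialias_fir(rec.fs, cfg.target_fs)
    else:
        aa_desc = "anti-alias: none (decimation factor 1)"
    knots = detrend_knots(resampled.n_samples, resampled.fs, cfg.detrend_breakpoint_ms)
    report = PreprocessReport(
        blanked_interval_ms=(rec.stim_time_ms - pre, rec.stim_time_ms + post),
        decimation_factor=factor,
        detrend_knots_ms=[k / resampled.fs * 1000.0 for k in knots],
        filter_description=(
            f"{aa_desc}; band-pass: Butterworth order 4, corners {low:.0f}-{high:.0f} Hz, "
            "zero-phase (forward-backward sosfiltfilt)"
        ),
    )
    return out, report
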