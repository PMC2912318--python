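"""Isolation of the post-stimulus gamma segment and its spectral checks.

The study window is a fixed half-open interval relative to stimulus onset
(default 150-250 ms); the programmatic gamma-dominance check replaces the
original visual inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import Recording, Segment

__all__ = [
    "PowerSpectrum",
    "isolate_gamma_segment",
    "power_spectrum",
    "dominant_frequency",
    "is_gamma_dominant",
]


@dataclass
class PowerSpectrum:
    """One-sided power spectral density on a regular frequency grid."""

    freqs: np.ndarray  # Hz, strictly increasing
    power: np.ndarray  # uV^2/Hz, >= 0
    method: str

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape or self.freqs.ndim != 1:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        if self.freqs.size > 1 and not np.all(np.diff(self.freqs) > 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative everywhere")


def isolate_gamma_segment(rec: Recording, window_ms: tuple[float, float]) -> Segment:
    """Extract samples in ``[stim + t0, stim + t1)`` ms as a :class:`Segment`."""
    t0, t1 = window_ms
    if not t1 > t0 >= 0:
        raise ValueError(f"window must satisfy t1 > t0 >= 0, got ({t0}, {t1})")
    post_extent_ms = rec.duration_ms - rec.stim_time_ms
    if post_extent_ms < t1:
        raise ValueError(
            f"trace extends only {post_extent_ms:.3f} ms past the stimulus; "
            f"window ({t0}, {t1}) ms requires {t1:.3f} ms"
        )
    i0 = round((rec.stim_time_ms + t0) / 1000.0 * rec.fs)
    n = round((t1 - t0) / 1000.0 * rec.fs)
    return Segment(
        samples=rec.samples[i0 : i0 + n].copy(),
        fs=rec.fs,
        window_ms=(t0, t1),
        slice_id=rec.slice_id,
        condition=rec.condition,
        meta={"source_stim_time_ms": rec.stim_time_ms},
    )


def power_spectrum(seg: Segment) -> PowerSpectrum:
    """Hann-windowed periodogram of the mean-removed segment on a ~1 Hz grid.

    The segment is zero-padded to one second's worth of points so the grid
    spacing is 1 Hz (padding interpolates the spectrum; it adds no
    information).  With density scaling, ``sum(power) * df`` equals the
    window-weighted signal variance (Parseval).
    """
    if seg.n_samples < 64:
        raise ValueError(f"segment too short for spectral analysis ({seg.n_samples} < 64)")
    nfft = max(int(round(seg.fs)), seg.n_samples)
    freqs, power = sps.periodogram(
        seg.samples, fs=seg.fs, window="hann", nfft=nfft, detrend="constant",
        scaling="density",
    )
    return PowerSpectrum(
        freqs=freqs,
        power=power,
        method=f"Hann periodogram, mean removed, zero-padded to nfft={nfft} "
               f"(grid {seg.fs / nfft:.3g} Hz)",
    )


def dominant_frequency(ps: PowerSpectrum, search_band: tuple[float, float]) -> float:
    """Frequency of maximum power within ``[lo, hi]``; ties go to the lower frequency."""
    lo, hi = search_band
    if not lo < hi:
        raise ValueError(f"search band must satisfy lo < hi, got ({lo}, {hi})")
    mask = (ps.freqs >= lo) & (ps.freqs <= hi)
    if not np.any(mask):
        raise ValueError(
            f"search band ({lo}, {hi}) Hz contains no grid points of the spectrum "
            f"({ps.freqs[0]:.3g}..{ps.freqs[-1]:.3g} Hz)"
        )
    band_freqs = ps.freqs[mask]
    band_power = ps.power[mask]
    return float(band_freqs[int(np.argmax(band_power))])  # argmax -> first max -> lowest f


def is_gamma_dominant(
    ps: PowerSpectrum,
    gamma_band: tuple[float, float] = (30.0, 120.0),
    margin: float = 2.0,
    analysis_band: tuple[float, float] = (30.0, 300.0),
) -> tuple[bool, dict]:
    """True iff the peak inside the gamma band is >= margin x the peak outside it.

    "Outside" is restricted to the analysed band-pass extent (default
    30-300 Hz).  Returns the verdict plus a diagnostics dict.
    """
    g_lo, g_hi = gamma_band
    a_lo, a_hi = analysis_band
    if not (g_lo < g_hi and a_lo < a_hi):
        raise ValueError("bands must satisfy lo < hi")
    in_mask = (ps.freqs >= g_lo) & (ps.freqs <= g_hi)
    out_mask = (ps.freqs >= a_lo) & (ps.freqs <= a_hi) & ~in_mask
    if not np.any(in_mask) or not np.any(out_mask):
        raise ValueError("bands contain no spectrum grid points")
    peak_in = float(np.max(ps.power[in_mask]))
    peak_out = float(np.max(ps.power[out_mask]))
    diag = {
        "peak_in_gamma": peak_in,
        "peak_outside_gamma": peak_out,
        "margin": margin,
        "gamma_band": list(gamma_band),
        "analysis_band": list(analysis_band),
    }
    if peak_in == 0.0:
        diag["reason"] = "no power in gamma band"
        return False, diag
    verdict = peak_in >= margin * peak_out
    diag["ratio"] = peak_in / peak_out if peak_out > 0 else float("inf")
    return bool(verdict), diag
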