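"""Domain types and on-disk formats shared across the pipeline.

Time convention: milliseconds, 0 = trace start; stimulus onset is stored
explicitly on each :class:`Recording`; all analysis windows are half-open
``[t0, t1)`` and expressed relative to stimulus onset.  Sample indexing is
0-based internally.

On-disk format: a two-column comma-delimited text file with header
``time_ms,voltage_uV`` plus a flat JSON sidecar carrying ``fs``,
``stim_time_ms``, ``condition`` and ``slice_id``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "CONDITIONS",
    "Recording",
    "Segment",
    "PipelineConfig",
    "read_recording",
    "write_recording",
    "read_config",
]

CONDITIONS = ("control", "nicotine", "washout")

_DATA_HEADER = "time_ms,voltage_uV"


@dataclass
class Recording:
    """A single-electrode field-potential trace with its acquisition metadata.

    Attributes
    ----------
    samples : ndarray
        Voltage samples in microvolts, trace order.
    fs : float
        Sampling rate in Hz.
    stim_time_ms : float
        Stimulus onset relative to trace start, in ms.
    condition : str
        One of ``control``, ``nicotine``, ``washout``.
    slice_id : str
        Opaque identifier of the slice; shared across conditions in a
        paired design.
    meta : dict
        Free-form annotations (provenance, generator parameters, ...).
    """

    samples: np.ndarray
    fs: float
    stim_time_ms: float
    condition: str
    slice_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("Recording.samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Recording.samples contains NaN or infinite values")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be > 0 Hz, got {self.fs}")
        if not 0 <= self.stim_time_ms < self.duration_ms:
            raise ValueError(
                f"stim_time_ms={self.stim_time_ms} outside trace [0, {self.duration_ms}) ms"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        return self.samples.size / self.fs * 1000.0

    def with_samples(self, samples, fs: float | None = None) -> "Recording":
        """Copy of this recording with new samples (and optionally a new rate)."""
        return replace(self, samples=np.asarray(samples, dtype=float),
                       fs=self.fs if fs is None else fs, meta=dict(self.meta))


@dataclass
class Segment:
    """A windowed excerpt of a Recording, tied to a post-stimulus window.

    ``window_ms`` is the half-open interval ``[t0, t1)`` in ms relative to
    stimulus onset; the sample count must equal ``round((t1 - t0)/1000 * fs)``.
    """

    samples: np.ndarray
    fs: float
    window_ms: tuple[float, float]
    slice_id: str
    condition: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        t0, t1 = self.window_ms
        if not t1 > t0 >= 0:
            raise ValueError(f"window must satisfy t1 > t0 >= 0, got ({t0}, {t1})")
        expected = round((t1 - t0) / 1000.0 * self.fs)
        if self.samples.size != expected:
            raise ValueError(
                f"segment has {self.samples.size} samples; window ({t0}, {t1}) ms at "
                f"{self.fs} Hz requires {expected}"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis chain, with the study defaults."""

    target_fs: float = 2000.0
    band: tuple[float, float] = (30.0, 300.0)
    gamma_window_ms: tuple[float, float] = (150.0, 250.0)
    artifact_blank_ms: tuple[float, float] = (2.0, 10.0)
    detrend_breakpoint_ms: float = 100.0
    apen_m: int = 2
    apen_r_coeff: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.target_fs <= 0:
            raise ValueError(f"target_fs must be > 0, got {self.target_fs}")
        lo, hi = self.band
        if not lo < hi:
            raise ValueError(f"band must satisfy low < high, got ({lo}, {hi})")
        t0, t1 = self.gamma_window_ms
        if not t1 > t0 >= 0:
            raise ValueError(f"gamma window must satisfy t1 > t0 >= 0, got ({t0}, {t1})")
        pre, post = self.artifact_blank_ms
        if pre < 0 or post < 0:
            raise ValueError("artifact blanking margins must be >= 0")
        if self.detrend_breakpoint_ms <= 0:
            raise ValueError("detrend_breakpoint_ms must be > 0")
        if int(self.apen_m) != self.apen_m or self.apen_m < 1:
            raise ValueError(f"apen_m must be a positive integer, got {self.apen_m}")
        if self.apen_r_coeff <= 0:
            raise ValueError(f"apen_r_coeff must be > 0, got {self.apen_r_coeff}")

    def to_dict(self) -> dict:
        return {
            "target_fs": self.target_fs,
            "band": list(self.band),
            "gamma_window_ms": list(self.gamma_window_ms),
            "artifact_blank_ms": list(self.artifact_blank_ms),
            "detrend_breakpoint_ms": self.detrend_breakpoint_ms,
            "apen_m": self.apen_m,
            "apen_r_coeff": self.apen_r_coeff,
            "seed": self.seed,
        }


_TUPLE_KEYS = {"band", "gamma_window_ms", "artifact_blank_ms"}


def read_config(path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from flat JSON; absent keys take defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a JSON object")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}; known keys: {sorted(known)}")
    kwargs = {}
    for key, value in raw.items():
        if key in _TUPLE_KEYS:
            value = tuple(value)
        kwargs[key] = value
    return PipelineConfig(**kwargs)


def read_recording(path_data, path_meta) -> Recording:
    """Read a recording from a data CSV plus its JSON sidecar.

    The declared sampling rate is cross-checked against the median time step
    of the data file; a mismatch above 1% is a hard error.
    """
    path_data, path_meta = Path(path_data), Path(path_meta)
    with open(path_meta, "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    for key in ("fs", "stim_time_ms", "condition", "slice_id"):
        if key not in meta:
            raise ValueError(f"metadata file {path_meta} missing required key {key!r}")
    table = np.genfromtxt(path_data, delimiter=",", skip_header=1)
    if table.ndim == 1:
        table = table.reshape(1, -1)
    if table.shape[1] != 2:
        raise ValueError(f"{path_data}: expected 2 columns ({_DATA_HEADER}), got {table.shape[1]}")
    if not np.all(np.isfinite(table)):
        raise ValueError(f"{path_data}: missing or non-finite samples")
    time_ms, volts = table[:, 0], table[:, 1]
    fs = float(meta["fs"])
    if fs <= 0:
        raise ValueError(f"declared fs must be > 0, got {fs}")
    if time_ms.size > 1:
        dt = float(np.median(np.diff(time_ms)))
        if dt <= 0:
            raise ValueError(f"{path_data}: non-increasing time column")
        implied_fs = 1000.0 / dt
        if abs(implied_fs - fs) > 0.01 * fs:
            raise ValueError(
                f"{path_data}: implied sampling rate {implied_fs:.6g} Hz disagrees with "
                f"declared fs {fs:.6g} Hz by more than 1%"
            )
    extra = {k: v for k, v in meta.items()
             if k not in ("fs", "stim_time_ms", "condition", "slice_id")}
    return Recording(
        samples=volts,
        fs=fs,
        stim_time_ms=float(meta["stim_time_ms"]),
        condition=str(meta["condition"]),
        slice_id=str(meta["slice_id"]),
        meta=extra,
    )


def write_recording(rec: Recording, path_data, path_meta) -> None:
    """Write a recording as data CSV + JSON sidecar (round-trips to <= 1e-6 uV)."""
    rec.validate()
    path_data, path_meta = Path(path_data), Path(path_meta)
    t_ms = np.arange(rec.n_samples) / rec.fs * 1000.0
    lines = [_DATA_HEADER]
    lines.extend(f"{t:.6f},{v:.8f}" for t, v in zip(t_ms, rec.samples))
    path_data.write_text("\n".join(lines) + "\n", encoding="utf-8")
    meta = {
        "fs": rec.fs,
        "stim_time_ms": rec.stim_time_ms,
        "condition": rec.condition,
        "slice_id": rec.slice_id,
    }
    meta.update({k: v for k, v in rec.meta.items() if _jsonable(v)})
    path_meta.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n", encoding="utf-8")


def _jsonable(value) -> bool:
    try:
        json.dumps(value)
        return True
    except (TypeError, ValueError):
        return False
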