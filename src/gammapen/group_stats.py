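"""Per-condition aggregation, paired comparisons, and pipeline orchestration.

The design is within-slice repeated measures, so the primary significance
test is a paired two-tailed t-test on per-slice differences; a paired
Wilcoxon signed-rank p-value is always reported alongside as a
distribution-free companion.  No multiple-testing correction is applied
across the three pairwise comparisons; all raw p-values are reported so a
user can apply one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from . import __version__
from .apen_core import ApEnParams, approximate_entropy
from .gamma_segment import (
    dominant_frequency,
    is_gamma_dominant,
    isolate_gamma_segment,
    power_spectrum,
)
from .preprocess import preprocess
from .signal_io import CONDITIONS, PipelineConfig, Recording, read_recording
from .synthetic_lfp import CohortSpec, generate_cohort

__all__ = [
    "ConditionSummary",
    "PairwiseComparison",
    "TraceResult",
    "ComparisonReport",
    "summarize_condition",
    "paired_comparison",
    "process_recording",
    "run_pipeline",
]

#: comparison pairs, sign convention (first - second)
PAIRS = (("nicotine", "control"), ("nicotine", "washout"), ("control", "washout"))


@dataclass
class ConditionSummary:
    condition: str
    values: list[float]
    mean: float
    sem: float
    n: int

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "values": list(self.values),
            "mean": self.mean,
            "sem": self.sem,
            "n": self.n,
        }


@dataclass
class PairwiseComparison:
    """Paired comparison between two conditions; sign convention (first - second)."""

    first: str
    second: str
    mean_difference: float
    t_statistic: float | None
    p_t: float | None
    p_wilcoxon: float | None
    n: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "first": self.first,
            "second": self.second,
            "mean_difference": self.mean_difference,
            "t_statistic": self.t_statistic,
            "p_t": self.p_t,
            "p_wilcoxon": self.p_wilcoxon,
            "n": self.n,
            "degenerate": self.degenerate,
        }


@dataclass
class TraceResult:
    """Per-trace analysis row."""

    slice_id: str
    condition: str
    n: int
    r_used: float
    phi_m: float
    phi_m1: float
    apen: float
    degenerate: bool
    dominant_freq_hz: float
    gamma_dominant: bool

    def to_dict(self) -> dict:
        return {
            "slice_id": self.slice_id,
            "condition": self.condition,
            "n": self.n,
            "r_used": self.r_used,
            "phi_m": self.phi_m,
            "phi_m1": self.phi_m1,
            "apen": self.apen,
            "degenerate": self.degenerate,
            "dominant_freq_hz": self.dominant_freq_hz,
            "gamma_dominant": self.gamma_dominant,
        }


@dataclass
class ComparisonReport:
    summaries: dict[str, ConditionSummary]
    pairwise: dict[str, PairwiseComparison]
    traces: list[TraceResult]
    n_slices: int
    config: dict
    qc: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "software": {"package": "gammapen", "version": __version__},
            "note": "raw p-values, no multiple-testing correction applied",
            "n_slices": self.n_slices,
            "config": self.config,
            "summaries": {k: v.to_dict() for k, v in self.summaries.items()},
            "pairwise": {k: v.to_dict() for k, v in self.pairwise.items()},
            "qc": self.qc,
            "traces": [t.to_dict() for t in self.traces],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def summarize_condition(values, condition: str) -> ConditionSummary:
    """Mean and SEM (sample SD / sqrt(n)) of per-slice values for one condition."""
    values = [float(v) for v in values]
    n = len(values)
    if n < 2:
        raise ValueError(f"SEM is undefined for n={n}; need at least 2 per-slice values")
    arr = np.asarray(values)
    return ConditionSummary(
        condition=condition,
        values=values,
        mean=float(arr.mean()),
        sem=float(arr.std(ddof=1) / np.sqrt(n)),
        n=n,
    )


def paired_comparison(a, b, slice_ids_a, slice_ids_b=None,
                      first: str = "a", second: str = "b") -> PairwiseComparison:
    """Paired two-tailed t-test (primary) and Wilcoxon signed-rank on a - b.

    ``slice_ids_a`` / ``slice_ids_b`` must pair the observations; when all
    per-slice differences are identical the comparison is flagged
    degenerate instead of raising (p = 1.0 when the difference is exactly
    zero, p = None otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ids_a = list(slice_ids_a)
    ids_b = ids_a if slice_ids_b is None else list(slice_ids_b)
    if ids_a != ids_b:
        raise ValueError(f"mismatched slice ids: {ids_a} vs {ids_b}")
    if not (len(a) == len(b) == len(ids_a)):
        raise ValueError("values and slice_ids must have equal lengths")
    if len(set(ids_a)) != len(ids_a):
        raise ValueError(f"duplicate slice ids in pairing: {ids_a}")
    n = len(a)
    if n < 3:
        raise ValueError(f"paired comparison needs n >= 3 slices, got {n}")
    diffs = a - b
    mean_diff = float(diffs.mean())
    scale = max(1.0, float(np.max(np.abs(diffs))), float(np.max(np.abs(a))))
    if np.ptp(diffs) <= 1e-12 * scale:
        # constant differences (to rounding): the t statistic is undefined
        p = 1.0 if abs(mean_diff) <= 1e-12 * scale else None
        return PairwiseComparison(
            first=first, second=second, mean_difference=mean_diff,
            t_statistic=None, p_t=p, p_wilcoxon=p, n=n, degenerate=True,
        )
    t_stat, p_t = stats.ttest_rel(a, b)
    try:
        _, p_w = stats.wilcoxon(a, b)
        p_w = float(p_w)
    except ValueError:
        p_w = None
    return PairwiseComparison(
        first=first, second=second, mean_difference=mean_diff,
        t_statistic=float(t_stat), p_t=float(p_t), p_wilcoxon=p_w, n=n,
    )


def process_recording(rec: Recording, cfg: PipelineConfig) -> TraceResult:
    """preprocess -> isolate gamma window -> spectral QC -> ApEn for one trace."""
    clean, _ = preprocess(rec, cfg)
    seg = isolate_gamma_segment(clean, cfg.gamma_window_ms)
    ps = power_spectrum(seg)
    dom = dominant_frequency(ps, (30.0, 120.0))
    gamma_ok, _ = is_gamma_dominant(ps)
    res = approximate_entropy(
        seg.samples, ApEnParams(m=cfg.apen_m, r_coeff=cfg.apen_r_coeff)
    )
    return TraceResult(
        slice_id=rec.slice_id,
        condition=rec.condition,
        n=res.n,
        r_used=res.r_used,
        phi_m=res.phi_m,
        phi_m1=res.phi_m1,
        apen=res.apen,
        degenerate=res.degenerate,
        dominant_freq_hz=dom,
        gamma_dominant=gamma_ok,
    )


def _load_recordings(input_dir) -> list[Recording]:
    input_dir = Path(input_dir)
    recs = []
    for meta_path in sorted(input_dir.glob("*.json")):
        if meta_path.name == "manifest.json":
            continue
        data_path = meta_path.with_suffix(".csv")
        if data_path.exists():
            recs.append(read_recording(data_path, meta_path))
    if not recs:
        raise ValueError(f"no recording (csv + json) pairs found in {input_dir}")
    return recs


def run_pipeline(
    cfg: PipelineConfig,
    recordings: list[Recording] | None = None,
    input_dir=None,
    cohort_spec: CohortSpec | None = None,
) -> ComparisonReport:
    """End-to-end analysis of a cohort (files, in-memory, or simulated).

    Every recording is preprocessed, windowed, spectrally checked and
    scored with ApEn; per-condition summaries and the three pairwise
    comparisons are assembled into a :class:`ComparisonReport`.  Traces
    failing the gamma-dominance QC are flagged but still analysed.
    """
    sources = [recordings is not None, input_dir is not None, cohort_spec is not None]
    if sum(sources) != 1:
        raise ValueError("provide exactly one of recordings, input_dir, cohort_spec")
    if cohort_spec is not None:
        recordings = generate_cohort(cohort_spec)
    elif input_dir is not None:
        recordings = _load_recordings(input_dir)

    traces = [process_recording(rec, cfg) for rec in recordings]

    by_condition: dict[str, dict[str, float]] = {}
    for tr in traces:
        per = by_condition.setdefault(tr.condition, {})
        if tr.slice_id in per:
            raise ValueError(f"duplicate trace for {tr.slice_id}/{tr.condition}")
        per[tr.slice_id] = tr.apen

    summaries = {}
    for cond in CONDITIONS:
        per = by_condition.get(cond, {})
        if len(per) < 2:
            raise ValueError(f"condition {cond!r} has {len(per)} slices; need >= 2")
        summaries[cond] = summarize_condition(
            [per[sid] for sid in sorted(per)], cond
        )

    pairwise = {}
    for first, second in PAIRS:
        ids = sorted(set(by_condition[first]) & set(by_condition[second]))
        pairwise[f"{first}_vs_{second}"] = paired_comparison(
            [by_condition[first][sid] for sid in ids],
            [by_condition[second][sid] for sid in ids],
            ids, first=first, second=second,
        )

    n_slices = len({tr.slice_id for tr in traces})
    qc = {
        "n_traces": len(traces),
        "n_gamma_dominance_failures": sum(not tr.gamma_dominant for tr in traces),
        "n_degenerate_apen": sum(tr.degenerate for tr in traces),
    }
    return ComparisonReport(
        summaries=summaries,
        pairwise=pairwise,
        traces=traces,
        n_slices=n_slices,
        config=cfg.to_dict(),
        qc=qc,
    )
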