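"""Approximate entropy (ApEn) for short, noisy time series.

ApEn summarises a length-N series into a nonnegative number: the average
log conditional probability that runs of m samples that are close (within
a tolerance r, Chebyshev distance) remain close when extended to m + 1
samples.  Lower values mean a more regular, predictable signal.

Conventions (fixed for bit-reproducibility):

* template vectors at embedding length m are ``X(i) = [x(i), ..., x(i+m-1)]``
  for ``i = 1 .. N - m + 1`` (1-based, 0-based internally);
* the match predicate is ``d <= r``;
* self-matches (j == i) are counted, so every correlation count is > 0 and
  every logarithm is finite; with this convention ApEn >= 0;
* ``phi(x, m, r)`` always uses the ``N - m + 1`` templates of length m, so
  the m+1 term of ApEn is an average over ``N - m`` templates;
* when r is derived from the data, the *population* standard deviation
  (ddof=0) of the analysed segment is used.

Two implementations are provided: a vectorised main routine
(:func:`approximate_entropy`) and a deliberately naive double-loop oracle
(:func:`approximate_entropy_oracle`) used to validate it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

__all__ = [
    "ApEnParams",
    "ApEnResult",
    "chebyshev_distance",
    "correlation_count",
    "phi",
    "approximate_entropy",
    "approximate_entropy_oracle",
    "tolerance_from_sd",
]


@dataclass(frozen=True)
class ApEnParams:
    """Parameters of the ApEn statistic.

    Parameters
    ----------
    m : int
        Embedding dimension (template length), >= 1.
    r : float, optional
        Absolute tolerance, in signal units.  When ``None`` the tolerance
        is derived from the analysed signal as ``r_coeff * SD``.
    r_coeff : float
        Coefficient applied to the signal SD when ``r`` is not given.
    """

    m: int = 2
    r: float | None = None
    r_coeff: float = 0.1

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 1:
            raise ValueError(f"embedding dimension m must be a positive integer, got {self.m}")
        if self.r is not None and self.r < 0:
            raise ValueError(f"tolerance r must be >= 0, got {self.r}")
        if self.r_coeff <= 0:
            raise ValueError(f"r_coeff must be > 0, got {self.r_coeff}")


@dataclass(frozen=True)
class ApEnResult:
    """ApEn value plus the diagnostics needed to audit it.

    ``apen == phi_m - phi_m1`` to machine precision.  ``degenerate`` is set
    when r resolved to 0 on a non-constant signal (the value then reflects
    counts of exact repeats only).
    """

    apen: float
    phi_m: float
    phi_m1: float
    n: int
    r_used: float
    params: ApEnParams
    degenerate: bool = False
    meta: dict = field(default_factory=dict)


def chebyshev_distance(u, v) -> float:
    """Maximum absolute componentwise difference between two equal-length vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.ndim != 1 or v.ndim != 1 or u.shape != v.shape or u.size < 1:
        raise ValueError(f"expected equal-length 1-D vectors, got shapes {u.shape} and {v.shape}")
    return float(np.max(np.abs(u - v)))


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D sequence, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains NaN or infinite samples")
    return x


def _count_matrix(x: np.ndarray, m: int, r: float) -> np.ndarray:
    """Per-template match fractions C_i at embedding length m (vectorised)."""
    templates = sliding_window_view(x, m)
    dist = cdist(templates, templates, metric="chebyshev")
    n_templates = templates.shape[0]
    return (dist <= r).sum(axis=1) / n_templates


def correlation_count(x, i: int, m: int, r: float) -> float:
    """Fraction of templates within tolerance r of template ``X(i)`` (i is 1-based).

    Includes the self-match ``j == i``, so the result is in ``(0, 1]``.
    """
    x = _as_series(x)
    n = x.size
    n_templates = n - m + 1
    if n_templates < 1:
        raise ValueError(f"need N >= m, got N={n}, m={m}")
    if not 1 <= i <= n_templates:
        raise IndexError(f"template index i={i} out of range 1..{n_templates}")
    xi = x[i - 1 : i - 1 + m]
    count = 0
    for j in range(n_templates):
        if chebyshev_distance(xi, x[j : j + m]) <= r:
            count += 1
    return count / n_templates


def phi(x, m: int, r: float) -> float:
    """Average of ``ln C_i`` over the ``N - m + 1`` templates of length m."""
    x = _as_series(x)
    if x.size <= m:
        raise ValueError(f"phi requires N > m, got N={x.size}, m={m}")
    counts = _count_matrix(x, m, r)
    return float(np.mean(np.log(counts)))


def tolerance_from_sd(x, r_coeff: float = 0.1) -> float:
    """Tolerance ``r = r_coeff * SD(x)`` with the population-SD convention."""
    x = _as_series(x)
    if x.size < 2:
        raise ValueError(f"need at least 2 samples to estimate SD, got {x.size}")
    sd = float(np.std(x))
    if sd == 0.0:
        warnings.warn("constant signal: SD-derived tolerance is 0", stacklevel=2)
        return 0.0
    return r_coeff * sd


def approximate_entropy(x, params: ApEnParams | None = None) -> ApEnResult:
    """ApEn(m, r, N) = phi(x, m, r) - phi(x, m + 1, r).

    When ``params.r`` is ``None`` the tolerance is ``r_coeff * SD(x)``
    computed on ``x`` itself.
    """
    params = params or ApEnParams()
    x = _as_series(x)
    n = x.size
    if n < params.m + 2:
        raise ValueError(f"ApEn requires N >= m + 2, got N={n}, m={params.m}")
    if params.r is not None:
        r = float(params.r)
    else:
        r = tolerance_from_sd(x, params.r_coeff)
    degenerate = False
    if r == 0.0 and np.ptp(x) > 0.0:
        degenerate = True
        warnings.warn(
            "r = 0 on a non-constant signal: ApEn counts exact repeats only", stacklevel=2
        )
    phi_m = phi(x, params.m, r)
    phi_m1 = phi(x, params.m + 1, r)
    return ApEnResult(
        apen=phi_m - phi_m1,
        phi_m=phi_m,
        phi_m1=phi_m1,
        n=n,
        r_used=r,
        params=params,
        degenerate=degenerate,
    )


def _phi_loops(x: np.ndarray, m: int, r: float) -> float:
    # literal double-loop transcription; no vectorisation by design
    n = len(x)
    n_templates = n - m + 1
    log_sum = 0.0
    for i in range(n_templates):
        count = 0
        for j in range(n_templates):
            d = 0.0
            for k in range(m):
                diff = abs(x[i + k] - x[j + k])
                if diff > d:
                    d = diff
            if d <= r:
                count += 1
        log_sum += math.log(count / n_templates)
    return log_sum / n_templates


def approximate_entropy_oracle(x, params: ApEnParams | None = None) -> float:
    """Brute-force O(N^2) ApEn with the same conventions as the main routine.

    Ground-truth reference; intended for N <= 2000.
    """
    params = params or ApEnParams()
    x = _as_series(x)
    n = x.size
    if n < params.m + 2:
        raise ValueError(f"ApEn requires N >= m + 2, got N={n}, m={params.m}")
    if params.r is not None:
        r = float(params.r)
    else:
        r = params.r_coeff * float(np.std(x))
    xs = [float(v) for v in x]
    return _phi_loops(xs, params.m, r) - _phi_loops(xs, params.m + 1, r)
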