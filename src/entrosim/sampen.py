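"""Sample Entropy SampEn(m, r, tau) with the maximum-entropy bound.

SampEn = -ln(A/B), where B counts unordered pairs of length-m template
vectors (delay tau between elements) within Chebyshev distance r*SD, and A
counts the pairs that still match when the templates are extended to m+1
points. Self-matches are excluded and the conditional probability A/B is
computed over the whole record (not template-wise). The largest observable
value for given (N, m, tau) is ln(N - m*tau - 1) + ln(N - m*tau) - ln 2,
reached when exactly one template pair matches at both lengths; dividing by
this bound gives a 0-1 normalized estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["SampEnParams", "SampEnResult", "sampen", "max_sampen", "normalize_sampen"]


@dataclass(frozen=True)
class SampEnParams:
    """Hyperparameters: template length m, radius r (in SD units), delay tau."""

    m: int = 1
    r: float = 0.25
    tau: int = 1

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")


@dataclass(frozen=True)
class SampEnResult:
    A: int  # matching template pairs at length m+1
    B: int  # matching template pairs at length m
    value: float  # -ln(A/B), nats; NaN when A or B is zero
    max_value: float  # maximum-entropy bound, nats
    normalized: float  # value / max_value; NaN when value is NaN
    effective_tolerance: float  # r * SD in signal units


@njit(cache=True)
def _count_matches(x, m, tau, tol):  # pragma: no cover - exercised via wrapper
    n = x.shape[0]
    nt = n - m * tau  # number of templates; same index range for A and B
    a = 0
    b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            dmax = 0.0
            for k in range(m):
                dd = abs(x[i + k * tau] - x[j + k * tau])
                if dd > dmax:
                    dmax = dd
            if dmax <= tol:
                b += 1
                if abs(x[i + m * tau] - x[j + m * tau]) <= tol:
                    a += 1
    return a, b


def max_sampen(n: int, m: int = 1, tau: int = 1) -> float:
    """Maximum attainable SampEn: ln(N - m*tau - 1) + ln(N - m*tau) - ln 2."""
    if n <= m * tau + 1:
        raise ValueError(f"need N > m*tau + 1, got N={n}, m={m}, tau={tau}")
    return math.log(n - m * tau - 1) + math.log(n - m * tau) - math.log(2.0)


def normalize_sampen(value: float, n: int, m: int = 1, tau: int = 1) -> float:
    """Divide a SampEn value by its maximum-entropy bound (0-1 scale)."""
    return value / max_sampen(n, m, tau)


def sampen(
    x: np.ndarray,
    params: SampEnParams = SampEnParams(),
    tolerance: float | None = None,
) -> SampEnResult:
    """Compute SampEn(m, r, tau) of a series.

    The match tolerance is r times the sample SD of the series as given
    (pass ``tolerance`` to override it in signal units). When A or B is
    zero the entropy is undefined: value and normalized are NaN, counts
    are retained.
    """
    x = np.ascontiguousarray(x, dtype=float)
    n = len(x)
    if n <= (params.m + 1) * params.tau:
        raise ValueError("series too short for the requested (m, tau)")
    tol = float(params.r * x.std()) if tolerance is None else float(tolerance)
    a, b = _count_matches(x, params.m, params.tau, tol)
    bound = max_sampen(n, params.m, params.tau)
    if a == 0 or b == 0:
        value = math.nan
        norm = math.nan
    else:
        value = -math.log(a / b)
        norm = value / bound
    return SampEnResult(
        A=int(a), B=int(b), value=value, max_value=bound, normalized=norm,
        effective_tolerance=tol,
    )
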