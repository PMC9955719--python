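"""Exact simulation of ARFIMA(0,d,0) fractional Gaussian noise and fBm.

The fGn/fBm family is parameterised here by the fractional difference order
``d`` of an ARFIMA(0,d,0) process. A stationary fGn has ``d`` in ]-0.5, 0.5[
and scaling exponent ``alpha = d + 0.5`` in ]0, 1[; its cumulative sum is a
nonstationary fBm with ``alpha = d + 1.5`` in ]1, 2[.

Sampling is *exact*: a Gaussian vector with the closed-form autocovariance
of the process is drawn either by the Durbin-Levinson recursion (short
series) or by circulant embedding (long series), so there is no burn-in or
MA-truncation error. Every generated dataset is standardized to mean 0 and
standard deviation 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from scipy.special import gammaln

__all__ = [
    "ArfimaSpec",
    "SimulatedSeries",
    "acvf_arfima",
    "simulate_fgn",
    "cumsum_series",
    "difference_series",
    "alpha_from_d",
    "standardize",
    "child_seed",
    "read_series",
    "write_series",
    "write_manifest",
]

# series length above which circulant embedding replaces Durbin-Levinson
_DL_MAX_N = 2048

STATIONARY = "stationary"
NONSTATIONARY = "nonstationary"


@dataclass(frozen=True)
class ArfimaSpec:
    """Parameters of one simulated realization.

    Parameters
    ----------
    d : float
        Fractional difference order, in ]-0.5, 0.5[.
    n : int
        Series length, at least 16.
    seed : int
        RNG seed; identical specs yield byte-identical series.
    integrate : bool
        If True, cumulatively sum the fGn to produce an fBm.
    """

    d: float
    n: int
    seed: int
    integrate: bool = False

    def __post_init__(self) -> None:
        if not -0.5 < self.d < 0.5:
            raise ValueError(f"d must lie in ]-0.5, 0.5[, got {self.d}")
        if self.n < 16:
            raise ValueError(f"n must be >= 16, got {self.n}")


@dataclass(frozen=True)
class SimulatedSeries:
    """A generated realization with its ground truth."""

    values: np.ndarray
    true_d: float
    true_alpha: float
    class_label: str
    seed: int


def alpha_from_d(d: float, was_differenced: bool = False) -> float:
    """Map a fractional difference order to the scaling exponent alpha.

    alpha = (2d + 1)/2 = d + 0.5 for stationary series; estimates obtained
    on differenced (nonstationary) data first add 1 to d, mapping onto
    ]1, 2[.
    """
    if not -0.5 < d < 0.5:
        raise ValueError(f"d must lie in ]-0.5, 0.5[, got {d}")
    if was_differenced:
        d = d + 1.0
    return (2.0 * d + 1.0) / 2.0


def acvf_arfima(d: float, max_lag: int) -> np.ndarray:
    """Autocovariance gamma(0..max_lag) of unit-innovation ARFIMA(0,d,0).

    gamma(0) = Gamma(1-2d)/Gamma(1-d)^2 and
    gamma(k) = gamma(k-1) * (k-1+d)/(k-d).
    """
    if not -0.5 < d < 0.5:
        raise ValueError(f"d must lie in ]-0.5, 0.5[, got {d}")
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    gamma = np.empty(max_lag + 1)
    gamma[0] = np.exp(gammaln(1.0 - 2.0 * d) - 2.0 * gammaln(1.0 - d))
    k = np.arange(1, max_lag + 1)
    if max_lag >= 1:
        gamma[1:] = gamma[0] * np.cumprod((k - 1.0 + d) / (k - d))
    return gamma


def standardize(x: np.ndarray) -> np.ndarray:
    """Center to mean 0 and rescale to SD 1 (population SD)."""
    x = np.asarray(x, dtype=float)
    s = x.std()
    if s == 0:
        raise ValueError("cannot standardize a constant series")
    return (x - x.mean()) / s


@njit(cache=True)
def _durbin_levinson(gamma, z):  # pragma: no cover - exercised via wrapper
    n = z.shape[0]
    x = np.empty(n)
    phi = np.zeros(n)
    phi_prev = np.zeros(n)
    v = gamma[0]
    x[0] = np.sqrt(v) * z[0]
    for t in range(1, n):
        acc = gamma[t]
        for j in range(1, t):
            acc -= phi_prev[j] * gamma[t - j]
        k = acc / v
        phi[t] = k
        for j in range(1, t):
            phi[j] = phi_prev[j] - k * phi_prev[t - j]
        v *= 1.0 - k * k
        m = 0.0
        for j in range(1, t + 1):
            m += phi[j] * x[t - j]
        x[t] = m + np.sqrt(v) * z[t]
        for j in range(1, t + 1):
            phi_prev[j] = phi[j]
    return x


def _circulant_fgn(d: float, n: int, rng: np.random.Generator) -> np.ndarray | None:
    """Draw an exact fGn of length n by circulant embedding.

    Returns None when the embedding is not nonnegative definite (does not
    occur for ARFIMA(0,d,0), but guarded anyway; caller falls back to
    Durbin-Levinson).
    """
    g = acvf_arfima(d, n)
    c = np.concatenate([g, g[-2:0:-1]])  # circulant first row, length 2n
    lam = np.fft.fft(c).real
    if lam.min() < -1e-8 * lam.max():
        return None
    lam = np.clip(lam, 0.0, None)
    m = 2 * n
    a = rng.standard_normal(m)
    b = rng.standard_normal(m)
    y = np.fft.fft(np.sqrt(lam) * (a + 1j * b))
    return y.real[:n] / np.sqrt(m)


def simulate_fgn(spec: ArfimaSpec) -> SimulatedSeries:
    """Simulate one standardized fGn (or fBm if spec.integrate) realization.

    The Gaussian vector has exactly the ARFIMA(0,d,0) autocovariance:
    Durbin-Levinson sampling for n <= 2048, circulant embedding above.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n <= _DL_MAX_N:
        gamma = acvf_arfima(spec.d, spec.n - 1)
        x = _durbin_levinson(gamma, rng.standard_normal(spec.n))
    else:
        x = _circulant_fgn(spec.d, spec.n, rng)
        if x is None:
            gamma = acvf_arfima(spec.d, spec.n - 1)
            x = _durbin_levinson(gamma, rng.standard_normal(spec.n))
    if spec.integrate:
        x = np.cumsum(x)
        label = NONSTATIONARY
        alpha = alpha_from_d(spec.d, was_differenced=True)
    else:
        label = STATIONARY
        alpha = alpha_from_d(spec.d)
    return SimulatedSeries(
        values=standardize(x),
        true_d=spec.d,
        true_alpha=alpha,
        class_label=label,
        seed=spec.seed,
    )


def cumsum_series(x: np.ndarray) -> np.ndarray:
    """Cumulative sum followed by standardization (the fBm convention)."""
    return standardize(np.cumsum(np.asarray(x, dtype=float)))


def difference_series(x: np.ndarray) -> np.ndarray:
    """First difference x_t - x_{t-1}, length n-1."""
    return np.diff(np.asarray(x, dtype=float))


def child_seed(master_seed: int, *key: int) -> int:
    """Deterministic per-replicate seed derived from a master seed.

    Counter-based: the key tuple selects an independent stream via
    ``numpy.random.SeedSequence`` spawn keys; the returned integer is
    below 2**31 so it can be recorded and replayed portably.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# plain-text series I/O


def read_series(path: str | Path) -> np.ndarray:
    """Read a univariate series: one value per line or single-column CSV.

    A non-numeric first line is treated as a header and skipped.
    """
    path = Path(path)
    text = path.read_text().strip().splitlines()
    start = 0
    if text:
        first = text[0].replace(",", " ").split()
        try:
            [float(v) for v in first]
        except ValueError:
            start = 1
    values = []
    for line in text[start:]:
        line = line.strip()
        if not line:
            continue
        values.extend(float(v) for v in line.replace(",", " ").split())
    return np.asarray(values, dtype=float)


def write_series(path: str | Path, x: np.ndarray, header: str | None = None) -> None:
    """Write a series as single-column text, optionally with a header line."""
    lines = [] if header is None else [header]
    lines.extend(repr(float(v)) for v in np.asarray(x, dtype=float))
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(path: str | Path, entries: list[dict]) -> None:
    """Write a JSON manifest recording d, alpha, N and seed per dataset."""
    Path(path).write_text(json.dumps(entries, indent=2) + "\n")
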