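"""Outlier injection, scaled-MAD detection, and cleaning remedies.

Contamination adds standard-normal draws scaled by a multiple of the
peak-to-peak signal amplitude to a small fraction of samples, the spike
model that inflates the sample SD and hence the effective SampEn tolerance
r*SD, biasing entropy downward. Detection uses a conservative threshold of
(by default) five scaled median absolute deviations. Remedies: shrink r by
the SD ratio, remove flagged samples, or classify the series first and
detect on the increments when it is nonstationary (spikes that do not stand
out in a wandering record stand out sharply in its differences).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import NONSTATIONARY, STATIONARY, difference_series
from .whittle import classify_and_estimate

__all__ = [
    "ContaminationSpec",
    "OutlierReport",
    "CleaningOutcome",
    "contaminate",
    "detect_outliers",
    "adjusted_r",
    "remove_outliers",
    "clean_with_classification",
    "percent_bias",
]

MAD_SCALE = 1.4826  # Gaussian consistency constant
DEFAULT_THRESHOLD = 5.0


@dataclass(frozen=True)
class ContaminationSpec:
    """Spike injection: fraction of samples and amplitude multiplier."""

    proportion: float = 0.01
    amplitude_factor: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.proportion < 0.5:
            raise ValueError("proportion must lie in ]0, 0.5[")
        if self.amplitude_factor < 0:
            raise ValueError("amplitude_factor must be >= 0")


@dataclass(frozen=True)
class OutlierReport:
    flagged_indices: np.ndarray  # 0-based, sorted, unique
    threshold_multiplier: float
    scaled_mad: float  # signal units
    sd_ratio: float  # SD(unflagged)/SD(all), in ]0, 1]


@dataclass(frozen=True)
class CleaningOutcome:
    cleaned_values: np.ndarray
    method: str  # adjust_r | remove | classify_remove
    adjusted_r: float | None
    removed_count: int
    class_label: str | None


def contaminate(x: np.ndarray, spec: ContaminationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Perturb ceil(proportion*N) distinct samples with scaled Gaussian spikes.

    Each chosen sample gets ``z * amplitude_factor * (max(x) - min(x))``
    added, z iid standard normal; the range is computed on the input as
    given. Returns the contaminated copy and the sorted perturbed indices.
    """
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(spec.seed)
    k = math.ceil(spec.proportion * len(x))
    idx = np.sort(rng.choice(len(x), size=k, replace=False))
    z = rng.standard_normal(k)
    out = x.copy()
    out[idx] += z * spec.amplitude_factor * (x.max() - x.min())
    return out, idx


def detect_outliers(x: np.ndarray, threshold_multiplier: float = DEFAULT_THRESHOLD) -> OutlierReport:
    """Flag samples farther than threshold * scaled MAD from the median.

    scaled MAD = 1.4826 * median(|x - median(x)|). A zero scaled MAD (over
    half the values identical) flags nothing, with a warning.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    dev = np.abs(x - med)
    smad = MAD_SCALE * np.median(dev)
    if smad == 0:
        warnings.warn("scaled MAD is zero; no outliers flagged", stacklevel=2)
        flags = np.empty(0, dtype=int)
    else:
        flags = np.flatnonzero(dev > threshold_multiplier * smad)
    if len(flags) == 0 or len(flags) == len(x):
        sd_ratio = 1.0
    else:
        keep = np.delete(x, flags)
        sd_all = x.std()
        sd_ratio = float(keep.std() / sd_all) if sd_all > 0 else 1.0
    return OutlierReport(
        flagged_indices=flags,
        threshold_multiplier=float(threshold_multiplier),
        scaled_mad=float(smad),
        sd_ratio=sd_ratio,
    )


def adjusted_r(r0: float, report: OutlierReport) -> float:
    """Shrink the SampEn radius by the SD ratio without/with outliers."""
    return r0 * report.sd_ratio


def remove_outliers(x: np.ndarray, report: OutlierReport) -> np.ndarray:
    """Drop flagged positions and concatenate the remainder (no gap fill)."""
    x = np.asarray(x, dtype=float)
    if len(report.flagged_indices) == 0:
        return x.copy()
    return np.delete(x, report.flagged_indices)


def _increment_flags_to_positions(flags: np.ndarray) -> np.ndarray:
    """Map flagged increments to original sample positions.

    Increment j = x_j - x_{j-1} flags position j (the difference array
    index i corresponds to j = i + 1). An additive spike at position p
    flags increments p and p+1, so adjacent flag pairs {j, j+1} merge to
    the single position j; isolated flags map to their own position.
    """
    positions = flags + 1
    kept: list[int] = []
    i = 0
    while i < len(positions):
        kept.append(int(positions[i]))
        if i + 1 < len(positions) and positions[i + 1] == positions[i] + 1:
            i += 2  # adjacent pair produced by one spike
        else:
            i += 1
    return np.asarray(kept, dtype=int)


def clean_with_classification(
    x: np.ndarray, threshold_multiplier: float = DEFAULT_THRESHOLD
) -> tuple[CleaningOutcome, OutlierReport]:
    """Classification-guided outlier removal.

    Stationary series: detect and remove on the raw values. Nonstationary
    series: detect on the first difference, map flagged increments back to
    sample positions, and remove those samples from the original
    (undifferenced) series — differences are never re-integrated.

    Classification runs on a spike-suppressed copy (increment-based
    detection and removal), not on the contaminated series itself: spikes
    add a white-noise floor to the spectrum that pulls the bounded Whittle
    fit away from the stationarity boundary, so classifying the raw
    contaminated record mislabels strongly persistent fBm as stationary.
    """
    x = np.asarray(x, dtype=float)
    inc_report = detect_outliers(difference_series(x), threshold_multiplier)
    positions = _increment_flags_to_positions(inc_report.flagged_indices)
    precleaned = np.delete(x, positions) if len(positions) else x
    fit = classify_and_estimate(precleaned)
    if fit.class_label == STATIONARY:
        report = detect_outliers(x, threshold_multiplier)
        cleaned = remove_outliers(x, report)
        label = STATIONARY
    else:
        report = inc_report
        cleaned = np.delete(x, positions) if len(positions) else x.copy()
        label = NONSTATIONARY
    outcome = CleaningOutcome(
        cleaned_values=cleaned,
        method="classify_remove",
        adjusted_r=None,
        removed_count=len(x) - len(cleaned),
        class_label=label,
    )
    return outcome, report


def percent_bias(estimate: float, baseline: float) -> float:
    """100 * (estimate - baseline) / baseline."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    return 100.0 * (estimate - baseline) / baseline
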