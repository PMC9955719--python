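"""Configurable reruns of the simulation studies.

Each study simulates fGn/fBm datasets over a grid of expected scaling
exponents alpha and lengths N, applies the estimators/remedies, and returns
one tidy row per (replicate x condition) plus a summary table. Per-row
seeds derive deterministically from the master seed so any single replicate
can be re-run in isolation.

Studies
-------
estimation      alpha recovery by ARFIMA-Whittle and DFA (bias/SD grids)
classification  proportion of replicates labeled nonstationary (coarse grid)
classification_fine  the same on a 0.01-step grid around the 1/f boundary
outlier         percent bias of SampEn under contamination and remedies
discrimination  SampEn mean/SD per (alpha, N) with alpha-hat scatter
normalization   raw vs bound-normalized SampEn, including long records
sweep           SampEn summaries over grids of m, r and tau
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contamination import (
    ContaminationSpec,
    adjusted_r,
    clean_with_classification,
    contaminate,
    detect_outliers,
    percent_bias,
    remove_outliers,
)
from .dfa import dfa_alpha, default_k
from .sampen import SampEnParams, normalize_sampen, sampen
from .simulate import NONSTATIONARY, ArfimaSpec, child_seed, simulate_fgn
from .whittle import classify_and_estimate

__all__ = [
    "DEFAULT_ALPHAS",
    "FINE_ALPHAS",
    "StudyConfig",
    "spec_for_alpha",
    "run_estimation_study",
    "summarize_estimation",
    "run_classification_study",
    "summarize_classification",
    "run_outlier_study",
    "summarize_outlier",
    "run_discrimination_study",
    "summarize_discrimination",
    "run_normalization_study",
    "summarize_normalization",
    "run_sweep",
    "summarize_sweep",
    "run_study",
]

# Table-1 grid: 0.1..0.9 stationary, 0.99 at the boundary, 1.1..1.9 nonstationary
DEFAULT_ALPHAS: tuple[float, ...] = tuple(
    round(a, 2) for a in [*np.arange(0.1, 1.0, 0.1), 0.99, *np.arange(1.1, 2.0, 0.1)]
)
# fine grid around the 1/f boundary; alpha = 1.0 itself is not representable
FINE_ALPHAS: tuple[float, ...] = tuple(
    round(a, 2) for a in np.arange(0.71, 1.295, 0.01) if abs(a - 1.0) > 1e-9
)
DEFAULT_LENGTHS: tuple[int, ...] = (250, 500, 1000)
OUTLIER_CONDITIONS: tuple[str, ...] = ("none", "adjust_r", "remove", "classify_remove")

STUDY_KINDS = (
    "estimation",
    "classification",
    "classification_fine",
    "outlier",
    "discrimination",
    "normalization",
    "sweep",
)


def spec_for_alpha(alpha: float, n: int, seed: int) -> ArfimaSpec:
    """Simulation spec for an expected scaling exponent.

    alpha < 1 is a stationary fGn with d = alpha - 0.5; alpha > 1 is an fBm
    built by integrating a fGn with d = alpha - 1.5. alpha = 1 is not
    representable (d would hit the stationarity bound).
    """
    if not 0 < alpha < 2 or abs(alpha - 1.0) < 1e-9:
        raise ValueError(f"alpha must lie in ]0, 2[ excluding 1, got {alpha}")
    if alpha < 1:
        return ArfimaSpec(d=alpha - 0.5, n=n, seed=seed, integrate=False)
    return ArfimaSpec(d=alpha - 1.5, n=n, seed=seed, integrate=True)


@dataclass
class StudyConfig:
    """Configuration shared by all studies; unused fields are ignored."""

    study_kind: str = "estimation"
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    lengths: tuple[int, ...] = DEFAULT_LENGTHS
    replicates: int = 100
    sampen_params: SampEnParams = field(default_factory=SampEnParams)
    contamination: ContaminationSpec = field(default_factory=ContaminationSpec)
    conditions: tuple[str, ...] = OUTLIER_CONDITIONS
    ms: tuple[int, ...] = (1, 2, 3)
    rs: tuple[float, ...] = (0.1, 0.15, 0.2, 0.25, 0.3, 0.35)
    taus: tuple[int, ...] = (1, 2, 3)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.study_kind not in STUDY_KINDS:
            raise ValueError(f"unknown study_kind {self.study_kind!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for a in self.alphas:
            if not 0 < a < 2 or abs(a - 1.0) < 1e-9:
                raise ValueError(f"alpha {a} outside ]0, 2[ \\ {{1}}")
        if self.study_kind == "classification_fine" and self.alphas == DEFAULT_ALPHAS:
            self.alphas = FINE_ALPHAS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sampen_params" in raw:
            raw["sampen_params"] = SampEnParams(**raw["sampen_params"])
        if "contamination" in raw:
            raw["contamination"] = ContaminationSpec(**raw["contamination"])
        for key in ("alphas", "lengths", "conditions", "ms", "rs", "taus"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _grid(cfg: StudyConfig):
    """Yield (alpha, n, replicate, seed, key) with deterministic per-row seeds.

    key is the integer index tuple the seed was derived from, so dependent
    streams (e.g. contamination noise) can branch off it reproducibly.
    """
    for ai, alpha in enumerate(cfg.alphas):
        for ni, n in enumerate(cfg.lengths):
            for rep in range(cfg.replicates):
                yield alpha, n, rep, child_seed(cfg.master_seed, ai, ni, rep), (ai, ni, rep)


# ---------------------------------------------------------------------------
# estimation (Whittle vs DFA alpha recovery)


def run_estimation_study(cfg: StudyConfig) -> pd.DataFrame:
    rows = []
    for alpha, n, rep, seed, key in _grid(cfg):
        sim = simulate_fgn(spec_for_alpha(alpha, n, seed))
        fit = classify_and_estimate(sim.values)
        rows.append(
            dict(study_kind="estimation", alpha_expected=alpha, N=n, replicate=rep,
                 seed=seed, method="arfima", alpha_hat=fit.alpha_hat,
                 class_label=fit.class_label, converged=fit.converged)
        )
        dfa = dfa_alpha(sim.values, n_min=10, n_max=n // 4, k=default_k(n))
        rows.append(
            dict(study_kind="estimation", alpha_expected=alpha, N=n, replicate=rep,
                 seed=seed, method="dfa", alpha_hat=dfa.alpha_hat,
                 class_label=None, converged=True)
        )
    return pd.DataFrame(rows)


def summarize_estimation(rows: pd.DataFrame) -> pd.DataFrame:
    g = rows.groupby(["alpha_expected", "N", "method"], as_index=False)["alpha_hat"]
    out = g.agg(mean="mean", sd="std")
    out["bias"] = out["mean"] - out["alpha_expected"]
    return out


# ---------------------------------------------------------------------------
# classification


def run_classification_study(cfg: StudyConfig) -> pd.DataFrame:
    rows = []
    kind = cfg.study_kind if cfg.study_kind.startswith("classification") else "classification"
    for alpha, n, rep, seed, key in _grid(cfg):
        sim = simulate_fgn(spec_for_alpha(alpha, n, seed))
        fit = classify_and_estimate(sim.values)
        rows.append(
            dict(study_kind=kind, alpha_expected=alpha, N=n, replicate=rep, seed=seed,
                 alpha_hat=fit.alpha_hat, class_label=fit.class_label)
        )
    return pd.DataFrame(rows)


def summarize_classification(rows: pd.DataFrame) -> pd.DataFrame:
    rows = rows.assign(nonstationary=rows["class_label"] == NONSTATIONARY)
    out = rows.groupby(["alpha_expected", "N"], as_index=False)["nonstationary"].mean()
    out = out.rename(columns={"nonstationary": "prop_nonstationary"})
    out["error_rate"] = np.where(
        out["alpha_expected"] < 1.0,
        out["prop_nonstationary"],
        1.0 - out["prop_nonstationary"],
    )
    return out


# ---------------------------------------------------------------------------
# outlier / cleaning


def run_outlier_study(cfg: StudyConfig) -> pd.DataFrame:
    """Percent bias of SampEn under contamination, per remedy condition.

    Baseline = SampEn of the same realization before contamination; the
    contaminated series keeps its inflated SD (the bias mechanism), and
    each condition recomputes SampEn after its remedy.
    """
    params = cfg.sampen_params
    rows = []
    for alpha, n, rep, seed, key in _grid(cfg):
        sim = simulate_fgn(spec_for_alpha(alpha, n, seed))
        base = sampen(sim.values, params)
        cspec = ContaminationSpec(
            proportion=cfg.contamination.proportion,
            amplitude_factor=cfg.contamination.amplitude_factor,
            seed=child_seed(cfg.master_seed, *key, 1),
        )
        xc, _ = contaminate(sim.values, cspec)
        report = detect_outliers(xc)
        for cond in cfg.conditions:
            if cond == "none":
                res = sampen(xc, params)
            elif cond == "adjust_r":
                r_adj = adjusted_r(params.r, report)
                res = sampen(xc, SampEnParams(m=params.m, r=r_adj, tau=params.tau))
            elif cond == "remove":
                res = sampen(remove_outliers(xc, report), params)
            elif cond == "classify_remove":
                outcome, _ = clean_with_classification(xc)
                res = sampen(outcome.cleaned_values, params)
            else:
                raise ValueError(f"unknown condition {cond!r}")
            pb = (
                percent_bias(res.value, base.value)
                if math.isfinite(res.value) and math.isfinite(base.value)
                else math.nan
            )
            rows.append(
                dict(study_kind="outlier", alpha_expected=alpha, N=n, replicate=rep,
                     seed=seed, condition=cond, sampen=res.value,
                     sampen_baseline=base.value, percent_bias=pb)
            )
    return pd.DataFrame(rows)


def summarize_outlier(rows: pd.DataFrame) -> pd.DataFrame:
    g = rows.groupby(["alpha_expected", "N", "condition"], as_index=False)
    out = g.agg(
        mean_percent_bias=("percent_bias", "mean"),
        sd_percent_bias=("percent_bias", "std"),
        n_defined=("percent_bias", "count"),
        n_total=("percent_bias", "size"),
    )
    out["n_undefined"] = out["n_total"] - out["n_defined"]
    return out


# ---------------------------------------------------------------------------
# discrimination (SampEn vs alpha, many-to-one)


def run_discrimination_study(cfg: StudyConfig) -> pd.DataFrame:
    rows = []
    for alpha, n, rep, seed, key in _grid(cfg):
        sim = simulate_fgn(spec_for_alpha(alpha, n, seed))
        fit = classify_and_estimate(sim.values)
        res = sampen(sim.values, cfg.sampen_params)
        rows.append(
            dict(study_kind="discrimination", alpha_expected=alpha, N=n, replicate=rep,
                 seed=seed, alpha_hat=fit.alpha_hat, class_label=fit.class_label,
                 sampen=res.value)
        )
    return pd.DataFrame(rows)


def summarize_discrimination(rows: pd.DataFrame) -> pd.DataFrame:
    return rows.groupby(["alpha_expected", "N"], as_index=False).agg(
        sampen_mean=("sampen", "mean"),
        sampen_sd=("sampen", "std"),
        alpha_hat_mean=("alpha_hat", "mean"),
        alpha_hat_sd=("alpha_hat", "std"),
        n_defined=("sampen", "count"),
        n_total=("sampen", "size"),
    )


# ---------------------------------------------------------------------------
# normalization (raw vs bound-normalized SampEn over lengths)


def run_normalization_study(cfg: StudyConfig) -> pd.DataFrame:
    params = cfg.sampen_params
    rows = []
    for alpha, n, rep, seed, key in _grid(cfg):
        sim = simulate_fgn(spec_for_alpha(alpha, n, seed))
        res = sampen(sim.values, params)
        rows.append(
            dict(study_kind="normalization", alpha_expected=alpha, N=n, replicate=rep,
                 seed=seed, sampen=res.value, sampen_normalized=res.normalized)
        )
    return pd.DataFrame(rows)


def summarize_normalization(rows: pd.DataFrame) -> pd.DataFrame:
    return rows.groupby(["alpha_expected", "N"], as_index=False).agg(
        sampen_mean=("sampen", "mean"),
        sampen_sd=("sampen", "std"),
        normalized_mean=("sampen_normalized", "mean"),
        normalized_sd=("sampen_normalized", "std"),
        n_defined=("sampen", "count"),
        n_total=("sampen", "size"),
    )


# ---------------------------------------------------------------------------
# hyperparameter sweep


def run_sweep(cfg: StudyConfig) -> pd.DataFrame:
    base = cfg.sampen_params
    rows = []
    for alpha, n, rep, seed, key in _grid(cfg):
        sim = simulate_fgn(spec_for_alpha(alpha, n, seed))
        for m in cfg.ms:
            res = sampen(sim.values, SampEnParams(m=m, r=base.r, tau=base.tau))
            rows.append(dict(alpha_expected=alpha, N=n, replicate=rep, seed=seed,
                             swept="m", m=m, r=base.r, tau=base.tau, sampen=res.value))
        for r in cfg.rs:
            res = sampen(sim.values, SampEnParams(m=base.m, r=r, tau=base.tau))
            rows.append(dict(alpha_expected=alpha, N=n, replicate=rep, seed=seed,
                             swept="r", m=base.m, r=r, tau=base.tau, sampen=res.value))
        for tau in cfg.taus:
            res = sampen(sim.values, SampEnParams(m=base.m, r=base.r, tau=tau))
            rows.append(dict(alpha_expected=alpha, N=n, replicate=rep, seed=seed,
                             swept="tau", m=base.m, r=base.r, tau=tau, sampen=res.value))
    out = pd.DataFrame(rows)
    out.insert(0, "study_kind", "sweep")
    return out


def summarize_sweep(rows: pd.DataFrame) -> pd.DataFrame:
    return rows.groupby(["alpha_expected", "N", "swept", "m", "r", "tau"], as_index=False).agg(
        sampen_mean=("sampen", "mean"),
        sampen_sd=("sampen", "std"),
        n_defined=("sampen", "count"),
        n_total=("sampen", "size"),
    )


_RUNNERS = {
    "estimation": (run_estimation_study, summarize_estimation),
    "classification": (run_classification_study, summarize_classification),
    "classification_fine": (run_classification_study, summarize_classification),
    "outlier": (run_outlier_study, summarize_outlier),
    "discrimination": (run_discrimination_study, summarize_discrimination),
    "normalization": (run_normalization_study, summarize_normalization),
    "sweep": (run_sweep, summarize_sweep),
}


def run_study(cfg: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run a study; returns (per-replicate rows, summary table)."""
    runner, summarizer = _RUNNERS[cfg.study_kind]
    rows = runner(cfg)
    return rows, summarizer(rows)
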