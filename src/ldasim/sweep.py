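"""Factorial parameter sweeps with a pluggable detector.

A sweep simulates B repetitions of every cell in a parameter grid
(e.g. sigma x n-per-group x q x trend), hands each simulated dataset to a
detector, and scores the detector with the metrics module. The detector is
any callable ``(SimulatedDataset) -> DetectorResult``; the method under
study is deliberately external to this package, so two reference detectors
are shipped for exercising the harness:

* ``oracle`` — returns the true trend and detects exactly when the truth
  is differential; the harness self-test (sensitivity and specificity 1).
* ``ttest`` — per-timepoint Welch two-sample t-test on the observed
  outcome with Bonferroni correction across timepoints; a deliberately
  simple baseline, not a recommended analysis method.

Repetition substreams are derived from the sweep seed keyed by (cell,
repetition), so results are reproducible and independent of execution
order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .covariance import CovarianceSpec
from .metrics import (
    DetectionOutcome,
    TrendComparison,
    cosine_similarity,
    euclidean_distance,
    normalized_euclidean,
    sensitivity,
    specificity,
)
from .simulate import SimulatedDataset, SimulationDesign, simulate_feature
from .trends import TrendSpec, evaluate_trend

__all__ = [
    "DetectorResult",
    "SweepConfig",
    "register_detector",
    "get_detector",
    "oracle_detector",
    "ttest_detector",
    "run_sweep",
    "summarize_sweep",
]


@dataclass(frozen=True)
class DetectorResult:
    """What a detector reports for one simulated dataset.

    ``f_hat`` is the estimated differential-abundance trend at the
    design's equidistant timepoint grid, or None when the method returned
    no estimate (an explicit no-estimate marker, never an exception).
    """

    detected_any: bool
    f_hat: np.ndarray | None = None


Detector = Callable[[SimulatedDataset], DetectorResult]

_DETECTORS: dict[str, Detector] = {}


def register_detector(name: str):
    """Decorator registering a detector plug-in under ``name``."""

    def deco(fn: Detector) -> Detector:
        _DETECTORS[name] = fn
        return fn

    return deco


def get_detector(name: str) -> Detector:
    try:
        return _DETECTORS[name]
    except KeyError:
        raise KeyError(
            f"no detector named {name!r}; available: {sorted(_DETECTORS)}"
        ) from None


def _design_grid(design: SimulationDesign) -> np.ndarray:
    return np.linspace(design.t_interval[0], design.t_interval[1], design.num_timepoints)


def _true_trend(design: SimulationDesign) -> np.ndarray:
    grid = _design_grid(design)
    return evaluate_trend(design.trend, grid, t_end=design.t_interval[1], validate=False)


@register_detector("oracle")
def oracle_detector(dataset: SimulatedDataset) -> DetectorResult:
    """Perfect detector: returns the generating trend itself.

    Detects differential abundance iff the true trend is nonzero anywhere
    on the design grid; used as the harness self-test.
    """
    f = _true_trend(dataset.design)
    return DetectorResult(detected_any=bool(np.any(f != 0.0)), f_hat=f)


@register_detector("ttest")
def ttest_detector(dataset: SimulatedDataset, alpha: float = 0.05) -> DetectorResult:
    """Per-timepoint Welch t-test with any-timepoint Bonferroni detection.

    Groups observations by their nearest design-grid timepoint (exact in
    equidistant mode), tests treatment vs control on the observed outcome
    at each, and declares detection if any Bonferroni-adjusted p-value is
    below ``alpha``. The estimate is the per-timepoint difference of group
    means. Returns a no-estimate marker when any timepoint has fewer than
    two observations per group.
    """
    rec = dataset.records
    grid = _design_grid(dataset.design)
    obs = rec["Y_obs"].to_numpy()
    keep = ~np.isnan(obs)
    t = rec["time"].to_numpy()[keep]
    y = obs[keep]
    is_treat = (rec["group"].to_numpy()[keep]) == "Treatment"
    bins = np.argmin(np.abs(t[:, None] - grid[None, :]), axis=1)

    f_hat = np.empty(grid.size)
    pvals = np.empty(grid.size)
    for j in range(grid.size):
        yj = y[bins == j]
        tj = is_treat[bins == j]
        a, b = yj[tj], yj[~tj]
        if a.size < 2 or b.size < 2:
            return DetectorResult(detected_any=False, f_hat=None)
        f_hat[j] = a.mean() - b.mean()
        pvals[j] = stats.ttest_ind(a, b, equal_var=False).pvalue
    detected = bool(np.any(pvals * grid.size < alpha))
    return DetectorResult(detected_any=detected, f_hat=f_hat)


@dataclass(frozen=True)
class SweepConfig:
    """A factorial sweep: grids of parameter values x B repetitions.

    ``grids`` maps parameter names to value lists. Recognized names:
    ``sigma``, ``rho``, ``structure``, ``n_per_group``, ``n_control``,
    ``n_treat``, ``q`` (timepoints per subject), ``missing_pct``,
    ``missing_per_subject``, ``control_mean``, and ``trend`` (a
    :class:`TrendSpec` or its mapping form). Unlisted parameters come from
    ``base_design``.
    """

    grids: dict[str, list]
    repetitions: int
    base_design: SimulationDesign
    detector: str = "oracle"
    seed: int = 0

    def validate(self) -> list[str]:
        v = []
        if self.repetitions < 1:
            v.append("repetitions must be >= 1")
        if not self.grids or any(len(vals) == 0 for vals in self.grids.values()):
            v.append("grids must be non-empty")
        unknown = set(self.grids) - set(_SETTERS)
        if unknown:
            v.append(f"unknown grid parameters: {sorted(unknown)}")
        if self.detector not in _DETECTORS:
            v.append(f"unknown detector {self.detector!r}")
        return v

    @property
    def n_settings(self) -> int:
        out = 1
        for vals in self.grids.values():
            out *= len(vals)
        return out

    @property
    def total_runs(self) -> int:
        return self.n_settings * self.repetitions


def _set_sigma(d, v):
    return replace(d, covariance=replace(d.covariance, sigma=float(v)))


def _set_rho(d, v):
    return replace(d, covariance=replace(d.covariance, rho=float(v)))


def _set_structure(d, v):
    return replace(d, covariance=replace(d.covariance, structure=str(v)))


def _set_trend(d, v):
    spec = v if isinstance(v, TrendSpec) else TrendSpec.from_dict(dict(v))
    return replace(d, trend=spec)


_SETTERS = {
    "sigma": _set_sigma,
    "rho": _set_rho,
    "structure": _set_structure,
    "trend": _set_trend,
    "n_per_group": lambda d, v: replace(d, n_control=int(v), n_treat=int(v)),
    "n_control": lambda d, v: replace(d, n_control=int(v)),
    "n_treat": lambda d, v: replace(d, n_treat=int(v)),
    "q": lambda d, v: replace(d, num_timepoints=int(v)),
    "missing_pct": lambda d, v: replace(d, missing_pct=float(v)),
    "missing_per_subject": lambda d, v: replace(d, missing_per_subject=int(v)),
    "control_mean": lambda d, v: replace(d, control_mean=float(v)),
}


def apply_setting(base: SimulationDesign, setting: dict) -> SimulationDesign:
    """Return the base design with one grid cell's values applied."""
    d = base
    for name, value in setting.items():
        d = _SETTERS[name](d, value)
    return d


def _setting_label(name: str, value) -> object:
    if name == "trend":
        spec = value if isinstance(value, TrendSpec) else TrendSpec.from_dict(dict(value))
        return spec.form if not spec.beta else f"{spec.form}{tuple(spec.beta)}"
    return value


def run_sweep(config: SweepConfig) -> pd.DataFrame:
    """Run every grid cell x repetition and score the detector.

    Returns a tidy table with one row per scheduled repetition: the grid
    values, the repetition index, whether the truth was differential,
    whether the detector fired, an estimate-missing flag (detector failure
    or explicit no-estimate), and the three continuous metrics (NaN when
    the estimate is missing or the truth is null, where direction metrics
    are undefined). Detector exceptions are recorded, not raised.
    """
    violations = config.validate()
    if violations:
        raise ValueError("invalid sweep config: " + "; ".join(violations))
    detector = get_detector(config.detector)
    names = list(config.grids)
    cells = list(itertools.product(*(config.grids[n] for n in names)))
    B = config.repetitions
    streams = np.random.SeedSequence(config.seed).spawn(len(cells) * B)

    rows = []
    for ci, cell in enumerate(cells):
        setting = dict(zip(names, cell))
        design = apply_setting(config.base_design, setting)
        f_true = _true_trend(design)
        truth_is_diff = bool(np.any(f_true != 0.0))
        labels = {n: _setting_label(n, v) for n, v in setting.items()}
        for rep in range(B):
            rng = np.random.default_rng(streams[ci * B + rep])
            ds = simulate_feature(design, rng)
            try:
                res = detector(ds)
            except Exception:
                res = DetectorResult(detected_any=False, f_hat=None)
            missing = res.f_hat is None
            cos = euc = neuc = np.nan
            if not missing and truth_is_diff:
                cmp_ = TrendComparison(f_hat=res.f_hat, f_true=f_true)
                if np.linalg.norm(res.f_hat) > 0:
                    cos = cosine_similarity(cmp_)
                    neuc = normalized_euclidean(cmp_)
                euc = euclidean_distance(cmp_)
            rows.append(
                {
                    **labels,
                    "repetition": rep,
                    "truth_is_diff": truth_is_diff,
                    "detected": bool(res.detected_any) and not missing,
                    "estimate_missing": missing,
                    "cosine": cos,
                    "euclidean": euc,
                    "norm_euclidean": neuc,
                }
            )
    return pd.DataFrame(rows)


def summarize_sweep(results: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Aggregate sweep results into a per-group summary table.

    Groups by ``by`` (default: the trend column if present, else all grid
    columns) and reports, per group: the detection rate — sensitivity for
    differential truths, specificity for null truths — mean continuous
    metrics over non-missing estimates, total repetitions, and the count
    of non-missing estimates.
    """
    if results.empty:
        raise ValueError("results table is empty")
    meta = {
        "repetition",
        "truth_is_diff",
        "detected",
        "estimate_missing",
        "cosine",
        "euclidean",
        "norm_euclidean",
    }
    if by is None:
        by = ["trend"] if "trend" in results.columns else [
            c for c in results.columns if c not in meta
        ]
    out = []
    for key, g in results.groupby(by, sort=False, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        outcomes = [
            DetectionOutcome(
                detected_any=bool(r.detected),
                truth_is_diff=bool(r.truth_is_diff),
                estimate_missing=bool(r.estimate_missing),
            )
            for r in g.itertuples()
        ]
        is_diff = bool(g["truth_is_diff"].iloc[0])
        rate = sensitivity(outcomes) if is_diff else specificity(outcomes)
        ok = g[~g["estimate_missing"]]
        out.append(
            {
                **dict(zip(by, key)),
                "metric": "sensitivity" if is_diff else "specificity",
                "rate": rate.value,
                "mean_cosine": float(ok["cosine"].mean()),
                "mean_euclidean": float(ok["euclidean"].mean()),
                "mean_norm_euclidean": float(ok["norm_euclidean"].mean()),
                "repetitions": int(len(g)),
                "non_missing_estimates": int(len(ok)),
            }
        )
    return pd.DataFrame(out)
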