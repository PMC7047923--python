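"""Performance metrics for trend-recovery methods.

Given an estimated trend ``f_hat`` and the true trend ``f`` evaluated at a
common set of timepoints, three continuous metrics quantify how close the
estimate is to the truth:

* cosine similarity, in [-1, 1] — comparable across grids of different
  length but not very discriminant near the boundaries;
* Euclidean distance, in [0, inf) — the grid length is highly influential,
  so values are only comparable at a fixed number of timepoints;
* normalized Euclidean distance, in [0, 2] — distance between the two
  unit vectors, comparable across grid lengths.

Binary detection is summarized over B simulation repetitions: sensitivity
is the fraction of repetitions with truly differential trends on which any
differential abundance was detected; specificity is the fraction of truly
null repetitions on which none was. Repetitions where the estimator
returned no estimate are excluded from denominators and counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike

__all__ = [
    "TrendComparison",
    "DetectionOutcome",
    "UndefinedMetricError",
    "cosine_similarity",
    "euclidean_distance",
    "normalized_euclidean",
    "sensitivity",
    "specificity",
    "BinaryRate",
]


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given input (zero-norm vector or
    empty eligible set)."""


@dataclass(frozen=True)
class TrendComparison:
    """An estimated and a true trend evaluated at the same timepoints."""

    f_hat: np.ndarray
    f_true: np.ndarray

    def __post_init__(self):
        fh = np.asarray(self.f_hat, dtype=float)
        ft = np.asarray(self.f_true, dtype=float)
        if fh.ndim != 1 or ft.ndim != 1 or fh.size == 0:
            raise ValueError("f_hat and f_true must be non-empty 1-D vectors")
        if fh.shape != ft.shape:
            raise ValueError(f"length mismatch: {fh.size} vs {ft.size}")
        object.__setattr__(self, "f_hat", fh)
        object.__setattr__(self, "f_true", ft)


@dataclass(frozen=True)
class DetectionOutcome:
    """One repetition's detection result against the known truth."""

    detected_any: bool
    truth_is_diff: bool
    estimate_missing: bool = False


@dataclass(frozen=True)
class BinaryRate:
    """A fraction with its explicit numerator and denominator."""

    value: float
    numerator: int
    denominator: int


def _nonzero_norms(c: TrendComparison) -> tuple[float, float]:
    nh = float(np.linalg.norm(c.f_hat))
    nt = float(np.linalg.norm(c.f_true))
    if nh == 0.0 or nt == 0.0:
        raise UndefinedMetricError(
            "cosine/normalized metrics are undefined for a zero-norm trend "
            "(e.g. a truly null form); use detection rates instead"
        )
    return nh, nt


def cosine_similarity(c: TrendComparison) -> float:
    """dot(f_hat, f_true) / (||f_hat|| * ||f_true||), in [-1, 1]."""
    nh, nt = _nonzero_norms(c)
    return float(np.dot(c.f_hat, c.f_true) / (nh * nt))


def euclidean_distance(c: TrendComparison) -> float:
    """||f_hat - f_true||_2 (not comparable across grid lengths)."""
    return float(np.linalg.norm(c.f_hat - c.f_true))


def normalized_euclidean(c: TrendComparison) -> float:
    """Distance between unit vectors, in [0, 2].

    Satisfies ``normalized_euclidean**2 == 2 * (1 - cosine_similarity)``.
    """
    nh, nt = _nonzero_norms(c)
    return float(np.linalg.norm(c.f_hat / nh - c.f_true / nt))


def _rate(outcomes, want_diff: bool, count_detected: bool) -> BinaryRate:
    eligible = [
        o for o in outcomes if o.truth_is_diff == want_diff and not o.estimate_missing
    ]
    if not eligible:
        kind = "sensitivity" if want_diff else "specificity"
        raise UndefinedMetricError(
            f"{kind} undefined: no eligible repetitions with a non-missing estimate"
        )
    if count_detected:
        num = sum(o.detected_any for o in eligible)
    else:
        num = sum(not o.detected_any for o in eligible)
    return BinaryRate(value=num / len(eligible), numerator=num, denominator=len(eligible))


def sensitivity(outcomes: list[DetectionOutcome]) -> BinaryRate:
    """Fraction of truly differential repetitions on which any
    differential abundance was detected."""
    return _rate(outcomes, want_diff=True, count_detected=True)


def specificity(outcomes: list[DetectionOutcome]) -> BinaryRate:
    """Fraction of truly null repetitions on which no differential
    abundance was detected at any timepoint."""
    return _rate(outcomes, want_diff=False, count_detected=False)
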