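"""Within-subject covariance structures.

Each subject's repeated measurements share a q×q covariance
``Sigma_i = sigma^2 * Omega(rho)`` where ``Omega`` is one of

* ``ar1`` — first-order autoregressive, entry (j, j') = rho^|j-j'|
  (indexed by measurement order, not elapsed time);
* ``compound`` — exchangeable, all off-diagonal correlations equal rho;
* ``independent`` — identity correlation.

Subjects are mutually independent, so the full N×N covariance is block
diagonal, ``Sigma = bdiag(Sigma_1, ..., Sigma_n)``. The blocks are the
canonical representation here; the dense matrix is assembled only on
request (it is O(N^2) memory and all cross-subject entries are zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
from numpy.typing import NDArray

__all__ = [
    "COVARIANCE_STRUCTURES",
    "CovarianceSpec",
    "CovarianceValidationError",
    "subject_covariance",
    "block_covariance",
    "BlockCovariance",
]

COVARIANCE_STRUCTURES = ("ar1", "compound", "independent")


class CovarianceValidationError(ValueError):
    pass


@dataclass(frozen=True)
class CovarianceSpec:
    """Global covariance parameters shared by all subjects.

    Parameters
    ----------
    structure
        One of ``ar1``, ``compound``, ``independent``.
    sigma
        Standard deviation (abundance units), > 0.
    rho
        Correlation parameter; (−1, 1) for ``ar1``, [0, 1) for ``compound``
        (negative exchangeable correlation is q-dependent and rejected),
        ignored for ``independent``.
    """

    structure: str
    sigma: float = 1.0
    rho: float = 0.0

    def validate(self) -> list[str]:
        v = []
        if self.structure not in COVARIANCE_STRUCTURES:
            v.append(
                f"unknown correlation structure {self.structure!r}; "
                f"valid: {', '.join(COVARIANCE_STRUCTURES)}"
            )
            return v
        if not self.sigma > 0:
            v.append(f"sigma must be positive, got {self.sigma}")
        if self.structure == "ar1" and not (-1 < self.rho < 1):
            v.append(f"ar1 requires rho in (-1, 1), got {self.rho}")
        if self.structure == "compound" and not (0 <= self.rho < 1):
            v.append(
                f"compound requires rho in [0, 1), got {self.rho} "
                "(negative exchangeable correlation is rejected)"
            )
        return v

    def to_dict(self) -> dict:
        return {"structure": self.structure, "sigma": self.sigma, "rho": self.rho}

    @classmethod
    def from_dict(cls, d: dict) -> "CovarianceSpec":
        return cls(
            structure=d["structure"],
            sigma=float(d.get("sigma", 1.0)),
            rho=float(d.get("rho", 0.0)),
        )


def _validated(spec: CovarianceSpec) -> CovarianceSpec:
    violations = spec.validate()
    if violations:
        raise CovarianceValidationError("; ".join(violations))
    return spec


def subject_covariance(spec: CovarianceSpec, q: int) -> NDArray[np.float64]:
    """Build one subject's q×q covariance matrix ``sigma^2 * Omega(rho)``."""
    _validated(spec)
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    var = spec.sigma**2
    if spec.structure == "independent":
        return var * np.eye(q)
    if spec.structure == "compound":
        omega = np.full((q, q), spec.rho)
        np.fill_diagonal(omega, 1.0)
        return var * omega
    # ar1: correlation decays geometrically with lag in measurement order
    lags = np.abs(np.subtract.outer(np.arange(q), np.arange(q)))
    return var * spec.rho**lags


@dataclass(frozen=True)
class BlockCovariance:
    """Block-diagonal covariance held as its per-subject blocks."""

    blocks: tuple[NDArray[np.float64], ...]

    @property
    def n_total(self) -> int:
        return sum(b.shape[0] for b in self.blocks)

    def dense(self) -> NDArray[np.float64]:
        """Assemble the full N×N matrix (use only at small N)."""
        return scipy.linalg.block_diag(*self.blocks)

    def cholesky_factors(self) -> list[NDArray[np.float64]]:
        """Lower Cholesky factor of each block; raises if any block is not PD."""
        return [np.linalg.cholesky(b) for b in self.blocks]


def block_covariance(spec: CovarianceSpec, q_per_subject: Sequence[int]) -> BlockCovariance:
    """Covariance for n independent subjects with ``q_i`` measurements each.

    Returns the per-subject blocks; cross-subject covariances are
    identically zero and never materialized.
    """
    _validated(spec)
    qs = [int(q) for q in q_per_subject]
    if not qs:
        raise ValueError("q_per_subject must be non-empty")
    if any(q < 1 for q in qs):
        raise ValueError("all subjects need at least one measurement")
    # identical q shares one block object; blocks are read-only by convention
    cache: dict[int, NDArray[np.float64]] = {}
    blocks = []
    for q in qs:
        if q not in cache:
            cache[q] = subject_covariance(spec, q)
        blocks.append(cache[q])
    return BlockCovariance(blocks=tuple(blocks))
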