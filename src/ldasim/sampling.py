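"""Draws from the (optionally left-truncated) multivariate normal.

Transformed microbiome abundances are non-negative, so the simulator draws
from ``Y ~ TN(mu, Sigma, a·1)`` — a multivariate normal restricted to all
coordinates above a left bound ``a`` (zero by default). Two regimes are
used, chosen per subject-block by the estimated acceptance probability
``p_acpt = P(Y > a·1)``:

* rejection sampling — redraw the whole block until every coordinate
  exceeds ``a``; exact, but infeasible when ``p_acpt`` is small;
* censoring with point imputation — when ``p_acpt`` falls at or below a
  threshold (default 0.1), draw once from the unconstrained normal and set
  coordinates below ``a`` to ``a``.

Because subject blocks are independent and the acceptance probability only
depends on a block's mean and covariance, ``p_acpt`` is estimated once per
distinct (mean-block, covariance-block) pair by a pilot Monte Carlo, and a
single mode is applied to every block sharing that pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "TruncationSpec",
    "estimate_acceptance",
    "sample_truncated_mvn",
    "RejectionCapExceeded",
]

logger = logging.getLogger(__name__)

#: hard cap on total redraw attempts per block in rejection mode
_MAX_REJECTION_ATTEMPTS = 100_000


class RejectionCapExceeded(RuntimeError):
    """Rejection sampling exhausted its attempt budget for one block."""


@dataclass(frozen=True)
class TruncationSpec:
    """Left-truncation settings.

    Parameters
    ----------
    enabled
        Impose the non-negativity (or ``a``-bounded) restriction.
    a
        Left-truncation value, abundance units. ``a = 0`` gives zero
        truncation.
    acceptance_threshold
        Blocks whose estimated acceptance probability is at or below this
        value fall back to censoring; in (0, 1].
    pilot_draws
        Unconstrained draws used for the Monte Carlo acceptance estimate.
    """

    enabled: bool = True
    a: float = 0.0
    acceptance_threshold: float = 0.1
    pilot_draws: int = 1000

    def validate(self) -> list[str]:
        v = []
        if not 0 < self.acceptance_threshold <= 1:
            v.append(
                f"acceptance_threshold must be in (0, 1], got {self.acceptance_threshold}"
            )
        if self.pilot_draws < 100:
            v.append(f"pilot_draws must be >= 100, got {self.pilot_draws}")
        return v

    def to_dict(self) -> dict:
        return {
            "enabled": self.enabled,
            "a": self.a,
            "acceptance_threshold": self.acceptance_threshold,
            "pilot_draws": self.pilot_draws,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruncationSpec":
        return cls(
            enabled=bool(d.get("enabled", True)),
            a=float(d.get("a", 0.0)),
            acceptance_threshold=float(d.get("acceptance_threshold", 0.1)),
            pilot_draws=int(d.get("pilot_draws", 1000)),
        )


def _chol(sigma_block: NDArray[np.float64]) -> NDArray[np.float64]:
    try:
        return np.linalg.cholesky(np.asarray(sigma_block, dtype=float))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"covariance block of shape {np.shape(sigma_block)} is not "
            f"positive-definite: {err}"
        ) from err


def _draw_blocks(
    mu: NDArray[np.float64],
    chol: NDArray[np.float64],
    n_draws: int,
    rng: np.random.Generator,
) -> NDArray[np.float64]:
    """(n_draws, q) unconstrained MVN draws via the Cholesky factor."""
    q = mu.shape[0]
    z = rng.standard_normal((n_draws, q))
    return mu + z @ chol.T


def estimate_acceptance(
    mu_block: NDArray[np.float64],
    sigma_block: NDArray[np.float64],
    a: float,
    pilot_draws: int,
    rng: np.random.Generator,
) -> float:
    """Monte Carlo estimate of ``P(all coordinates > a)`` for one block.

    Draws ``pilot_draws`` samples from the unconstrained ``N(mu, Sigma)``
    and returns the fraction with every coordinate above ``a``. The
    estimate carries the usual binomial Monte Carlo error.
    """
    mu = np.atleast_1d(np.asarray(mu_block, dtype=float))
    chol = _chol(sigma_block)
    draws = _draw_blocks(mu, chol, int(pilot_draws), rng)
    return float(np.mean(np.all(draws > a, axis=1)))


def _rejection_sample_block(
    mu: NDArray[np.float64],
    chol: NDArray[np.float64],
    a: float,
    rng: np.random.Generator,
) -> NDArray[np.float64]:
    attempts = 0
    batch = 1  # most blocks accept immediately; escalate only on misses
    while attempts < _MAX_REJECTION_ATTEMPTS:
        draws = _draw_blocks(mu, chol, batch, rng)
        ok = np.all(draws > a, axis=1)
        hit = np.flatnonzero(ok)
        if hit.size:
            return draws[hit[0]]
        attempts += batch
        batch = min(batch * 4, 1024)
    raise RejectionCapExceeded(
        f"rejection sampling exceeded {_MAX_REJECTION_ATTEMPTS} attempts for a "
        f"block with mean ~{float(np.mean(mu)):.3g}; the acceptance probability "
        "is too low — lower acceptance_threshold so the block is censored, or "
        "reconsider the design"
    )


def sample_truncated_mvn(
    mu_blocks: Sequence[NDArray[np.float64]],
    sigma_blocks: Sequence[NDArray[np.float64]],
    trunc: TruncationSpec,
    rng: np.random.Generator,
) -> tuple[NDArray[np.float64], list[str]]:
    """Sample the stacked outcome vector block by block.

    Parameters
    ----------
    mu_blocks, sigma_blocks
        Per-subject mean vectors and covariance matrices (equal length).
    trunc
        Truncation settings; when disabled, plain MVN draws are returned
        with every block flagged ``untruncated``.
    rng
        Seeded generator; identical seeds give bit-identical output.

    Returns
    -------
    y : ndarray
        Concatenated draws, length ``N = sum(q_i)``; all ``>= a`` when
        truncation is enabled.
    modes : list of str
        Per-block sampling mode: ``rejection``, ``censored`` or
        ``untruncated``.
    """
    violations = trunc.validate()
    if violations:
        raise ValueError("; ".join(violations))
    if len(mu_blocks) != len(sigma_blocks):
        raise ValueError(
            f"{len(mu_blocks)} mean blocks but {len(sigma_blocks)} covariance blocks"
        )

    mus = [np.atleast_1d(np.asarray(m, dtype=float)) for m in mu_blocks]
    chols: dict[int, NDArray[np.float64]] = {}

    def chol_for(i: int) -> NDArray[np.float64]:
        key = id(sigma_blocks[i])
        if key not in chols:
            chols[key] = _chol(sigma_blocks[i])
        return chols[key]

    if not trunc.enabled:
        out = [_draw_blocks(mus[i], chol_for(i), 1, rng)[0] for i in range(len(mus))]
        return np.concatenate(out), ["untruncated"] * len(mus)

    # one acceptance estimate (hence one mode) per distinct (mu, Sigma) pair
    mode_cache: dict[tuple[bytes, int], str] = {}
    pieces = []
    modes = []
    for i, mu in enumerate(mus):
        chol = chol_for(i)
        key = (mu.tobytes(), id(sigma_blocks[i]))
        if key not in mode_cache:
            p_acpt = estimate_acceptance(mu, sigma_blocks[i], trunc.a, trunc.pilot_draws, rng)
            mode_cache[key] = (
                "rejection" if p_acpt > trunc.acceptance_threshold else "censored"
            )
            logger.info(
                "block group (mean ~%.3g, q=%d): p_acpt ~ %.3f -> %s",
                float(np.mean(mu)), mu.size, p_acpt, mode_cache[key],
            )
        mode = mode_cache[key]
        if mode == "rejection":
            y = _rejection_sample_block(mu, chol, trunc.a, rng)
        else:
            y = _draw_blocks(mu, chol, 1, rng)[0]
            y = np.where(y < trunc.a, trunc.a, y)
        pieces.append(y)
        modes.append(mode)
    return np.concatenate(pieces), modes
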