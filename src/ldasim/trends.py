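"""Mean differential-abundance trend families.

The treatment-group mean at time ``t`` is ``mu_0 + f(t)``; this module
evaluates and validates ``f`` for every supported functional family:

* ``none`` — no differential abundance, ``f ≡ 0``.
* ``linear`` / ``quadratic`` / ``cubic`` — polynomial trends
  ``f(t) = Σ_k β_k t^k`` with p = 1, 2 or 3.
* ``oscillating_M`` / ``oscillating_W`` — piecewise-linear trends with three
  inflection points (IP1 < IP2 < IP3) rising/falling to a peak (or trough)
  value ``v = β0 + β1·IP1`` at IP1, crossing exactly zero at IP2, returning
  to ``v`` at IP3 and decaying back to zero at the end of the interval.
* ``L_up`` / ``L_down`` — "hockey stick" trends, flat in one region and
  linear in the complementary region, split at a single inflection point IP
  (for ``L_down`` implied by the coefficients, IP = −β0/β1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "TREND_FORMS",
    "TrendSpec",
    "TrendValidationError",
    "validate_trend",
    "evaluate_trend",
]

TREND_FORMS = (
    "none",
    "linear",
    "quadratic",
    "cubic",
    "oscillating_M",
    "oscillating_W",
    "L_up",
    "L_down",
)

#: coefficient-vector length required by each polynomial form
_POLY_NCOEF = {"linear": 2, "quadratic": 3, "cubic": 4}


class TrendValidationError(ValueError):
    """Raised when a trend specification violates its constraints.

    Carries the full list of violations in :attr:`violations`.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(violations))


@dataclass(frozen=True)
class TrendSpec:
    """Parameterization of the differential-abundance function ``f(t)``.

    Parameters
    ----------
    form
        One of :data:`TREND_FORMS`.
    beta
        Coefficient vector, in abundance units. Length 2/3/4 for
        linear/quadratic/cubic; ``(β0, β1)`` for oscillating forms;
        a single slope ``(β1,)`` for ``L_up``; ``(β0, β1)`` for ``L_down``.
    ip
        Inflection points, in time units. Three sorted values for
        oscillating forms, one value for ``L_up``, empty otherwise
        (``L_down`` implies IP = −β0/β1).
    """

    form: str
    beta: tuple[float, ...] = ()
    ip: tuple[float, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "beta", tuple(float(b) for b in np.atleast_1d(self.beta)))
        object.__setattr__(self, "ip", tuple(float(p) for p in np.atleast_1d(self.ip)))

    @property
    def implied_ip(self) -> float | None:
        """Inflection point for hockey-stick forms (−β0/β1 for L_down)."""
        if self.form == "L_down" and len(self.beta) == 2 and self.beta[1] != 0:
            return -self.beta[0] / self.beta[1]
        if self.form == "L_up" and len(self.ip) == 1:
            return self.ip[0]
        return None

    def to_dict(self) -> dict:
        return {"form": self.form, "beta": list(self.beta), "ip": list(self.ip)}

    @classmethod
    def from_dict(cls, d: dict) -> "TrendSpec":
        return cls(form=d["form"], beta=tuple(d.get("beta", ())), ip=tuple(d.get("ip", ())))


def validate_trend(
    spec: TrendSpec, t_interval: tuple[float, float] | None = None
) -> list[str]:
    """Check a trend spec against its structural and interval constraints.

    Parameters
    ----------
    spec
        The trend specification.
    t_interval
        ``(t1, tq)`` study interval. Interval-dependent checks (hockey-stick
        IP inside the interval, oscillating IP3 != tq) are skipped when None.

    Returns
    -------
    list of str
        Human-readable violations; empty when the spec is valid.
    """
    v: list[str] = []
    if spec.form not in TREND_FORMS:
        return [f"unknown trend form {spec.form!r}; valid forms: {', '.join(TREND_FORMS)}"]
    if t_interval is not None:
        t1, tq = float(t_interval[0]), float(t_interval[1])
        if not t1 < tq:
            return [f"t_interval must satisfy t1 < tq, got ({t1}, {tq})"]
    else:
        t1 = tq = None

    if spec.form == "none":
        if spec.beta and any(b != 0.0 for b in spec.beta):
            v.append("form 'none' admits no nonzero coefficients")
        return v

    if spec.form in _POLY_NCOEF:
        want = _POLY_NCOEF[spec.form]
        if len(spec.beta) != want:
            v.append(
                f"{spec.form} requires {want} coefficients (beta0..beta{want - 1}), "
                f"got {len(spec.beta)}"
            )
        return v

    if spec.form in ("oscillating_M", "oscillating_W"):
        if len(spec.beta) != 2:
            v.append(f"{spec.form} requires beta = (beta0, beta1), got {len(spec.beta)} values")
        else:
            b1 = spec.beta[1]
            if spec.form == "oscillating_M" and not b1 > 0:
                v.append("oscillating_M requires beta1 > 0 (initially increasing)")
            if spec.form == "oscillating_W" and not b1 < 0:
                v.append("oscillating_W requires beta1 < 0 (initially decreasing)")
        if len(spec.ip) != 3:
            v.append(f"{spec.form} requires 3 inflection points, got {len(spec.ip)}")
        else:
            ip1, ip2, ip3 = spec.ip
            if not (ip1 < ip2 < ip3):
                v.append(f"inflection points must satisfy IP1 < IP2 < IP3, got {spec.ip}")
            if tq is not None:
                if ip3 == tq:
                    v.append("IP3 must differ from the last timepoint tq")
                if not (t1 < ip1 < tq):
                    v.append(f"IP1 = {ip1} outside interval ({t1}, {tq})")
        return v

    if spec.form == "L_up":
        if len(spec.beta) != 1:
            v.append(f"L_up requires a single slope beta1, got {len(spec.beta)} values")
        elif not spec.beta[0] > 0:
            v.append("L_up slope must be positive (beta1 > 0)")
        if len(spec.ip) != 1:
            v.append(f"L_up requires one inflection point, got {len(spec.ip)}")
        elif tq is not None and not (t1 < spec.ip[0] < tq):
            v.append(f"IP = {spec.ip[0]} outside interval ({t1}, {tq})")
        return v

    # L_down
    if len(spec.beta) != 2:
        v.append(f"L_down requires beta = (beta0, beta1), got {len(spec.beta)} values")
    else:
        b0, b1 = spec.beta
        if not b0 > 0:
            v.append("L_down requires beta0 > 0")
        if not b1 < 0:
            v.append("L_down requires a negative slope (beta1 < 0)")
        if b0 > 0 and b1 < 0 and tq is not None:
            ip = -b0 / b1
            if not (t1 < ip < tq):
                v.append(f"implied IP = -beta0/beta1 = {ip} outside interval ({t1}, {tq})")
    if spec.ip:
        v.append("L_down takes no explicit inflection point (IP is implied by -beta0/beta1)")
    return v


def _check(spec: TrendSpec, t_interval: tuple[float, float] | None) -> None:
    violations = validate_trend(spec, t_interval)
    if violations:
        raise TrendValidationError(violations)


def evaluate_trend(
    spec: TrendSpec,
    timepoints: ArrayLike,
    t_end: float | None = None,
    validate: bool = True,
) -> NDArray[np.float64]:
    """Evaluate ``f`` pointwise on a sorted vector of timepoints.

    Parameters
    ----------
    spec
        A valid trend specification.
    timepoints
        Sorted evaluation times; need not be the design grid, so
        asynchronous schedules reuse this code path.
    t_end
        Last timepoint ``tq`` of the study interval, which anchors the final
        decay segment of the oscillating forms. Defaults to
        ``timepoints[-1]``.
    validate
        Validate the spec against ``(timepoints[0], t_end)`` first.

    Returns
    -------
    ndarray
        ``f(t)`` for each ``t``, in abundance units.
    """
    t = np.asarray(timepoints, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("timepoints must be a non-empty 1-D vector")
    tq = float(t[-1]) if t_end is None else float(t_end)
    if validate:
        interval = (float(t[0]), tq) if tq > float(t[0]) else None
        _check(spec, interval)

    form = spec.form
    if form == "none":
        return np.zeros_like(t)

    if form in _POLY_NCOEF:
        # polynomial coefficients are beta0..betap in increasing degree
        return np.polynomial.polynomial.polyval(t, spec.beta)

    if form in ("oscillating_M", "oscillating_W"):
        b0, b1 = spec.beta
        ip1, ip2, ip3 = spec.ip
        v = b0 + b1 * ip1  # peak (M) or trough (W) value
        f = np.empty_like(t)
        seg0 = t < ip1
        seg1 = (t >= ip1) & (t < ip2)
        seg2 = (t >= ip2) & (t < ip3)
        seg3 = t >= ip3
        f[seg0] = b0 + b1 * t[seg0]
        f[seg1] = v - v / (ip2 - ip1) * (t[seg1] - ip1)
        f[seg2] = v / (ip3 - ip2) * (t[seg2] - ip2)
        if np.any(seg3):
            if tq == ip3:
                raise TrendValidationError(["IP3 must differ from the last timepoint tq"])
            f[seg3] = v - v / (tq - ip3) * (t[seg3] - ip3)
        return f

    if form == "L_up":
        (b1,) = spec.beta
        (ip,) = spec.ip
        return np.where(t >= ip, b1 * (t - ip), 0.0)

    # L_down: differential region before the implied IP, flat after
    b0, b1 = spec.beta
    ip = -b0 / b1
    return np.where(t < ip, b0 + b1 * t, 0.0)
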