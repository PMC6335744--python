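"""Dependent-correlation comparison (Steiger's Z) and CI decision rules.

``steiger_z`` tests whether two correlations sharing one variable —
r12 = r(X1, X2) and r13 = r(X1, X3), with r23 = r(X2, X3) — differ, using
Fisher z-transforms and Steiger's (1980) Z-bar-star-h covariance term with
the pooled back-transformed correlation. Williams' t is available as an
alternative.

CI rules mirror the conventional percentile-bootstrap reading: two
correlation scores differ when their CIs are disjoint, and a score is
unreliable when its CI covers zero. Intervals are treated as closed, so a
shared endpoint counts as overlap (the conservative tie rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InvalidSpecError

__all__ = ["SteigerResult", "steiger_z", "williams_t",
           "ci_overlap_decision", "reliability"]


@dataclass(frozen=True)
class SteigerResult:
    z: float
    p: float
    n: int
    r12: float
    r13: float
    r23: float
    method: str = "steiger_zh"


def _check_inputs(r12: float, r13: float, r23: float, n: int) -> None:
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not np.isfinite(r) or abs(r) >= 1:
            raise InvalidSpecError(f"{name} must satisfy |r| < 1, got {r}")
    if n < 4:
        raise InvalidSpecError(f"n must be >= 4, got {n}")


def steiger_z(r12: float, r13: float, r23: float, n: int) -> SteigerResult:
    """Steiger's Z-bar-star-h for H0: rho12 = rho13 (two-tailed).

    z1 - z2 are the Fisher transforms; their covariance uses the pooled
    correlation rbar = (r12 + r13)/2:

        cov = [r23 (1 - 2 rbar^2) - rbar^2 (1 - 2 rbar^2 - r23^2)/ ... ]

    concretely  psi = r23 (1 - 2 rbar^2) - 0.5 rbar^2 (1 - 2 rbar^2 - r23^2)
    and         s   = psi / (1 - rbar^2)^2,
    giving      Z   = (z12 - z13) sqrt((n - 3) / (2 (1 - s))).
    """
    _check_inputs(r12, r13, r23, n)
    z12, z13 = np.arctanh(r12), np.arctanh(r13)
    rbar = (r12 + r13) / 2.0
    psi = r23 * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (1.0 - 2.0 * rbar**2 - r23**2)
    s = psi / (1.0 - rbar**2) ** 2
    z = float((z12 - z13) * np.sqrt((n - 3) / (2.0 * (1.0 - s))))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerResult(z=z, p=p, n=int(n), r12=r12, r13=r13, r23=r23)


def williams_t(r12: float, r13: float, r23: float, n: int) -> SteigerResult:
    """Williams' (1959) t for the same hypothesis, on n-3 degrees of freedom."""
    _check_inputs(r12, r13, r23, n)
    det = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    rbar = (r12 + r13) / 2.0
    num = (r12 - r13) * np.sqrt((n - 1) * (1.0 + r23))
    den = np.sqrt(2.0 * det * (n - 1) / (n - 3) + rbar**2 * (1.0 - r23) ** 3)
    t = float(num / den) if den > 0 else 0.0
    p = float(2.0 * stats.t.sf(abs(t), df=n - 3))
    return SteigerResult(z=t, p=p, n=int(n), r12=r12, r13=r13, r23=r23,
                         method="williams_t")


def _check_interval(ci: tuple[float, float], name: str) -> tuple[float, float]:
    lo, hi = float(ci[0]), float(ci[1])
    if lo > hi:
        raise InvalidSpecError(f"{name}: interval lower bound {lo} > upper bound {hi}")
    return lo, hi


def ci_overlap_decision(ci_a: tuple[float, float], ci_b: tuple[float, float]) -> str:
    """'different' iff the closed intervals are disjoint, else 'not-distinguished'."""
    lo_a, hi_a = _check_interval(ci_a, "ci_a")
    lo_b, hi_b = _check_interval(ci_b, "ci_b")
    disjoint = hi_a < lo_b or hi_b < lo_a
    return "different" if disjoint else "not-distinguished"


def reliability(ci: tuple[float, float]) -> str:
    """'unreliable' iff the closed interval covers zero, else 'reliable'."""
    lo, hi = _check_interval(ci, "ci")
    return "unreliable" if lo <= 0.0 <= hi else "reliable"
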