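"""Extrapolation of IAM retention to a fully aqueous mobile phase.

Very lipophilic compounds elute too slowly from an IAM column with a
100% aqueous eluent for log kw^IAM to be measured directly.  Instead the
retention factor log k is measured at several volume fractions φ of a
water-miscible organic modifier and extrapolated to φ = 0 with the
linear Soczewiński–Wachmeister relation

    log k = log kw + S · φ,

an ordinary least-squares line whose intercept is the aqueous retention
estimate log kw and whose slope S characterises the eluent strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class IsocraticSeries:
    """Retention measurements (φ, log k) for one compound."""

    phi: tuple[float, ...]
    log_k: tuple[float, ...]

    def __init__(self, phi: Sequence[float], log_k: Sequence[float]):
        phi_t = tuple(float(p) for p in phi)
        k_t = tuple(float(k) for k in log_k)
        if len(phi_t) != len(k_t):
            raise ValueError(
                f"phi and log_k lengths differ ({len(phi_t)} vs {len(k_t)})"
            )
        if len(phi_t) < 2:
            raise ValueError("at least two (phi, log k) points are required")
        if any(not (0.0 <= p < 1.0) for p in phi_t):
            raise ValueError("phi values must lie in [0, 1)")
        object.__setattr__(self, "phi", phi_t)
        object.__setattr__(self, "log_k", k_t)


@dataclass(frozen=True)
class ExtrapolationResult:
    """Fitted Soczewiński–Wachmeister line."""

    log_kw: float
    slope_S: float
    r_squared: float
    se_log_kw: float | None
    n_points: int


def fit_soczewinski(series: IsocraticSeries) -> ExtrapolationResult:
    """Least-squares fit of log k on φ; the intercept estimates log kw^IAM.

    With exactly two points the fit is exact (R² = 1) and the intercept
    standard error is undefined, reported as ``None``.

    Raises
    ------
    ValueError
        If all φ values coincide (the slope is unidentifiable).
    """
    phi = np.asarray(series.phi)
    log_k = np.asarray(series.log_k)
    if np.ptp(phi) == 0.0:
        raise ValueError("all phi values are identical; slope is unidentifiable")

    fit = stats.linregress(phi, log_k)
    n = phi.size
    # rvalue is NaN for a perfectly flat response; the line still fits exactly
    if np.allclose(log_k - (fit.intercept + fit.slope * phi), 0.0, atol=1e-12):
        r2 = 1.0
    else:
        r2 = float(fit.rvalue**2)

    se_log_kw: float | None = float(fit.intercept_stderr) if n > 2 else None
    return ExtrapolationResult(
        log_kw=float(fit.intercept),
        slope_S=float(fit.slope),
        r_squared=r2,
        se_log_kw=se_log_kw,
        n_points=int(n),
    )
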