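"""Weibull distribution primitives for 1-NN distance modeling.

The first-nearest-neighbor (1-NN) distance distribution of an ordered
cell-type pair is summarized by a two-parameter Weibull density

    f(x; a, b) = (a/b) (x/b)^(a-1) exp(-(x/b)^a),  x >= 0,

with shape ``a`` (dimensionless) and scale ``b`` (μm). Under complete
spatial randomness of the target type at intensity λ the cross 1-NN
distances are exactly Weibull with a = 2 and b = (πλ)^(−1/2), which makes
the CSR case a closed-form oracle for the whole pipeline.

Because the mixed-effects fit is unconstrained, shape and scale are
re-parameterized through scaled logistic links onto bounded intervals:

    a = 10 / (1 + e^(−A)),   b = 500 / (1 + e^(−B)),

with ``A`` and ``B`` unconstrained reals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

logger = logging.getLogger(__name__)

SHAPE_UPPER = 10.0
SCALE_UPPER = 500.0

#: Zero distances (coincident nuclei centroids) are floored here before
#: maximum-likelihood fitting, since the Weibull likelihood diverges at 0.
ZERO_DISTANCE_FLOOR = 0.01


class DegenerateDistancesError(ValueError):
    """Distance vector carries no information (all values identical)."""


def link_transform(A: float, B: float) -> tuple[float, float]:
    """Map unconstrained (A, B) to (shape, scale) via scaled logistics."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    a = SHAPE_UPPER / (1.0 + np.exp(-A))
    b = SCALE_UPPER / (1.0 + np.exp(-B))
    if a.ndim == 0:
        return float(a), float(b)
    return a, b


def inverse_link(a: float, b: float) -> tuple[float, float]:
    """Map (shape, scale) back to unconstrained (A, B)."""
    a = float(a)
    b = float(b)
    if not (0.0 < a < SHAPE_UPPER):
        raise ValueError(f"shape must lie in (0, {SHAPE_UPPER}), got {a}")
    if not (0.0 < b < SCALE_UPPER):
        raise ValueError(f"scale must lie in (0, {SCALE_UPPER}), got {b}")
    A = -math.log(SHAPE_UPPER / a - 1.0)
    B = -math.log(SCALE_UPPER / b - 1.0)
    return A, B


@dataclass(frozen=True)
class WeibullParams:
    """Shape/scale pair with access to the unconstrained coordinates."""

    shape: float
    scale: float

    def __post_init__(self):
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("shape and scale must be positive")

    @classmethod
    def from_unconstrained(cls, A: float, B: float) -> "WeibullParams":
        a, b = link_transform(A, B)
        return cls(shape=a, scale=b)

    @property
    def unconstrained(self) -> tuple[float, float]:
        return inverse_link(self.shape, self.scale)


def weibull_pdf(x, p: WeibullParams) -> np.ndarray:
    """Weibull density at ``x`` (μm); raises on negative arguments.

    The limit at x = 0 is taken: 0 for shape > 1, 1/scale for shape = 1,
    +inf for shape < 1.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Weibull density is defined on x >= 0")
    out = stats.weibull_min.pdf(x, c=p.shape, scale=p.scale)
    return out if out.ndim else float(out)


def analytic_cdf(r, p: WeibullParams) -> np.ndarray:
    """Weibull CDF: 1 − exp(−(r/b)^a); the analytic G-function."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("CDF argument must be >= 0")
    out = -np.expm1(-np.power(r / p.scale, p.shape))
    return out if out.ndim else float(out)


def weibull_g_auc(p: WeibullParams, T: float) -> float:
    """Area under the analytic CDF over [0, T] (μm), by quadrature."""
    if T <= 0:
        raise ValueError("threshold T must be positive")
    val, _ = integrate.quad(
        lambda r: analytic_cdf(r, p), 0.0, T, epsabs=1e-8, epsrel=1e-10, limit=200
    )
    return float(val)


def median_1nn(p: WeibullParams) -> float:
    """Median of the 1-NN distance distribution: scale · (ln 2)^(1/shape)."""
    return p.scale * math.log(2.0) ** (1.0 / p.shape)


def csr_scale(intensity: float) -> float:
    """CSR closed form: scale of the cross 1-NN Weibull, (πλ)^(−1/2)."""
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    return (math.pi * intensity) ** -0.5


def fit_weibull_mle(distances) -> WeibullParams:
    """Maximum-likelihood Weibull fit of a raw 1-NN distance vector.

    Used to initialize the mixed-effects fit, not as a final estimate.
    Zero distances are floored at ``ZERO_DISTANCE_FLOOR`` μm (logged);
    an all-identical vector is degenerate and rejected.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 5:
        raise ValueError(f"need at least 5 distances for an MLE, got {d.size}")
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite and non-negative")
    n_zero = int(np.sum(d < ZERO_DISTANCE_FLOOR))
    if n_zero:
        logger.info("floored %d near-zero distance(s) at %g μm", n_zero, ZERO_DISTANCE_FLOOR)
        d = np.maximum(d, ZERO_DISTANCE_FLOOR)
    if np.ptp(d) == 0:
        raise DegenerateDistancesError("all distances identical; cannot fit a Weibull")
    shape, _, scale = stats.weibull_min.fit(d, floc=0)
    # Keep initializer inside the open link-transform bounds.
    shape = float(np.clip(shape, 1e-3, SHAPE_UPPER * (1 - 1e-6)))
    scale = float(np.clip(scale, 1e-3, SCALE_UPPER * (1 - 1e-6)))
    return WeibullParams(shape=shape, scale=scale)
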