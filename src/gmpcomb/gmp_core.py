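"""Generalized mean p-values (GMPs) and their Bayes-factor interpretation.

The generalized mean p-value with exponent ``r`` of p-values ``p_1, ..., p_K``
is

    M_{r,K}(p_1, ..., p_K) = ((p_1^r + ... + p_K^r) / K)^{1/r},

which interpolates between the minimum (r -> -inf), harmonic mean (r = -1),
geometric mean (r -> 0), arithmetic mean (r = 1) and maximum (r -> +inf).
Smaller (more negative) exponents weight small p-values more heavily.

Under the grand null hypothesis the summands ``X_i = p_i^r`` are
Pareto(1, -1/r) for r < 0 and Beta(1/r, 1) for r > 0, so the sum of the
``X_i`` is heavy-tailed with tail index ``lambda = -1/r`` when r < 0.  The
moments and tail index exposed here drive the stable-law significance
thresholds in :mod:`gmpcomb.thresholds`.

When the constituent tests evaluate mutually exclusive alternatives against a
common null on the same data, the GMP with -1 < r < 0 has an exact
model-averaging reading: ``M_{r,K}^r`` equals the average Bayes factor under
Beta(1 + r, 1) alternatives.  Outside that range the GMP bounds the averaged
Bayes factor; see :func:`mean_bayes_factor` and :func:`bf_bound`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, logsumexp

__all__ = [
    "GEOMETRIC_SENTINEL_TOL",
    "BetaAlternative",
    "PowerMoments",
    "bf_bound",
    "compute_gmp",
    "mean_bayes_factor",
    "power_moments",
    "tail_index",
    "validate_pvalues",
]

#: |r| below this is treated as the geometric-mean limit r -> 0.  The 1/r
#: exponent is numerically explosive near zero while the limit is exact.
GEOMETRIC_SENTINEL_TOL = 1e-8


def validate_pvalues(p, floor: float | None = None) -> np.ndarray:
    """Validate a vector of p-values, returning a float array in (0, 1].

    Parameters
    ----------
    p : array_like
        The constituent p-values.  Must be non-empty with every element in
        (0, 1].
    floor : float, optional
        If given, p-values of exactly 0 are clipped up to this value instead
        of raising.  Clipping is opt-in because a zero p-value makes the GMP
        undefined for r < 0 and silently flooring can hide upstream bugs.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        arr = arr.reshape(-1)
    if arr.size == 0:
        raise ValueError("at least one p-value is required")
    if np.any(~np.isfinite(arr)):
        raise ValueError("p-values must be finite")
    if floor is not None:
        if not 0 < floor < 1:
            raise ValueError("floor must lie in (0, 1)")
        arr = np.maximum(arr, floor)
    if np.any(arr <= 0):
        raise ValueError(
            "p-values must be strictly positive; pass floor= to clip exact zeros"
        )
    if np.any(arr > 1):
        raise ValueError("p-values must not exceed 1")
    return arr


def compute_gmp(p, r: float) -> float:
    """Generalized mean p-value M_{r,K} of a vector of p-values.

    ``r`` may be any extended real: ``-inf`` returns ``min(p)``, ``+inf``
    returns ``max(p)``, and |r| <= 1e-8 is treated as the geometric-mean
    limit ``exp(mean(log p))``.

    The finite-``r`` evaluation goes through
    ``exp((1/r) * (logsumexp(r * log p) - log K))`` so that extreme exponents
    (e.g. r = -10 with p ~ 1e-30) neither overflow nor underflow.
    """
    arr = validate_pvalues(p)
    if math.isinf(r):
        return float(arr.min() if r < 0 else arr.max())
    logp = np.log(arr)
    if abs(r) <= GEOMETRIC_SENTINEL_TOL:
        return float(np.exp(logp.mean()))
    k = arr.size
    return float(np.exp((logsumexp(r * logp) - math.log(k)) / r))


def gmp_rows(pmat: np.ndarray, r: float) -> np.ndarray:
    """Row-wise GMP of a (n_replicates, K) matrix of p-values.

    Vectorized companion of :func:`compute_gmp` for simulation work; the
    rows are assumed already validated.
    """
    logp = np.log(pmat)
    if math.isinf(r):
        return pmat.min(axis=1) if r < 0 else pmat.max(axis=1)
    if abs(r) <= GEOMETRIC_SENTINEL_TOL:
        return np.exp(logp.mean(axis=1))
    k = pmat.shape[1]
    return np.exp((logsumexp(r * logp, axis=1) - math.log(k)) / r)


def tail_index(r: float) -> float:
    """Tail index lambda of X = p^r for p ~ Uniform(0, 1).

    lambda = -1/r for r < 0 (Pareto tail) and infinity for r > 0 (bounded
    support).  For distributional purposes any lambda > 2 behaves as the
    Gaussian case lambda = 2; callers clamp accordingly.  r = 0 is a domain
    error: the geometric mean is handled exactly by Fisher's method rather
    than through a stable limit.
    """
    if r == 0 or abs(r) <= GEOMETRIC_SENTINEL_TOL:
        raise ValueError("tail index undefined at r = 0 (use Fisher's method)")
    if r > 0:
        return math.inf
    return -1.0 / r


@dataclass(frozen=True)
class PowerMoments:
    """Mean and variance of X = p^r for p ~ Uniform(0, 1); inf when divergent."""

    mean: float
    variance: float


def power_moments(r: float) -> PowerMoments:
    """Moments of X = p^r under the null.

    E[X] = 1/(1+r) for r > -1 and infinite otherwise; V[X] =
    r^2 / ((1+r)^2 (1+2r)) for r > -1/2 and infinite otherwise.  The
    divergence boundaries are what make the r <= -1/2 regime genuinely
    heavy-tailed (stable rather than normal limits).
    """
    if not math.isfinite(r) or r == 0:
        raise ValueError("power_moments requires finite nonzero r")
    mean = 1.0 / (1.0 + r) if r > -1 else math.inf
    if r > -0.5:
        variance = r * r / ((1.0 + r) ** 2 * (1.0 + 2.0 * r))
    else:
        variance = math.inf
    return PowerMoments(mean=mean, variance=variance)


@dataclass(frozen=True)
class BetaAlternative:
    """Beta(xi, zeta) model for the p-value distribution under the alternative.

    The density must be non-increasing in p, hence 0 < xi <= 1 and
    zeta >= 1.  zeta = 1 with xi = 1 + r gives the local-alternatives family
    under which the GMP has its exact model-averaging interpretation.
    """

    xi: float
    zeta: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.xi <= 1:
            raise ValueError("xi must lie in (0, 1]")
        if self.zeta < 1:
            raise ValueError("zeta must be >= 1")


def mean_bayes_factor(p, alt: BetaAlternative) -> float:
    """Model-averaged Bayes factor for a Beta(xi, zeta) alternative.

    BF-bar = (1/K) * sum_i p_i^{xi-1} (1-p_i)^{zeta-1} / B(xi, zeta),

    the average likelihood ratio when the alternative is a mixture of K
    mutually exclusive local alternatives sharing a common null.  With
    zeta = 1 and xi = 1 + r this equals (1 + r) * M_{r,K}^r.
    """
    arr = validate_pvalues(p)
    lbeta = betaln(alt.xi, alt.zeta)
    if alt.zeta == 1.0:
        # handled separately: (1-p)^0 is 1 even at p = 1, where log1p(-p)
        # would be -inf
        logterms = (alt.xi - 1.0) * np.log(arr)
    else:
        logterms = (alt.xi - 1.0) * np.log(arr) + (alt.zeta - 1.0) * np.log1p(-arr)
    return float(np.exp(logsumexp(logterms) - math.log(arr.size) - lbeta))


def bf_bound(p, r_star: float, r: float) -> float:
    """Upper bound (1 + r) * M_{r*,K}^r on the mean Bayes factor.

    Requires r_star < r < 0.  Because the GMP is nondecreasing in its
    exponent, M_{r,K} >= M_{r*,K} and hence (1+r) M_{r*,K}^r bounds the
    averaged Bayes factor under the Beta(1 + r, 1) alternative from above.
    """
    if not (r_star < r < 0):
        raise ValueError("bf_bound requires r_star < r < 0")
    m = compute_gmp(p, r_star)
    return float((1.0 + r) * m**r)
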