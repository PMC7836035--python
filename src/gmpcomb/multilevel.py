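"""Multilevel (closed testing) procedures for subsets of p-values.

A combined GMP test rejects the grand null; multilevel testing asks which
*subsets* of the K tests can be declared significant while controlling the
strong-sense family-wise error rate at eps.  The shortcut to the closed
testing procedure compares the subset GMP p-bar_{r,R} = M_{r,|R|}(p_i : i in R)
against a deflated threshold

    p-bar_{r,R} <= f_{|R|} * Psi_{r,|R|}(eps),

where the factor f_{|R|} is the largest value for which subset significance
implies significance of the full combination even if every p-value outside
the subset equals 1 (consonance).  The exact partition identity

    K * p-bar_r^r = |R| * p-bar_{r,R}^r + |R'| * p-bar_{r,R'}^r

yields the general factor; for r < -1 both the GCLT and RRA thresholds
satisfy Psi_{r,K}/Psi_{r,m} = (m/K)^{1+1/r}, collapsing the factor to the
simple f = m/K and giving closed-form subset thresholds:

    GCLT small-eps (r <= -1):  m^{-1/r} * eps / K
    RRA (r < -1):              (m/K)^{-1/r} * Psi_RRA,r,K(eps)

For r > 0 the factor's numerator Psi_{r,K}^r - (1 - m/K) can go negative:
no subset smaller than K (1 - Psi_{r,K}^r) can ever be significant through
this shortcut, reported via the NOT_REJECTABLE sentinel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .gmp_core import compute_gmp
from .thresholds import ThresholdResult, gclt_threshold, rra_threshold

__all__ = [
    "NOT_REJECTABLE",
    "CtpDecision",
    "ctp_factor",
    "multilevel_reject",
    "subset_threshold",
]


class _NotRejectable:
    """Sentinel: no subset of this size can be significant via the shortcut."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NOT_REJECTABLE"


NOT_REJECTABLE = _NotRejectable()


def _threshold(method: str, r: float, K: int, eps: float) -> ThresholdResult:
    method = method.lower()
    if method == "gclt":
        return gclt_threshold(r, K, eps)
    if method == "rra":
        return rra_threshold(r, K, eps)
    raise ValueError(f"unknown threshold method {method!r}; use 'gclt' or 'rra'")


def _warn_transitional(r: float) -> None:
    if -1 < r < 0:
        warnings.warn(
            "GCLT thresholds for -1 < r < 0 showed inflated false positive "
            "rates under dependence; multilevel inference here assumes "
            "independence holds",
            stacklevel=3,
        )


def ctp_factor(r: float, subset_size: int, K: int, eps: float, method: str = "gclt"):
    """Closed-testing deflation factor f_{|R|} for a subset of given size.

    Returns a float in (0, 1], or NOT_REJECTABLE when r > 0 and the subset
    is too small for any p-values to force rejection of the full
    combination.  For r < -1 the factor is exactly subset_size / K (both
    threshold families satisfy the required threshold-ratio property).
    r = 0 has no closed testing procedure in this framework.
    """
    if r == 0:
        raise ValueError("no closed testing procedure is defined for r = 0")
    if not 1 <= subset_size <= K:
        raise ValueError("subset_size must lie in [1, K]")
    if subset_size == K:
        return 1.0
    if r < -1:
        return subset_size / K
    _warn_transitional(r)
    psi_k = _threshold(method, r, K, eps).psi
    psi_m = _threshold(method, r, subset_size, eps).psi
    frac = subset_size / K
    num = psi_k**r - (1.0 - frac)
    if num <= 0:
        if r > 0:
            return NOT_REJECTABLE
        raise ValueError("degenerate factor numerator for r < 0")  # pragma: no cover
    return min(1.0, (num / (frac * psi_m**r)) ** (1.0 / r))


def subset_threshold(
    r: float,
    subset_size: int,
    K: int,
    eps: float,
    method: str = "gclt",
    small_eps: bool = False,
):
    """Significance threshold for the GMP of a subset of ``subset_size`` p-values.

    * ``small_eps=True`` (requires r <= -1): the closed form
      subset_size^{-1/r} * eps / K; for singletons this is Bonferroni-like.
    * RRA with r < -1: (subset_size/K)^{-1/r} * Psi_RRA,r,K(eps).
    * GCLT with r < -1: (subset_size/K)^{-1/r} * Psi_GCLT,r,K(eps), exactly
      f * Psi_{r,|R|} by the threshold-ratio property.
    * otherwise: the general factor route f_{|R|} * Psi_{r,|R|}(eps), which
      needs subset_size >= 2 for the stable-law threshold to exist.

    Returns a float, or NOT_REJECTABLE when the factor is degenerate (r > 0,
    subset too small).
    """
    if not 1 <= subset_size <= K:
        raise ValueError("subset_size must lie in [1, K]")
    if small_eps:
        if r > -1:
            raise ValueError("small-eps subset thresholds require r <= -1")
        return float(subset_size ** (-1.0 / r) * eps / K)
    if r < -1:
        psi_k = _threshold(method, r, K, eps).psi
        return float((subset_size / K) ** (-1.0 / r) * psi_k)
    f = ctp_factor(r, subset_size, K, eps, method=method)
    if f is NOT_REJECTABLE:
        return NOT_REJECTABLE
    if subset_size == K:
        return float(_threshold(method, r, K, eps).psi)
    psi_m = _threshold(method, r, subset_size, eps).psi
    return float(f * psi_m)


@dataclass(frozen=True)
class CtpDecision:
    """Outcome of a multilevel subset test."""

    subset_size: int
    K: int
    r: float
    eps: float
    method: str
    factor: object  # float or NOT_REJECTABLE
    subset_threshold: object  # float or NOT_REJECTABLE
    subset_gmp: float
    reject: bool


def multilevel_reject(
    p,
    subset,
    r: float,
    eps: float,
    method: str = "gclt",
    small_eps: bool = False,
) -> CtpDecision:
    """Test a subset of p-values at strong-sense FWER eps.

    ``subset`` is a sequence of 0-based indices into ``p``.  The subset GMP
    is compared against :func:`subset_threshold`; a rejection implies
    (consonance) that the grand null would also be rejected even with all
    complement p-values at their least favourable value 1.
    """
    arr = np.asarray(p, dtype=float)
    idx = np.asarray(subset, dtype=int)
    if idx.size == 0:
        raise ValueError("subset must be nonempty")
    if np.unique(idx).size != idx.size:
        raise ValueError("subset indices must be unique")
    if idx.min() < 0 or idx.max() >= arr.size:
        raise ValueError("subset indices out of range")
    K = arr.size
    m = idx.size
    gmp_sub = compute_gmp(arr[idx], r)
    thr = subset_threshold(r, m, K, eps, method=method, small_eps=small_eps)
    if r < -1 or small_eps:
        factor = m / K
    else:
        factor = ctp_factor(r, m, K, eps, method=method)
    reject = (thr is not NOT_REJECTABLE) and gmp_sub <= thr
    return CtpDecision(
        subset_size=m,
        K=K,
        r=r,
        eps=eps,
        method=method,
        factor=factor,
        subset_threshold=thr,
        subset_gmp=gmp_sub,
        reject=bool(reject),
    )
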