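"""Significance thresholds for generalized mean p-values.

A GMP is not itself uniformly distributed under the grand null, so it is
used as a test statistic against a significance threshold Psi_{r,K}(eps)
chosen to cap the false positive rate at eps.  Two families are provided:

* **GCLT thresholds** — under independence, the sum Y = sum_i p_i^r is in
  the domain of attraction of an extremal stable law S_{lambda,1} with
  tail index lambda = -1/r (clamped at 2, the Gaussian case).  With
  centering a_{r,K} and scaling b_{r,K} from the classical generalized
  central limit theorem, the threshold is

      Psi_GCLT = [(a_{r,K} + b_{r,K} q) / K]^{1/r},

  where q is the upper 1-eps quantile of S_{lambda,1} for r < 0 and the
  lower eps quantile of S_{2,1} = Normal(0, 2) for r > 0.  For r <= -1 the
  heavy tails confer partial robustness to dependence (the Davis–Resnick
  tail-independence condition); for r > -1/2 this is the plain CLT with no
  such robustness.

* **RRA thresholds** — worst-case merging bounds from robust risk analysis
  (Vovk & Wang), valid under *arbitrary* dependence.  They are linear in
  eps: Psi_RRA = m(r, K) * eps with multiplier ((r+1)/r) K^{-(1+1/r)} for
  r < -1, 1/log K for r = -1, and (r+1)^{-1/r} for r > -1 (limit 1/e at
  r = 0).

The gap between the two families quantifies the power/robustness trade-off;
the inverse maps :func:`fpr_under_independence` and :func:`fpr_worst_case`
translate one family's threshold into the other family's realized false
positive rate.

Stable quantiles use Nolan's S1 parameterization (alpha = lambda, beta = 1,
sigma = 1, mu = 0), validated against a Chambers–Mallows–Stuck sampling
oracle in the test suite; the S0/S1 distinction matters (the two differ by
a shift beta * tan(pi * lambda / 2) for lambda != 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .gmp_core import compute_gmp, power_moments, validate_pvalues

__all__ = [
    "GcltCoefficients",
    "TestDecision",
    "ThresholdResult",
    "bonferroni",
    "fisher",
    "fpr_under_independence",
    "fpr_worst_case",
    "gclt_coefficients",
    "gclt_threshold",
    "rra_multiplier",
    "rra_threshold",
    "sidak",
    "simes",
    "small_eps_threshold",
    "stable_cdf",
    "stable_quantile",
    "stable_sf",
]

#: GCLT tail approximations degrade for large target levels; warn past this.
EPS_WARN_LEVEL = 0.2

#: Below this tail index the stable quantile is numerically intractable
#: (values overflow double precision) and the sum is utterly dominated by
#: its largest term, so the GMP is treated through the exact distribution
#: of the minimum p-value (the Frechet/extreme-value regime).
FRECHET_LAMBDA = 0.05


def _clamped_alpha(lam: float) -> float:
    # S_{lambda,1} with lambda > 2 is distributionally S_{2,1} = Normal(0, 2)
    return min(lam, 2.0)


def _with_s1(func, *args):
    dist = stats.levy_stable
    prev = dist.parameterization
    dist.parameterization = "S1"
    try:
        return func(*args)
    finally:
        dist.parameterization = prev


# Numerical strategy for the extremal stable law S_{alpha,1} (S1, sigma=1):
# the library's piecewise-integrated CDF is accurate in the central region
# but saturates deep in the upper tail (and its quantile function saturates
# even earlier), so beyond the switch levels below we use the Zolotarev
# tail expansion
#
#   Pr(S > x) = (1/pi) sum_k (-1)^{k+1} (Gamma(k a)/k!) sin(k pi a rho)
#               * sec(pi a / 2)^k * x^{-k a},
#
# with rho = 1 for a < 1 (convergent series) and rho = 1 - 1/a for
# 1 < a < 2 (asymptotic; truncated at the smallest term).  For a = 1 the
# expansion degenerates and the leading term 2/(pi x) is used.  Both
# branches were validated against Chambers-Mallows-Stuck sampling.
_SERIES_TAIL_LEVEL = 1e-3  # use the series once the tail is below this
_PPF_SCIPY_MIN_TAIL = 5e-3  # library quantile trusted down to this tail
_ALPHA1_SCIPY_X_MAX = 300.0  # library alpha=1 CDF trusted up to here


def _series_sf_logx(alpha: float, log_x: float, max_terms: int = 400) -> float:
    lam = abs(1.0 / math.cos(math.pi * alpha / 2.0))
    rho = 1.0 if alpha < 1 else 1.0 - 1.0 / alpha
    total, prev = 0.0, math.inf
    for k in range(1, max_terms + 1):
        logmag = (
            math.lgamma(k * alpha)
            - math.lgamma(k + 1)
            + k * math.log(lam)
            - k * alpha * log_x
        )
        term = (-1) ** (k + 1) / math.pi * math.sin(k * math.pi * alpha * rho) * math.exp(logmag)
        if alpha > 1 and abs(term) > prev:
            break
        total += term
        if abs(term) < 1e-16 * abs(total):
            break
        prev = abs(term)
    return total


def _first_order_log_c1(alpha: float) -> float:
    # log of the coefficient of x^{-alpha} in the tail expansion
    lam = abs(1.0 / math.cos(math.pi * alpha / 2.0))
    rho = 1.0 if alpha < 1 else 1.0 - 1.0 / alpha
    return (
        math.lgamma(alpha)
        + math.log(math.sin(math.pi * alpha * rho))
        + math.log(lam)
        - math.log(math.pi)
    )


def stable_quantile(lam: float, q: float) -> float:
    """Quantile F^{-1}_{lambda,1}(q) of the extremal stable law S_{lambda,1}.

    Nolan S1 parameterization with alpha = min(lambda, 2), beta = 1,
    sigma = 1, mu = 0.  lambda = 2 (and anything above) is exactly
    Normal(0, 2) and is evaluated in closed form; deep upper-tail
    quantiles are obtained by inverting the tail expansion.
    """
    if not 0 < q < 1:
        raise ValueError("quantile level must lie in (0, 1)")
    alpha = _clamped_alpha(lam)
    if alpha <= 0:
        raise ValueError("tail index must be positive")
    if alpha == 2.0:
        return float(math.sqrt(2.0) * stats.norm.ppf(q))
    p = 1.0 - q
    if p >= _PPF_SCIPY_MIN_TAIL:
        return float(_with_s1(stats.levy_stable.ppf, q, alpha, 1.0))
    if abs(alpha - 1.0) < 1e-9:
        return 2.0 / (math.pi * p)
    from scipy.optimize import brentq

    log_x1 = (_first_order_log_c1(alpha) - math.log(p)) / alpha
    f = lambda t: _series_sf_logx(alpha, t) - p
    lo, hi = log_x1 - 3.0, log_x1 + 3.0
    return float(math.exp(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)))


def stable_sf(lam: float, x: float) -> float:
    """Upper tail probability of S_{lambda,1} in the S1 parameterization."""
    alpha = _clamped_alpha(lam)
    if alpha == 2.0:
        return float(stats.norm.sf(x / math.sqrt(2.0)))
    if abs(alpha - 1.0) < 1e-9:
        if x <= _ALPHA1_SCIPY_X_MAX:
            return float(_with_s1(stats.levy_stable.sf, x, 1.0, 1.0))
        return 2.0 / (math.pi * x)
    if x > 1.0:
        log_x = math.log(x)
        if math.exp(_first_order_log_c1(alpha) - alpha * log_x) < _SERIES_TAIL_LEVEL:
            return _series_sf_logx(alpha, log_x)
    return float(_with_s1(stats.levy_stable.sf, x, alpha, 1.0))


def stable_cdf(lam: float, x: float) -> float:
    """CDF of S_{lambda,1} in the S1 parameterization."""
    alpha = _clamped_alpha(lam)
    if alpha == 2.0:
        return float(stats.norm.cdf(x / math.sqrt(2.0)))
    sf = stable_sf(lam, x)
    if sf < 0.5:
        return 1.0 - sf
    return float(_with_s1(stats.levy_stable.cdf, x, alpha, 1.0))


@dataclass(frozen=True)
class GcltCoefficients:
    """Centering a, scaling b and normalized constant C for (Y - a)/b -> S_{lambda,1}."""

    a: float
    b: float
    C: float
    lam: float


def _tail_constant(r: float) -> float:
    # [(2/pi) Gamma(-1/r) sin(-pi/(2r))]^r, the stable-law scaling constant
    # for Pareto(1, -1/r) summands with 0 < lambda < 2, lambda != 1.
    # Evaluated in log space: Gamma(-1/r) overflows for r << -170.
    log_bracket = (
        math.log(2.0 / math.pi)
        + math.lgamma(-1.0 / r)
        + math.log(math.sin(-math.pi / (2.0 * r)))
    )
    return math.exp(r * log_bracket)


def gclt_coefficients(r: float, K: int) -> GcltCoefficients:
    """Generalized-CLT centering and scaling for Y = sum_i p_i^r, K terms.

    The five regimes follow the classical tables for sums of non-negative
    regularly varying random variables:

    ========  ===========  =========  ============================
    regime    lambda       a          b
    ========  ===========  =========  ============================
    r < -1    (0, 1)       0          C K^{-r}
    r = -1    1            K log K    (pi/2) K
    -1<r<-.5  (1, 2)       K/(1+r)    C K^{-r}
    r = -1/2  2            2K         sqrt(K log K)
    r > -1/2  2 (normal)   K/(1+r)    sqrt(K V[X] / 2)
    ========  ===========  =========  ============================

    with C = b / K^{max(1/2, -r)} reported alongside.
    """
    if not math.isfinite(r) or r == 0:
        raise ValueError("gclt_coefficients requires finite nonzero r")
    if K < 1:
        raise ValueError("K must be positive")
    if r < -1:
        lam = -1.0 / r
        C = _tail_constant(r)
        return GcltCoefficients(a=0.0, b=C * K ** (-r), C=C, lam=lam)
    if r == -1:
        C = math.pi / 2.0
        return GcltCoefficients(a=K * math.log(K), b=C * K, C=C, lam=1.0)
    if r < -0.5:
        lam = -1.0 / r
        C = _tail_constant(r)
        return GcltCoefficients(a=K / (1.0 + r), b=C * K ** (-r), C=C, lam=lam)
    if r == -0.5:
        C = math.sqrt(math.log(K))
        return GcltCoefficients(a=2.0 * K, b=C * math.sqrt(K), C=C, lam=2.0)
    var = power_moments(r).variance
    C = math.sqrt(var / 2.0)
    return GcltCoefficients(a=K / (1.0 + r), b=C * math.sqrt(K), C=C, lam=2.0)


@dataclass(frozen=True)
class ThresholdResult:
    """A significance threshold Psi for (method, r, K, eps)."""

    method: str
    r: float
    K: int
    eps: float
    psi: float


def _check_eps(eps: float) -> None:
    if not 0 < eps < 1:
        raise ValueError("eps must lie in (0, 1)")
    if eps > EPS_WARN_LEVEL:
        warnings.warn(
            f"eps = {eps:g} > {EPS_WARN_LEVEL}: GCLT tail approximations "
            "degrade for large target levels",
            stacklevel=3,
        )


@lru_cache(maxsize=8192)
def gclt_threshold(r: float, K: int, eps: float) -> ThresholdResult:
    """GCLT significance threshold Psi_GCLT,r,K(eps) for the GMP.

    For r < 0 small values of the GMP correspond to large values of the
    heavy-tailed sum Y, so the *upper* 1-eps stable quantile is used; for
    r > 0 the lower eps quantile of Normal(0, 2) applies.  The result is
    clipped into (0, 1].
    """
    if not math.isfinite(r) or r == 0:
        raise ValueError(
            "gclt_threshold requires finite nonzero r; use Fisher's method for r = 0"
        )
    if K < 2:
        raise ValueError("K must be at least 2")
    _check_eps(eps)
    if r < 0 and -1.0 / r < FRECHET_LAMBDA:
        # Extreme-exponent regime: the GMP is min(p) * K^{-1/r} up to a
        # vanishing correction, and Pr(min p <= t) = 1 - (1 - t)^K exactly,
        # recovering the Sidak threshold in the r -> -inf limit.
        psi = (1.0 - (1.0 - eps) ** (1.0 / K)) * K ** (-1.0 / r)
        return ThresholdResult(method="gclt", r=r, K=K, eps=eps, psi=float(min(psi, 1.0)))
    coef = gclt_coefficients(r, K)
    if r < 0:
        q = stable_quantile(coef.lam, 1.0 - eps)
        y = coef.a + coef.b * q
        psi = (y / K) ** (1.0 / r)
    else:
        q = stable_quantile(2.0, eps)
        y = coef.a + coef.b * q
        if y <= 0:
            raise ValueError(
                f"GCLT construction broke down: a + b q = {y:g} <= 0 "
                f"for r = {r:g}, K = {K}, eps = {eps:g}"
            )
        psi = (y / K) ** (1.0 / r)
    psi = min(psi, 1.0)
    return ThresholdResult(method="gclt", r=r, K=K, eps=eps, psi=float(psi))


def small_eps_threshold(r: float, K: int, eps: float) -> ThresholdResult:
    """Small-eps limit of the GCLT threshold: Psi = eps * K^{-(1+1/r)}.

    Valid only for r < -1/2 (the genuinely heavy-tailed regime); for
    r >= -1/2 the tail behaviour is Gaussian and the regular-variation
    limit is unreliable, so the request is refused.  At r = -1 the
    threshold is exactly eps (the harmonic mean p-value is directly
    interpretable for small values); as r -> -inf it approaches the
    Bonferroni threshold eps / K.
    """
    if not r < -0.5:
        raise ValueError(
            "small-eps approximation requires r < -1/2; the tail is Gaussian "
            "above that and the approximation is not helpful"
        )
    if K < 2:
        raise ValueError("K must be at least 2")
    _check_eps(eps)
    psi = eps * K ** -(1.0 + 1.0 / r)
    return ThresholdResult(method="gclt-small", r=r, K=K, eps=eps, psi=float(psi))


def rra_multiplier(r: float, K: int) -> float:
    """Slope m of the worst-case (RRA) threshold Psi_RRA = m * eps.

    r < -1: ((r+1)/r) K^{-(1+1/r)}; r = -1: 1/log K; -1 < r (r != 0):
    (r+1)^{-1/r}; r = 0: 1/e (the r -> 0 limit).  As r -> -inf the
    multiplier tends to 1/K, i.e. Bonferroni.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if r < -1:
        return ((r + 1.0) / r) * K ** -(1.0 + 1.0 / r)
    if r == -1:
        return 1.0 / math.log(K)
    if abs(r) <= 1e-12:
        return 1.0 / math.e
    return float((r + 1.0) ** (-1.0 / r))


def rra_threshold(r: float, K: int, eps: float) -> ThresholdResult:
    """Worst-case-dependence (robust risk analysis) threshold for the GMP.

    Valid under arbitrary dependence, and asymptotically precise: for each
    eps some dependence structure attains the bound.
    """
    _check_eps(eps)
    psi = rra_multiplier(r, K) * eps
    return ThresholdResult(method="rra", r=r, K=K, eps=eps, psi=float(psi))


def _as_psi(t) -> float:
    return t.psi if isinstance(t, ThresholdResult) else float(t)


def fpr_under_independence(t, r: float, K: int) -> float:
    """False positive rate of threshold ``t`` under independent uniforms.

    Inverts the GCLT map: returns the eps solving
    gclt_threshold(r, K, eps).psi = t, using the stable CDF at
    z = (K t^r - a)/b (upper tail for r < 0, lower for r > 0).  Applied to
    an RRA threshold this measures how conservative the worst-case bound is
    when the tests happen to be independent.
    """
    psi = _as_psi(t)
    if not 0 < psi < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if r < 0 and -1.0 / r < FRECHET_LAMBDA:
        t_min = psi * K ** (1.0 / r)
        return 1.0 - (1.0 - t_min) ** K
    coef = gclt_coefficients(r, K)
    z = (K * psi**r - coef.a) / coef.b
    if r < 0:
        return stable_sf(coef.lam, z)
    return stable_cdf(2.0, z)


def fpr_worst_case(t, r: float, K: int) -> float:
    """Worst-case false positive rate of threshold ``t`` under dependence.

    Inverts the RRA map, taking the RRA bounds as precise: since
    Psi_RRA = m * eps, the threshold t corresponds to worst-case rate
    min(1, t / m).  Applied to a GCLT threshold this quantifies its
    inflation under adversarial dependence.
    """
    psi = _as_psi(t)
    if not 0 < psi < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return min(1.0, psi / rra_multiplier(r, K))


@dataclass(frozen=True)
class TestDecision:
    """Outcome of a classical combined test at level eps."""

    method: str
    statistic: float
    threshold: float
    reject: bool
    combined_p: float | None = None


def bonferroni(p, eps: float) -> TestDecision:
    """Bonferroni: reject iff min p <= eps / K.  Valid under arbitrary dependence."""
    arr = validate_pvalues(p)
    thr = eps / arr.size
    stat = float(arr.min())
    return TestDecision("bonferroni", stat, thr, stat <= thr,
                        combined_p=min(1.0, stat * arr.size))


def sidak(p, eps: float) -> TestDecision:
    """Sidak: reject iff min p <= 1 - (1 - eps)^{1/K}.  Assumes independence."""
    arr = validate_pvalues(p)
    thr = 1.0 - (1.0 - eps) ** (1.0 / arr.size)
    stat = float(arr.min())
    return TestDecision("sidak", stat, thr, stat <= thr,
                        combined_p=min(1.0, 1.0 - (1.0 - stat) ** arr.size))


def simes(p, eps: float) -> TestDecision:
    """Simes: reject iff min_i K p_(i) / i <= eps.  Valid under positive dependence."""
    arr = np.sort(validate_pvalues(p))
    k = arr.size
    stat = float(np.min(k * arr / np.arange(1, k + 1)))
    return TestDecision("simes", stat, eps, stat <= eps, combined_p=min(1.0, stat))


def fisher(p, eps: float) -> TestDecision:
    """Fisher: -2 sum log p against chi-squared with 2K df.  Assumes independence."""
    arr = validate_pvalues(p)
    stat = float(-2.0 * np.log(arr).sum())
    combined = float(stats.chi2.sf(stat, 2 * arr.size))
    return TestDecision("fisher", stat, float(stats.chi2.isf(eps, 2 * arr.size)),
                        combined <= eps, combined_p=combined)


def combine(p, r: float, eps: float, method: str = "gclt") -> dict:
    """One-shot combined GMP test: statistic, threshold and decision.

    ``method`` selects the threshold family: ``gclt``, ``gclt-small`` or
    ``rra``.  Returns a plain dict suitable for JSON serialization.
    """
    arr = validate_pvalues(p)
    gmp = compute_gmp(arr, r)
    k = arr.size
    if method == "gclt":
        res = gclt_threshold(r, k, eps)
    elif method in ("gclt-small", "gclt_small"):
        res = small_eps_threshold(r, k, eps)
    elif method == "rra":
        res = rra_threshold(r, k, eps)
    else:
        raise ValueError(f"unknown threshold method: {method!r}")
    return {
        "method": res.method,
        "r": r,
        "K": k,
        "eps": eps,
        "gmp": gmp,
        "psi": res.psi,
        "reject": bool(gmp <= res.psi),
    }
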