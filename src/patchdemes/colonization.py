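"""Likelihood inference of patch colonization rate and founder-group size.

The generative model: colonization events arrive on each patch as a Poisson
process with mean ``lambda_c`` events per patch lifetime, and each event
delivers a zero-truncated Poisson number of dauer founders with parameter
``lambda_d``.  Two observables identify the parameters:

* the fraction of *empty* patches, Binomial(n, e^{-lambda_c}), identifies
  lambda_c;
* the fraction of occupied patches holding *exactly one* worm — patches
  that received one colonization delivering one dauer — constrains
  (lambda_c, lambda_d) jointly along a likelihood ridge, with success
  probability

      p = lambda_c * lambda_d / ((e^{lambda_c} - 1) (e^{lambda_d} - 1)),

  the product of the two zero-truncated single-event probabilities.

Confidence intervals are profile-likelihood intervals at a 1.92-log drop
(half the 95% quantile of chi-square with 1 df).
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import gammaln

from patchdemes.records import OccupancySummary, RateEstimate, RidgePoint

#: Search domain for scalar rate maximization.
_RATE_LO, _RATE_HI = 1e-8, 50.0
_TOL = 1e-8

#: Half the chi-square(1) 95% quantile: the 1-parameter profile-CI drop.
DEFAULT_DROP = 1.92


def _log_binom(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def loglik_empty(lambda_c: float, summary: OccupancySummary,
                 include_constant: bool = True) -> float:
    """Binomial log-likelihood of the empty-patch count at rate ``lambda_c``.

    With n patches of which k are empty, each patch is empty with
    probability e^{-lambda_c}, so the log-likelihood is
    ``k*(-lambda_c) + (n-k)*log(1 - e^{-lambda_c})`` plus the binomial
    coefficient (included by default so reported maxima are comparable
    across datasets; it does not move the maximizer).
    """
    if lambda_c <= 0:
        raise ValueError("lambda_c must be > 0")
    n, k = summary.n_patches, summary.n_empty
    ll = k * (-lambda_c)
    if n > k:
        ll += (n - k) * math.log(-math.expm1(-lambda_c))
    if include_constant:
        ll += _log_binom(n, k)
    return ll


def estimate_colonization_rate(summary: OccupancySummary,
                               drop: float = DEFAULT_DROP) -> RateEstimate:
    """MLE and profile-likelihood CI of the per-patch colonization rate.

    The MLE has the closed form ``-log(n_empty / n_patches)``; the estimate
    is obtained by bounded scalar maximization (and agrees with the closed
    form to optimizer tolerance).  CI bounds are the two roots of
    ``loglik(lam) = loglik_max - drop`` found by bracketed root-finding.

    Degenerate occupancy (0 or n occupied patches) yields a boundary-flagged
    estimate with a one-sided interval.
    """
    n, k_occ = summary.n_patches, summary.n_occupied
    if k_occ == 0:
        # Likelihood n*(-lam) is maximal as lam -> 0.
        hi = drop / n
        return RateEstimate(mle=0.0, ci_low=0.0, ci_high=hi,
                            loglik_max=0.0, drop_used=drop,
                            method="closed_form", boundary="all_empty")
    if k_occ == n:
        # Likelihood n*log(1-e^-lam) increases without bound in lam.
        lo = -math.log(-math.expm1(-drop / n))
        return RateEstimate(mle=math.nan, ci_low=lo, ci_high=math.inf,
                            loglik_max=0.0, drop_used=drop,
                            method="closed_form", boundary="none_empty")

    res = minimize_scalar(lambda lam: -loglik_empty(lam, summary),
                          bounds=(_RATE_LO, _RATE_HI), method="bounded",
                          options={"xatol": _TOL})
    mle = float(res.x)
    llmax = loglik_empty(mle, summary)

    def shifted(lam: float) -> float:
        return loglik_empty(lam, summary) - (llmax - drop)

    lo = brentq(shifted, _RATE_LO, mle, xtol=_TOL)
    hi_bracket = mle + 1.0
    while shifted(hi_bracket) > 0 and hi_bracket < _RATE_HI:
        hi_bracket += 1.0
    hi = brentq(shifted, mle, hi_bracket, xtol=_TOL)
    return RateEstimate(mle=mle, ci_low=float(lo), ci_high=float(hi),
                        loglik_max=llmax, drop_used=drop, method="brent")


def rate_from_occupancy_fraction(fraction_occupied: float) -> float:
    """Poisson rate whose zero class matches an occupancy *fraction*.

    ``-log(1 - fraction)``; used when only a percentage of occupied patches
    is available rather than raw counts.
    """
    if not 0 <= fraction_occupied < 1:
        raise ValueError("fraction_occupied must be in [0, 1)")
    return -math.log1p(-fraction_occupied)


def zt_poisson_mean(lambda_d: float) -> float:
    """Mean of the zero-truncated Poisson: lambda / (1 - e^{-lambda}).

    Continuous at the origin with limit 1 (a vanishing rate conditioned on
    at least one arrival always delivers exactly one).
    """
    if lambda_d < 0:
        raise ValueError("lambda_d must be >= 0")
    if lambda_d == 0:
        return 1.0
    return lambda_d / -math.expm1(-lambda_d)


def zt_rate_from_mean(mean_founders: float) -> float:
    """Invert ``zt_poisson_mean``: the Poisson rate with a given ZT mean."""
    if mean_founders < 1:
        raise ValueError("a zero-truncated Poisson mean is >= 1")
    if mean_founders == 1:
        return 0.0
    hi = mean_founders + 5.0
    return float(brentq(lambda lam: zt_poisson_mean(lam) - mean_founders,
                        1e-12, hi, xtol=1e-12))


def p_single(lambda_c: float, lambda_d: float) -> float:
    """P(an occupied patch holds exactly one worm).

    Product of the zero-truncated probabilities of a single colonization
    event and of a single dauer in its founder group:
    ``lambda_c * lambda_d / ((e^{lambda_c}-1)(e^{lambda_d}-1))``.
    """
    if lambda_c <= 0 or lambda_d <= 0:
        raise ValueError("rates must be > 0")
    return (lambda_c * lambda_d
            / (math.expm1(lambda_c) * math.expm1(lambda_d)))


def _single_loglik(lambda_d: float, lambda_c: float,
                   n_occupied: int, n_single: int) -> float:
    p = p_single(lambda_c, lambda_d)
    return (_log_binom(n_occupied, n_single)
            + n_single * math.log(p)
            + (n_occupied - n_single) * math.log1p(-p))


def profile_dauer_rate(summary: OccupancySummary,
                       lambda_c: float) -> RidgePoint:
    """Conditional MLE of the founder-group rate at fixed ``lambda_c``.

    Maximizes the binomial likelihood of ``n_single`` single-worm patches
    among ``n_occupied`` occupied ones over lambda_d.  Because
    lambda_d / (e^{lambda_d} - 1) is strictly decreasing, the interior
    optimum solves

        lambda_d / (e^{lambda_d} - 1)
            = (n_single/n_occupied) * (e^{lambda_c} - 1) / lambda_c,

    attainable only when the right side is < 1; otherwise the likelihood is
    maximal at the lambda_d -> 0 boundary (flagged ``"no_solution"``).
    """
    if lambda_c <= 0:
        raise ValueError("lambda_c must be > 0")
    n_occ, n_one = summary.n_occupied, summary.n_single
    if not 0 < n_one < n_occ:
        raise ValueError("need 0 < n_single < n_occupied for a profile MLE")
    target = (n_one / n_occ) * math.expm1(lambda_c) / lambda_c
    if target >= 1.0:
        # Even one-dauer groups cannot make single-worm patches this common.
        return RidgePoint(lambda_c=lambda_c, lambda_d_hat=0.0,
                          expected_founders=1.0,
                          loglik=_single_loglik(1e-10, lambda_c, n_occ, n_one),
                          boundary="no_solution")
    res = minimize_scalar(
        lambda ld: -_single_loglik(ld, lambda_c, n_occ, n_one),
        bounds=(_RATE_LO, _RATE_HI), method="bounded",
        options={"xatol": _TOL})
    ld_hat = float(res.x)
    return RidgePoint(lambda_c=lambda_c, lambda_d_hat=ld_hat,
                      expected_founders=zt_poisson_mean(ld_hat),
                      loglik=_single_loglik(ld_hat, lambda_c, n_occ, n_one))


def joint_ridge(summary: OccupancySummary,
                lambda_c_grid: Sequence[float],
                region_drop: float = 3.0
                ) -> Tuple[List[RidgePoint], np.ndarray]:
    """Profile the founder-group likelihood along a grid of lambda_c.

    Returns the ridge points and a boolean mask flagging grid points whose
    profile log-likelihood lies within ``region_drop`` of the global maximum
    (3.0 approximates the joint 95% region for two parameters, chi-square
    with 2 df).
    """
    grid = list(lambda_c_grid)
    if not grid:
        raise ValueError("lambda_c_grid must be non-empty")
    points = [profile_dauer_rate(summary, lc) for lc in grid]
    logliks = np.array([pt.loglik for pt in points])
    mask = logliks >= logliks.max() - region_drop
    return points, mask


def ridge_quadratic_fit(points: Sequence[RidgePoint]) -> np.ndarray:
    """Least-squares quadratic of expected founders against lambda_c.

    Returns ``(a0, a1, a2)`` for E[n_d] ~ a0 + a1*lambda_c + a2*lambda_c^2,
    a compact description of the likelihood ridge.
    """
    x = np.array([pt.lambda_c for pt in points])
    y = np.array([pt.expected_founders for pt in points])
    design = np.vstack([np.ones_like(x), x, x * x]).T
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def multiple_colonization_fraction(lambda_c: float) -> float:
    """P(an occupied patch received >= 2 colonization events).

    ``1 - lambda_c e^{-lambda_c} / (1 - e^{-lambda_c})``; tends to 0 as
    colonizations become rare and to 1 as they become common.
    """
    if lambda_c <= 0:
        raise ValueError("lambda_c must be > 0")
    return 1.0 - lambda_c * math.exp(-lambda_c) / -math.expm1(-lambda_c)
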