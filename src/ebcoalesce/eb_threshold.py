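"""Empirical Bayes thresholding under a point-mass/Laplace mixture prior.

A coefficient observed with unit Gaussian noise, ``z ~ N(mu, 1)``, is modelled
with the mixture prior

    mu ~ (1 - w) * delta_0 + w * Laplace(a),

where ``Laplace(a)`` has density ``(a/2) exp(-a|u|)``.  The posterior median
of ``mu`` is an exact-zero thresholding rule with bounded shrinkage for large
``|z|``; it is the workhorse behind both the sparse-loading penalty used when
coalescing SNPs and the coordinate update of the variable-selection fit.

All tail quantities are evaluated in log space (``log_ndtr`` / ``ndtri_exp``)
so that observations up to ``|z| ~ 40`` and beyond are handled without
overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "MixturePrior",
    "ShrinkageResult",
    "laplace_marginal_density",
    "log_laplace_marginal",
    "posterior_nonzero_prob",
    "posterior_median",
    "posterior_median_array",
    "threshold",
    "conditional_mode_w",
    "conditional_mode_a",
    "A_MIN_DEFAULT",
    "A_MAX_DEFAULT",
    "W_FLOOR",
    "W_CEIL",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: Default bounds keeping the Laplace scale identifiable.
A_MIN_DEFAULT = 0.05
A_MAX_DEFAULT = 3.0

#: Hard floor/ceiling for the mixture weight (callers usually pass 1/p).
W_FLOOR = 1e-6
W_CEIL = 1.0 - 1e-6


@dataclass(frozen=True)
class MixturePrior:
    """Mixture prior: point mass at zero with weight ``1 - w`` plus a
    Laplace slab of scale ``a`` with weight ``w``.

    Parameters
    ----------
    w : float
        Prior probability that a coefficient is nonzero, in ``[0, 1]``.
    a : float
        Scale of the Laplace component ``(a/2) exp(-a|u|)``, strictly
        positive.
    """

    w: float
    a: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.w <= 1.0):
            raise ValueError(f"mixture weight w must be in [0, 1], got {self.w}")
        if not (self.a > 0.0) or not math.isfinite(self.a):
            raise ValueError(f"Laplace scale a must be positive and finite, got {self.a}")


@dataclass(frozen=True)
class ShrinkageResult:
    """Posterior-median estimate together with the nonzero probability."""

    estimate: float
    prob_nonzero: float


def _log_phi(z: np.ndarray | float) -> np.ndarray | float:
    return -0.5 * np.square(z) - _LOG_SQRT_2PI


def log_laplace_marginal(z, a: float):
    """``log g(z)`` where ``g`` is the Laplace density convolved with the
    standard normal density.

    Closed form (symmetric in ``z``)::

        g(z) = (a/2) [ e^{a^2/2 - a z} Phi(z - a) + e^{a^2/2 + a z} Phi(-z - a) ]

    evaluated through ``log_ndtr`` so each exponent is formed before
    exponentiation.
    """
    if not (a > 0.0) or not math.isfinite(a):
        raise ValueError(f"Laplace scale a must be positive and finite, got {a}")
    az = np.abs(np.asarray(z, dtype=float))
    half_a2 = 0.5 * a * a
    t1 = half_a2 - a * az + special.log_ndtr(az - a)
    t2 = half_a2 + a * az + special.log_ndtr(-az - a)
    out = math.log(a / 2.0) + np.logaddexp(t1, t2)
    if np.isscalar(z):
        return float(out)
    return out


def laplace_marginal_density(z, a: float):
    """Marginal density ``g(z) = (Laplace(a) * N(0,1))(z)`` of an
    observation whose mean is drawn from the Laplace slab."""
    return np.exp(log_laplace_marginal(z, a)) if not np.isscalar(z) else float(
        math.exp(log_laplace_marginal(z, a))
    )


def _log_posterior_odds(z: np.ndarray, prior: MixturePrior) -> np.ndarray:
    logg = log_laplace_marginal(z, prior.a)
    logphi = _log_phi(z)
    return special.logit(prior.w) + logg - logphi


def posterior_nonzero_prob(z, prior: MixturePrior):
    """Posterior probability that the mean behind ``z`` is nonzero:
    ``w g(z) / (w g(z) + (1 - w) phi(z))``; monotone nondecreasing in
    ``|z|``."""
    if prior.w == 0.0:
        return np.zeros_like(np.asarray(z, dtype=float)) if not np.isscalar(z) else 0.0
    if prior.w == 1.0:
        return np.ones_like(np.asarray(z, dtype=float)) if not np.isscalar(z) else 1.0
    za = np.asarray(z, dtype=float)
    out = special.expit(_log_posterior_odds(za, prior))
    return float(out) if np.isscalar(z) else out


def _median_core(z: np.ndarray, prior: MixturePrior) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized posterior median; returns (estimate, prob_nonzero).

    For ``z >= 0`` the median is the root ``m`` of ``P * T(m) = 1/2`` where
    ``T(m)`` is the upper tail of the slab part of the posterior beyond
    ``m``:

        T(m) = (a/2) e^{a^2/2 - a z} Phi(z - a - m) / g(z),

    which inverts in closed form through ``ndtri_exp``.  ``m <= 0`` (or no
    root) means the point mass straddles the half-way mark and the median is
    exactly zero.
    """
    a = prior.a
    az = np.abs(z)
    sign = np.sign(z)
    if prior.w == 0.0:
        return np.zeros_like(az), np.zeros_like(az)

    logg = log_laplace_marginal(az, a)
    if prior.w == 1.0:
        log_p = np.zeros_like(az)
    else:
        log_p = special.log_expit(_log_posterior_odds(az, prior))

    # c = log Phi(z - a - m) at the root
    c = math.log(0.5) - log_p - math.log(a / 2.0) - 0.5 * a * a + a * az + logg
    with np.errstate(invalid="ignore"):
        root = az - a - special.ndtri_exp(np.minimum(c, 0.0))
    est = np.where(c < 0.0, np.maximum(root, 0.0), 0.0)
    est = np.minimum(est, az)  # shrinkage can never amplify
    return sign * est, np.exp(log_p)


def posterior_median(z: float, prior: MixturePrior) -> ShrinkageResult:
    """Median of the posterior of the mean given ``z ~ N(mean, 1)``.

    Antisymmetric and monotone in ``z``; exactly zero for
    ``|z| <= threshold(prior)``.
    """
    est, prob = _median_core(np.asarray(float(z)), prior)
    return ShrinkageResult(estimate=float(est), prob_nonzero=float(prob))


def posterior_median_array(z: np.ndarray, prior: MixturePrior) -> np.ndarray:
    """Entrywise :func:`posterior_median` estimates for an array of
    observations."""
    est, _ = _median_core(np.asarray(z, dtype=float), prior)
    return est


def threshold(prior: MixturePrior, tol: float = 1e-8) -> float:
    """Smallest ``z >= 0`` at which the posterior median becomes nonzero.

    Returns ``inf`` when ``w == 0`` (the prior carries no signal mass) and
    ``0`` when ``w == 1``.  Found by bisection to ``tol``.
    """
    if prior.w == 0.0:
        return math.inf
    if prior.w == 1.0:
        return 0.0

    hi = 1.0
    while posterior_median(hi, prior).estimate == 0.0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - unreachable for w >= W_FLOOR
            return math.inf
    lo = 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if posterior_median(mid, prior).estimate > 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def conditional_mode_w(
    beta: np.ndarray,
    *,
    alpha: float = 1.0,
    beta_shape: float = 1.0,
    w_min: float = W_FLOOR,
    w_max: float = W_CEIL,
) -> float:
    """Mode of the full conditional of the mixture weight given the current
    coefficient vector.

    The conditional is ``w^k (1-w)^{p-k}`` times a ``Beta(alpha, beta_shape)``
    hyperprior (``alpha = beta_shape = 1`` is flat, mode ``k/p``); the result
    is clamped to ``[w_min, w_max]``.
    """
    b = np.asarray(beta, dtype=float)
    if b.size == 0:
        raise ValueError("beta must be non-empty")
    if not np.all(np.isfinite(b)):
        raise ValueError("beta must be finite")
    k = int(np.count_nonzero(b))
    p = b.size
    denom = p + alpha + beta_shape - 2.0
    if denom <= 0.0:
        mode = k / p
    else:
        mode = (k + alpha - 1.0) / denom
    return float(min(max(mode, w_min), w_max))


def conditional_mode_a(
    beta: np.ndarray,
    sigma: float = 1.0,
    *,
    a_current: float = 0.5,
    shape: float = 1.0,
    rate: float = 0.0,
    a_min: float = A_MIN_DEFAULT,
    a_max: float = A_MAX_DEFAULT,
) -> float:
    """Mode of the full conditional of the Laplace scale.

    With ``k`` nonzero coefficients and ``S = sum |beta_j| / sigma`` over
    them, the flat-hyperprior mode is ``k/S``; a ``Gamma(shape, rate)``
    hyperprior shifts it to ``(k + shape - 1) / (S + rate)``.  Clamped to
    ``[a_min, a_max]``; with ``k == 0`` the current value ``a_current`` is
    returned unchanged.
    """
    b = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(b)):
        raise ValueError("beta must be finite")
    if sigma <= 0.0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    nz = b[b != 0.0]
    k = nz.size
    if k == 0:
        return float(a_current)
    s = float(np.sum(np.abs(nz)) / sigma)
    num = k + shape - 1.0
    denom = s + rate
    if denom <= 0.0 or num <= 0.0:
        return float(a_max if denom <= 0.0 else a_min)
    return float(min(max(num / denom, a_min), a_max))
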