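"""Closed-form mathematics of the generalized normal distribution (gNDF).

The generalized normal distribution (also called the exponential power or
generalized Gaussian family) interpolates, through its shape exponent
``beta``, between the Laplace (``beta = 1``), the Gaussian (``beta = 2``)
and, in the limit ``beta -> inf``, a flat-topped profile with Heaviside
edges of half-width ``sigma``.  A nanopore current blockade is modelled as

    I(t) = I_O + dI_B * exp(-(|t - mu| / sigma) ** beta)

where ``I_O`` is the open-pore current, ``dI_B`` the (signed) current
difference caused by the blockade, ``mu`` the event localization in time,
``sigma`` the scale and ``beta`` the shape.  Because the kernel reaches
exactly 1 at ``t = mu``, ``I_O + dI_B`` is the blockade plateau current.

Everything in this module is pure, vectorized math; all distribution
quantities (PDF, CDF, quantile, full width at half maximum) are exact
closed forms built on the (regularized) lower incomplete gamma function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "BETA_MAX_DEFAULT",
    "GNDFShape",
    "GNDFParams",
    "kernel",
    "pdf",
    "cdf",
    "quantile",
    "fwhm",
    "event_model",
]

#: Largest shape exponent treated as distinguishable from a rectangular
#: pulse.  Above this the kernel edges are steeper than any realistic
#: band-limited acquisition chain can produce, and shape-derived
#: quantities such as the per-event sampling frequency are undefined.
BETA_MAX_DEFAULT = 500.0

# beta * ln(|x-mu|/sigma) beyond this would overflow exp(); the kernel
# underflows to exactly 0 there.
_LOG_OVERFLOW = 700.0


@dataclass(frozen=True)
class GNDFShape:
    """Location/scale/shape triplet of the generalized normal distribution.

    Parameters
    ----------
    mu : float
        Location (event localization), seconds.
    sigma : float
        Scale, seconds.  Must be strictly positive.
    beta : float
        Shape exponent, dimensionless.  Must be >= 1; values below 1
        produce a cusped kernel that no band-limited pulse can exhibit.
    """

    mu: float
    sigma: float
    beta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be positive and finite, got {self.sigma}")
        if not (np.isfinite(self.beta) and self.beta >= 1):
            raise ValueError(f"beta must be >= 1 and finite, got {self.beta}")


@dataclass(frozen=True)
class GNDFParams:
    """Five-parameter description of a single-level nanopore blockade.

    Parameters
    ----------
    i_open : float
        Open-pore current ``I_O``, pA.
    di_b : float
        Signed current difference ``dI_B`` of the blockade plateau relative
        to the open pore, pA.  Negative for blockades (the usual case),
        positive for current enhancements.
    mu, sigma, beta : float
        Location (s), scale (s) and shape of the event profile.
    beta_max : float
        Upper bound of the physically meaningful shape domain; fits pinned
        here are treated as rectangular.
    """

    i_open: float
    di_b: float
    mu: float
    sigma: float
    beta: float
    beta_max: float = field(default=BETA_MAX_DEFAULT, compare=False)

    def __post_init__(self) -> None:
        # reuse the shape validation
        GNDFShape(self.mu, self.sigma, self.beta)
        if not np.isfinite(self.i_open) or not np.isfinite(self.di_b):
            raise ValueError("i_open and di_b must be finite")
        if self.beta > self.beta_max:
            raise ValueError(
                f"beta={self.beta} exceeds beta_max={self.beta_max}"
            )
        plateau = self.i_open + self.di_b
        if self.i_open != 0 and (
            plateau * self.i_open < 0 or abs(self.di_b) > abs(self.i_open)
        ):
            warnings.warn(
                "event plateau current crosses zero or exceeds the open-pore "
                f"current (i_open={self.i_open}, di_b={self.di_b}); "
                "not a physical blockade",
                stacklevel=2,
            )

    @property
    def shape(self) -> GNDFShape:
        return GNDFShape(self.mu, self.sigma, self.beta)


def _as_shape(shape) -> GNDFShape:
    if isinstance(shape, GNDFParams):
        return shape.shape
    if isinstance(shape, GNDFShape):
        return shape
    raise TypeError(f"expected GNDFShape or GNDFParams, got {type(shape)!r}")


def _z(x, shape: GNDFShape):
    """(|x - mu| / sigma) ** beta, computed in log space to dodge overflow."""
    r = np.abs(np.asarray(x, dtype=float) - shape.mu) / shape.sigma
    with np.errstate(divide="ignore"):
        t = shape.beta * np.log(r)  # -inf at r == 0 is fine: exp -> 0
    return np.exp(np.minimum(t, _LOG_OVERFLOW))


def kernel(x, shape):
    """Unnormalized event profile ``exp(-(|x - mu| / sigma) ** beta)``.

    Equals 1 exactly at ``x = mu``, is symmetric about ``mu`` and decreases
    monotonically in ``|x - mu|``; underflows to exactly 0 where the
    exponent would overflow.
    """
    shape = _as_shape(shape)
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("kernel requires finite x")
    t = shape.beta * _safe_log_ratio(x, shape)
    out = np.where(t > _LOG_OVERFLOW, 0.0, np.exp(-np.exp(np.minimum(t, _LOG_OVERFLOW))))
    return out if out.ndim else float(out)


def _safe_log_ratio(x, shape: GNDFShape):
    r = np.abs(x - shape.mu) / shape.sigma
    with np.errstate(divide="ignore"):
        return np.log(r)


def pdf(x, shape):
    """Probability density ``beta / (2 sigma Gamma(1/beta)) * kernel(x)``."""
    shape = _as_shape(shape)
    norm = shape.beta / (2.0 * shape.sigma * special.gamma(1.0 / shape.beta))
    return norm * kernel(x, shape)


def cdf(x, shape):
    """Cumulative distribution function of the gNDF.

    ``1/2 + sign(x - mu)/2 * P(1/beta, (|x - mu| / sigma) ** beta)`` where
    ``P`` is the regularized lower incomplete gamma function
    ``gamma(a, z) / Gamma(a)``.

    At large ``beta`` the argument ``z`` underflows double precision long
    before ``P`` becomes negligible (``P ~ z**(1/beta) / Gamma(1 + 1/beta)``
    for small ``z``), so that regime is evaluated in log space.
    """
    shape = _as_shape(shape)
    x = np.asarray(x, dtype=float)
    a = 1.0 / shape.beta
    logz = shape.beta * _safe_log_ratio(x, shape)
    with np.errstate(over="ignore"):
        z = np.exp(np.minimum(logz, _LOG_OVERFLOW))
    small = logz < -46.0  # z < ~1e-20: leading series term to 1e-12
    p_small = np.exp(a * np.where(small, logz, 0.0) - special.gammaln(1.0 + a))
    p = np.where(small, p_small, special.gammainc(a, np.where(small, 1.0, z)))
    out = 0.5 + np.sign(x - shape.mu) * 0.5 * p
    return out if out.ndim else float(out)


def quantile(p, shape):
    """Quantile function (inverse CDF) of the gNDF.

    ``mu + sign(p - 1/2) * sigma * [P^{-1}(1/beta, |2p - 1|)] ** (1/beta)``
    with ``P^{-1}`` the inverse of the regularized lower incomplete gamma
    function in its second argument.  Exact inverse of :func:`cdf`.
    """
    shape = _as_shape(shape)
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("quantile requires 0 < p < 1")
    a = 1.0 / shape.beta
    q = np.abs(2.0 * p - 1.0)
    # mirror of the cdf's small-z regime: at large beta the incomplete-gamma
    # argument underflows for small q, but its a-th power q*Gamma(1+a) does not
    with np.errstate(divide="ignore"):
        logz = (np.log(q) + special.gammaln(1.0 + a)) / a
    small = logz < -690.0
    r_small = np.exp(a * np.where(small, logz, 0.0))
    r = np.where(
        small,
        r_small,
        np.power(special.gammaincinv(a, np.where(small, 0.5, q)), a),
    )
    r = np.where(q == 0.0, 0.0, r)
    out = shape.mu + np.sign(p - 0.5) * shape.sigma * r
    return out if out.ndim else float(out)


def fwhm(shape) -> float:
    """Full width at half maximum of the kernel: ``2 sigma (ln 2)**(1/beta)``."""
    shape = _as_shape(shape)
    return 2.0 * shape.sigma * np.log(2.0) ** (1.0 / shape.beta)


def event_model(x, params: GNDFParams):
    """Five-parameter blockade model ``I_O + dI_B * kernel(x; mu, sigma, beta)``.

    Tends to ``I_O`` far from the event, equals ``I_O + dI_B`` at the
    localization, is Gaussian-profiled at ``beta = 2`` and approaches a
    rectangular pulse of half-width ``sigma`` as ``beta`` grows.
    """
    return params.i_open + params.di_b * kernel(x, params.shape)
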