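"""Probabilistic core: Gamma marginals, Gaussian copula, zero-inflated joint law.

The Gamma marginal is parametrized by its mean ``mu`` and coefficient of
variation ``sigma`` (shape ``1/sigma**2``, scale ``mu*sigma**2``), so that
``E(W) = mu`` and ``Var(W) = sigma**2 * mu**2``.  Non-zero expression pairs
are joined by a Gaussian copula with correlation ``rho``; exact zeros are
produced by independent Bernoulli "off" masks with rates ``p1`` and ``p2``.

The log-likelihood returned by :func:`cell_loglik` deliberately drops the
additive constant that depends only on ``(p1, p2)``: estimation of the five
copula-side parameters is decoupled from the zero-inflation rates, which are
fitted separately by logistic regression on the zero indicators.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import special

from .types import CellObservation, CellParams, GammaParam

# Floor applied to Gamma-CDF values before the normal quantile transform;
# keeps Phi^{-1}(u) finite without visibly perturbing the likelihood.
U_EPS = 1e-12
# |rho| is kept strictly below 1 so that 1 - rho**2 never underflows.
RHO_EPS = 1e-8


def _check_gamma_args(w, mu, sigma, allow_zero_w: bool = False) -> None:
    w, mu, sigma = np.asarray(w), np.asarray(mu), np.asarray(sigma)
    if np.any(mu <= 0) or np.any(sigma <= 0):
        raise ValueError("mu and sigma must be positive")
    if allow_zero_w:
        if np.any(w < 0):
            raise ValueError("w must be non-negative")
    elif np.any(w <= 0):
        raise ValueError("w must be positive")


def _unpack(par) -> tuple:
    """Accept GammaParam or (mu, sigma)."""
    if isinstance(par, GammaParam):
        return np.asarray(par.mu), np.asarray(par.sigma)
    mu, sigma = par
    return np.asarray(mu), np.asarray(sigma)


def gamma_logpdf(w, mu, sigma):
    """Log density of the (mu, sigma)-parametrized Gamma, vectorized."""
    w = np.asarray(w, dtype=float)
    shape = 1.0 / np.asarray(sigma, dtype=float) ** 2
    scale = np.asarray(mu, dtype=float) * np.asarray(sigma, dtype=float) ** 2
    return (special.xlogy(shape - 1.0, w) - w / scale
            - special.xlogy(shape, scale) - special.gammaln(shape))


def gamma_pdf(w, par):
    """Gamma density with mean ``mu`` and coefficient of variation ``sigma``."""
    mu, sigma = _unpack(par)
    _check_gamma_args(w, mu, sigma)
    return np.exp(gamma_logpdf(w, mu, sigma))


def gamma_cdf(w, par):
    """Gamma CDF: regularized lower incomplete gamma at (1/sigma^2, w/(mu sigma^2))."""
    mu, sigma = _unpack(par)
    _check_gamma_args(w, mu, sigma, allow_zero_w=True)
    w = np.asarray(w, dtype=float)
    return special.gammainc(1.0 / sigma**2, w / (mu * sigma**2))


def gamma_ppf(u, par):
    """Quantile function of the (mu, sigma)-parametrized Gamma."""
    mu, sigma = _unpack(par)
    if np.any(mu <= 0) or np.any(sigma <= 0):
        raise ValueError("mu and sigma must be positive")
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("u must lie in [0, 1]")
    return special.gammaincinv(1.0 / sigma**2, u) * (mu * sigma**2)


def _check_rho(rho) -> None:
    if np.any(np.abs(np.asarray(rho)) >= 1):
        raise ValueError("|rho| must be < 1")


def gaussian_copula_logdensity(u1, u2, rho):
    """Log of the Gaussian copula density c(u1, u2; rho) (no domain checks)."""
    q1 = special.ndtri(np.clip(u1, U_EPS, 1.0 - U_EPS))
    q2 = special.ndtri(np.clip(u2, U_EPS, 1.0 - U_EPS))
    r = np.clip(rho, -1.0 + RHO_EPS, 1.0 - RHO_EPS)
    om = 1.0 - r**2
    return -0.5 * np.log(om) - (r**2 * (q1**2 + q2**2) - 2.0 * r * q1 * q2) / (2.0 * om)


def gaussian_copula_density(u1, u2, rho):
    """Gaussian copula density phi2(q1, q2; rho) / (phi(q1) phi(q2)).

    Symmetric in (u1, u2), identically 1 at rho = 0.
    """
    _check_rho(rho)
    u1, u2 = np.asarray(u1, dtype=float), np.asarray(u2, dtype=float)
    if np.any((u1 <= 0) | (u1 >= 1) | (u2 <= 0) | (u2 >= 1)):
        raise ValueError("u1, u2 must lie strictly inside (0, 1)")
    return np.exp(gaussian_copula_logdensity(u1, u2, rho))


# 48-point Gauss-Legendre rule; gives the bivariate normal CDF via Plackett's
# identity to ~1e-15, deterministically.
_GL_NODES, _GL_WEIGHTS = leggauss(48)


def bvn_cdf(h, k, rho):
    """Bivariate standard normal CDF Phi2(h, k; rho).

    Uses Plackett's formula: Phi2 = Phi(h)Phi(k) +
    (1/2pi) * integral_0^rho exp(-(h^2 - 2 r h k + k^2)/(2(1-r^2))) / sqrt(1-r^2) dr,
    evaluated with a fixed Gauss-Legendre rule (deterministic, ~1e-14).
    """
    _check_rho(rho)
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    # nodes r = rho/2 * (x + 1), x in (-1, 1)
    r = 0.5 * rho[..., None] * (_GL_NODES + 1.0)
    om = 1.0 - r**2
    hh, kk = h[..., None], k[..., None]
    integrand = np.exp(-(hh**2 - 2.0 * r * hh * kk + kk**2) / (2.0 * om)) / np.sqrt(om)
    integral = 0.5 * rho * (integrand * _GL_WEIGHTS).sum(axis=-1)
    out = special.ndtr(h) * special.ndtr(k) + integral / (2.0 * np.pi)
    return np.clip(out, 0.0, 1.0)


def joint_nonzero_density(w1, w2, par: CellParams):
    """Joint density of the non-zero part: copula density times Gamma margins."""
    f1 = gamma_pdf(w1, par.gene1)
    f2 = gamma_pdf(w2, par.gene2)
    u1 = gamma_cdf(w1, par.gene1)
    u2 = gamma_cdf(w2, par.gene2)
    _check_rho(par.rho)
    return np.exp(gaussian_copula_logdensity(u1, u2, par.rho)) * f1 * f2


def joint_nonzero_cdf(w1, w2, par: CellParams):
    """Gaussian-copula CDF of the non-zero part, C(F1(w1), F2(w2); rho)."""
    u1 = gamma_cdf(w1, par.gene1)
    u2 = gamma_cdf(w2, par.gene2)
    q1 = special.ndtri(np.clip(u1, U_EPS, 1.0 - U_EPS))
    q2 = special.ndtri(np.clip(u2, U_EPS, 1.0 - U_EPS))
    return bvn_cdf(q1, q2, par.rho)


def joint_cdf(y1, y2, par: CellParams):
    """Joint CDF of the zero-inflated pair P(Y1 <= y1, Y2 <= y2).

    Exact zeros carry probability mass p1, p2; the continuous part enters
    through the Gamma margins and their Gaussian-copula joint CDF.  The four
    masses over the zero/non-zero partition sum to one.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if np.any(y1 < 0) or np.any(y2 < 0):
        raise ValueError("y1, y2 must be non-negative")
    p1, p2 = np.asarray(par.p1, float), np.asarray(par.p2, float)
    F1 = np.where(y1 > 0, gamma_cdf(np.maximum(y1, 1e-300), par.gene1), 0.0)
    F2 = np.where(y2 > 0, gamma_cdf(np.maximum(y2, 1e-300), par.gene2), 0.0)
    F12 = np.where((y1 > 0) & (y2 > 0), joint_nonzero_cdf(
        np.maximum(y1, 1e-300), np.maximum(y2, 1e-300), par), 0.0)
    out = (p1 * p2
           + F1 * (1.0 - p1) * p2
           + F2 * p1 * (1.0 - p2)
           + F12 * (1.0 - p1) * (1.0 - p2))
    return out[()] if out.ndim == 0 else out


def zi_copula_loglik(y1, y2, mu1, sigma1, mu2, sigma2, rho):
    """Per-cell copula-side log-likelihood, vectorized over cells.

    Returns the four-case log-likelihood with the additive constant that
    depends only on the zero-inflation rates dropped:

    * both zero          -> 0
    * only y1 non-zero   -> log f_GA(y1)
    * only y2 non-zero   -> log f_GA(y2)
    * both non-zero      -> log c(F1, F2; rho) + log f_GA(y1) + log f_GA(y2)

    Invalid inputs produce -inf rather than raising, so optimizer steps into
    bad regions are rejected instead of crashing.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    mu1, sigma1, mu2, sigma2, rho = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (mu1, sigma1, mu2, sigma2, rho)),
        y1)[:5]
    out = np.zeros(y1.shape, dtype=float)
    m1 = y1 > 0
    m2 = y2 > 0
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        lf1 = np.where(m1, gamma_logpdf(np.where(m1, y1, 1.0), mu1, sigma1), 0.0)
        lf2 = np.where(m2, gamma_logpdf(np.where(m2, y2, 1.0), mu2, sigma2), 0.0)
        out = lf1 + lf2
        both = m1 & m2
        if np.any(both):
            u1 = special.gammainc(1.0 / sigma1[both] ** 2,
                                  y1[both] / (mu1[both] * sigma1[both] ** 2))
            u2 = special.gammainc(1.0 / sigma2[both] ** 2,
                                  y2[both] / (mu2[both] * sigma2[both] ** 2))
            out[both] += gaussian_copula_logdensity(u1, u2, rho[both])
    return out


def cell_loglik(obs, par: CellParams):
    """Copula-side log-likelihood of one cell (additive p-constant dropped).

    ``obs`` may be a :class:`CellObservation` or an ``(y1, y2)`` pair.
    Raises on numerical underflow (non-finite log-likelihood).
    """
    if isinstance(obs, CellObservation):
        y1, y2 = obs.y1, obs.y2
    else:
        y1, y2 = obs
    mu1, sigma1 = _unpack(par.gene1)
    mu2, sigma2 = _unpack(par.gene2)
    _check_rho(par.rho)
    val = zi_copula_loglik(np.atleast_1d(y1), np.atleast_1d(y2),
                           mu1, sigma1, mu2, sigma2, par.rho)
    val = float(val[0])
    if not np.isfinite(val):
        raise FloatingPointError(
            f"log-likelihood underflow at observation (y1={y1}, y2={y2})")
    return val


def total_loglik(data, params):
    """Sum of per-cell log-likelihoods.

    ``data`` is a sequence of CellObservation (or (y1, y2) pairs) and
    ``params`` a matching sequence of CellParams.
    """
    data = list(data)
    params = list(params)
    if len(data) != len(params):
        raise ValueError(
            f"{len(data)} observations but {len(params)} parameter sets")
    return float(sum(cell_loglik(o, p) for o, p in zip(data, params)))
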