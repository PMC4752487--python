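"""Probability mass/density functions and samplers for the generating and
analysis distributions.

Count families
--------------
* Poisson
* negative binomial, parameterized by mean ``m`` and overdispersion ``k``
  so that ``Var = m + m**2 / k`` (``k -> inf`` recovers the Poisson)
* lognormal-Poisson: a Poisson whose rate is multiplied by a lognormal
  latent factor with unit mean (``eps ~ N(-sd^2/2, sd^2)``), evaluated by
  Gauss-Hermite quadrature
* zero-inflated negative binomial: extra point mass ``p_zi`` at zero

Frequency family
----------------
Zero-inflated gamma: a point mass ``p0`` at zero plus a gamma density with
mean ``mu`` and shape ``alpha`` on the positive reals.  The zero mass is
linked to the expectancy through a responsiveness parameter ``g``.  Two
orientations of the link are supported (see :func:`zero_inflation_prob`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "CountFamily",
    "ZiGammaParams",
    "poisson_logpmf",
    "negbinom_logpmf",
    "zinb_logpmf",
    "lognormal_poisson_logpmf",
    "count_logpmf",
    "count_sample",
    "zero_inflation_prob",
    "zi_gamma_logdensity",
    "zi_gamma_loglik",
]

FAMILIES = ("poisson", "negbinom", "lognormal_poisson", "zi_negbinom")

#: default number of Gauss-Hermite nodes for the lognormal-Poisson pmf
GH_NODES = 40


@dataclass(frozen=True)
class CountFamily:
    """A count-data family together with exactly its relevant parameters.

    Parameters
    ----------
    family:
        One of ``poisson``, ``negbinom``, ``lognormal_poisson``,
        ``zi_negbinom``.
    k:
        Overdispersion of the (zero-inflated) negative binomial;
        ``Var = m + m^2/k``.
    sd:
        Log-scale standard deviation of the lognormal-Poisson latent
        multiplier.
    p_zi:
        Zero-inflation mass in ``[0, 1)`` (``zi_negbinom`` only).
    lognormal_mean_one:
        If True (default) the lognormal multiplier has mean 1
        (``eps ~ N(-sd^2/2, sd^2)``) so the rate keeps its expectation
        interpretation; if False the multiplier has median 1.
    """

    family: str
    k: float | None = None
    sd: float | None = None
    p_zi: float | None = None
    lognormal_mean_one: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.family in ("negbinom", "zi_negbinom"):
            if self.k is None or self.k <= 0:
                raise ValueError("negbinom/zi_negbinom require k > 0")
        elif self.k is not None:
            raise ValueError(f"k is not a parameter of {self.family}")
        if self.family == "lognormal_poisson":
            if self.sd is None or self.sd < 0:
                raise ValueError("lognormal_poisson requires sd >= 0")
        elif self.sd is not None:
            raise ValueError(f"sd is not a parameter of {self.family}")
        if self.family == "zi_negbinom":
            if self.p_zi is None or not (0 <= self.p_zi < 1):
                raise ValueError("zi_negbinom requires p_zi in [0, 1)")
        elif self.p_zi is not None:
            raise ValueError(f"p_zi is not a parameter of {self.family}")


@dataclass(frozen=True)
class ZiGammaParams:
    """Zero-inflated gamma parameters.

    ``mu`` is the expectancy of the gamma component (visits per flower per
    observation period), ``shape`` the gamma shape alpha, and ``g`` the
    responsiveness of the zero-inflation probability to the expectancy.
    """

    mu: float
    shape: float
    g: float
    link: str = "corrected"

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.shape <= 0:
            raise ValueError("shape must be > 0")
        if self.link not in ("corrected", "literal"):
            raise ValueError("link must be 'corrected' or 'literal'")


# ---------------------------------------------------------------------------
# log pmf / pdf primitives (vectorized, broadcasting over all arguments)
# ---------------------------------------------------------------------------

def poisson_logpmf(y, m):
    """Poisson log pmf; ``y`` nonnegative integers, ``m`` positive means."""
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    return y * np.log(m) - m - gammaln(y + 1.0)


def negbinom_logpmf(y, m, k):
    """Negative binomial log pmf with mean ``m`` and overdispersion ``k``.

    ``Var = m + m^2/k``; equals the Poisson in the limit ``k -> inf``.
    """
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    k = np.asarray(k, dtype=float)
    # log pmf = C(y+k-1, y) * (k/(k+m))^k * (m/(k+m))^y, written stably
    log_km = np.log(k + m)
    return (
        gammaln(y + k)
        - gammaln(k)
        - gammaln(y + 1.0)
        + k * (np.log(k) - log_km)
        + y * (np.log(m) - log_km)
    )


def zinb_logpmf(y, m, k, p_zi):
    """Zero-inflated negative binomial log pmf (constant inflation mass)."""
    y = np.asarray(y, dtype=float)
    nb = negbinom_logpmf(y, m, k)
    p_zi = np.asarray(p_zi, dtype=float)
    with np.errstate(divide="ignore"):
        log_p = np.log(p_zi)
        log_1mp = np.log1p(-p_zi)
    body = log_1mp + nb
    return np.where(y == 0, np.logaddexp(np.broadcast_to(log_p, body.shape), body), body)


def lognormal_poisson_logpmf(y, m, sd, n_nodes: int = GH_NODES, mean_one: bool = True):
    """Lognormal-Poisson log pmf via Gauss-Hermite quadrature.

    The latent log-rate perturbation is ``eps ~ N(mu0, sd^2)`` with
    ``mu0 = -sd^2/2`` (mean-one multiplier, default) or ``mu0 = 0``
    (median-one).  ``sd = 0`` degenerates to the Poisson.
    """
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    if sd == 0:
        return poisson_logpmf(y, m)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    mu0 = -0.5 * sd**2 if mean_one else 0.0
    eps = mu0 + np.sqrt(2.0) * sd * nodes  # (n_nodes,)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)
    # broadcast: (..., n_nodes)
    terms = poisson_logpmf(y[..., None], m[..., None] * np.exp(eps)) + log_w
    return logsumexp(terms, axis=-1)


def _validate_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if not np.issubdtype(y.dtype, np.number):
        raise ValueError("y must be numeric")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be nonnegative integers")
    return y


def count_logpmf(y, rate, flowers, family: CountFamily):
    """Log pmf of a visit count given a per-flower rate and an exposure.

    The mean is ``m = flowers * rate``.  ``y`` may be a scalar or array.
    """
    y = _validate_counts(y)
    rate = np.asarray(rate, dtype=float)
    flowers = np.asarray(flowers, dtype=float)
    if np.any(rate <= 0) or np.any(flowers <= 0):
        raise ValueError("rate and flowers must be positive")
    m = flowers * rate
    if family.family == "poisson":
        return poisson_logpmf(y, m)
    if family.family == "negbinom":
        return negbinom_logpmf(y, m, family.k)
    if family.family == "zi_negbinom":
        return zinb_logpmf(y, m, family.k, family.p_zi)
    if family.family == "lognormal_poisson":
        return lognormal_poisson_logpmf(y, m, family.sd, mean_one=family.lognormal_mean_one)
    raise AssertionError("unreachable")


def count_sample(rate, flowers, family: CountFamily, rng: np.random.Generator, size=None):
    """Draw visit counts with mean ``flowers * rate`` from ``family``.

    For the lognormal-Poisson a latent multiplier is drawn first so that the
    marginal mean is preserved (mean-one convention, configurable on the
    family).  Broadcasts over ``rate``/``flowers``; ``size`` as in numpy.
    """
    rate = np.asarray(rate, dtype=float)
    flowers = np.asarray(flowers, dtype=float)
    if np.any(rate <= 0) or np.any(flowers <= 0):
        raise ValueError("rate and flowers must be positive")
    m = np.broadcast_to(flowers * rate, np.broadcast_shapes(rate.shape, flowers.shape))
    if size is None:
        size = m.shape
    if family.family == "poisson":
        return rng.poisson(m, size=size)
    if family.family == "negbinom":
        k = family.k
        return rng.negative_binomial(k, k / (k + m), size=size)
    if family.family == "lognormal_poisson":
        sd = family.sd
        mu0 = -0.5 * sd**2 if family.lognormal_mean_one else 0.0
        eps = rng.normal(mu0, sd, size=size)
        return rng.poisson(m * np.exp(eps), size=size)
    if family.family == "zi_negbinom":
        k = family.k
        counts = rng.negative_binomial(k, k / (k + m), size=size)
        zeros = rng.random(size=size) < family.p_zi
        return np.where(zeros, 0, counts)
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# zero-inflated gamma
# ---------------------------------------------------------------------------

def zero_inflation_prob(mu, g, link: str = "corrected"):
    """Probability of the extra point mass at zero as a function of the
    expectancy ``mu`` and the responsiveness ``g``.

    ``link='corrected'`` (default) uses ``p0 = 1 / (1 + e^g mu)``, which is
    monotonically decreasing in ``mu`` (the zero mass grows as the expected
    number of visits shrinks).  ``link='literal'`` uses the increasing form
    ``p0 = e^g mu / (1 + e^g mu)``.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be > 0")
    eta = np.asarray(g, dtype=float) + np.log(mu)
    if link == "corrected":
        return np.exp(-np.logaddexp(0.0, eta))
    if link == "literal":
        return np.exp(eta - np.logaddexp(0.0, eta))
    raise ValueError("link must be 'corrected' or 'literal'")


def _gamma_logpdf(x, log_x, mu, log_mu, alpha, log_alpha):
    """Gamma log pdf with mean ``mu`` and shape ``alpha`` (rate alpha/mu)."""
    return (
        alpha * (log_alpha - log_mu)
        - gammaln(alpha)
        + (alpha - 1.0) * log_x
        - alpha * x / mu
    )


def zi_gamma_loglik(freq, log_mu, eta0, log_shape, link: str = "corrected"):
    """Vectorized zero-inflated gamma log density used by the inference layer.

    Parameters broadcast against the data axis (last axis): ``freq`` is the
    (n,) data vector; ``log_mu`` the per-row log expectancy, ``eta0`` the
    per-row zero-inflation linear predictor (``g`` plus any covariate shift)
    and ``log_shape`` the log gamma shape.
    """
    freq = np.asarray(freq, dtype=float)
    eta = eta0 + log_mu
    # corrected: log p0 = -log(1 + e^eta); literal: log p0 = eta - log(1+e^eta)
    lse = np.logaddexp(0.0, eta)
    if link == "corrected":
        log_p0 = -lse
        log_1mp0 = eta - lse
    elif link == "literal":
        log_p0 = eta - lse
        log_1mp0 = -lse
    else:
        raise ValueError("link must be 'corrected' or 'literal'")
    zero = freq == 0
    safe_log_freq = np.where(zero, 0.0, np.log(np.where(zero, 1.0, freq)))
    alpha = np.exp(log_shape)
    lpdf = _gamma_logpdf(freq, safe_log_freq, np.exp(log_mu), log_mu, alpha, log_shape)
    return np.where(zero, log_p0, log_1mp0 + lpdf)


def zi_gamma_logdensity(freq, params: ZiGammaParams):
    """Log density of the zero-inflated gamma at ``freq`` (>= 0).

    ``freq = 0`` returns ``log p0``; ``freq > 0`` returns
    ``log(1 - p0)`` plus the gamma log density with mean ``params.mu`` and
    shape ``params.shape``.
    """
    freq = np.asarray(freq, dtype=float)
    if np.any(freq < 0):
        raise ValueError("freq must be >= 0")
    return zi_gamma_loglik(
        freq,
        log_mu=np.log(params.mu),
        eta0=params.g,
        log_shape=np.log(params.shape),
        link=params.link,
    )
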