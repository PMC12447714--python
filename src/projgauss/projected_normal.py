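"""The projected normal (angular Gaussian) distribution ``PN(mu, Sigma)``.

A Gaussian vector ``x ~ N(mu, Sigma)`` radially projected onto the unit
sphere, ``y = x / ||x||``, follows the projected normal distribution.  This
module provides:

* :func:`pn_sample` — draw projected samples,
* :func:`pn_pdf` / :func:`pn_logpdf` — the density on the sphere, built on
  the radial-moment recursion :func:`m_recursion`,
* :func:`pn_moments_taylor` — analytic second-order Taylor approximations
  of the first and second moments (no closed forms exist in general),
* :func:`pn_moments_isotropic_exact` — exact moments for the isotropic
  special case ``Sigma = sigma**2 I`` via confluent hypergeometric
  functions,
* :func:`empirical_moments` — sample moments, the Monte-Carlo ground truth
  used to validate the approximations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from ._taylor import taylor_moments
from .params import GaussianParams, MomentPair

__all__ = [
    "RadialIntegralTerms",
    "pn_sample",
    "m_recursion",
    "radial_terms",
    "pn_pdf",
    "pn_logpdf",
    "pn_moments_taylor",
    "pn_moments_isotropic_exact",
    "empirical_moments",
]

#: Reject density evaluation when Sigma is ill-conditioned beyond this.
MAX_CONDITION_NUMBER = 1e12

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass
class RadialIntegralTerms:
    """Ingredients of the sphere density at a point ``y``.

    ``q1 = mu' Sigma^-1 mu``, ``q2 = mu' Sigma^-1 y``,
    ``q3 = y' Sigma^-1 y``, ``alpha = q2 / sqrt(q3)``, and ``m_values`` are
    the radial moments ``M_0 .. M_{n-1}`` at ``alpha``.
    """

    q1: float
    q2: float
    q3: float
    alpha: float
    m_values: np.ndarray


def _sigma_factor(sigma: np.ndarray) -> np.ndarray:
    """Symmetric square root of a covariance matrix (for sampling)."""
    eigval, eigvec = np.linalg.eigh(sigma)
    if eigval.min() <= 0:
        raise ValueError("covariance must be positive definite for sampling")
    return (eigvec * np.sqrt(eigval)) @ eigvec.T


def pn_sample(g: GaussianParams, n_samples: int, seed: int) -> np.ndarray:
    """Draw ``n_samples`` points of ``y = x / ||x||`` with ``x ~ N(mu, Sigma)``.

    Returns an ``(n_samples, n)`` array whose rows have unit norm.
    Deterministic given ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    fac = _sigma_factor(g.sigma)
    x = g.mu + rng.standard_normal((n_samples, g.n)) @ fac
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        raise FloatingPointError("drew a zero vector; cannot project")
    return x / norms[:, None]


def m_recursion(alpha: float, k_max: int, scaled: bool = False) -> np.ndarray:
    """Radial moments ``M_k(alpha) = int_0^inf r**k phi(r - alpha) dr``.

    Computed by the two-term recursion ``M_{k+1} = alpha M_k + k M_{k-1}``
    with ``M_0 = Phi(alpha)`` and ``M_1 = alpha Phi(alpha) + phi(alpha)``,
    where ``phi`` / ``Phi`` are the standard normal pdf / cdf.  Returns the
    array ``[M_0, ..., M_{k_max}]``.

    With ``scaled=True`` the values returned are ``M_k * exp(alpha**2 / 2)``
    (computed via the scaled complementary error function), which stay
    representable for arbitrarily negative ``alpha``; the density routine
    uses this form.  Unscaled values underflow to zero for
    ``alpha < about -37``, and the forward recursion loses relative digits
    slowly for very large ``k_max`` (tens of orders beyond any dimension
    used here); direct quadrature of the defining integral is the fallback
    oracle in that regime.
    """
    if k_max < 0:
        raise ValueError("k_max must be non-negative")
    alpha = float(alpha)
    if scaled:
        m0 = 0.5 * special.erfcx(-alpha / np.sqrt(2.0))
        phi_term = 1.0 / _SQRT2PI
    else:
        m0 = special.ndtr(alpha)
        phi_term = np.exp(-0.5 * alpha * alpha) / _SQRT2PI
    out = np.empty(k_max + 1)
    out[0] = m0
    if k_max >= 1:
        out[1] = alpha * m0 + phi_term
    for k in range(1, k_max):
        out[k + 1] = alpha * out[k] + k * out[k - 1]
    return out


def _solve_terms(g: GaussianParams, y: np.ndarray):
    cond = np.linalg.cond(g.sigma)
    if cond > MAX_CONDITION_NUMBER:
        raise np.linalg.LinAlgError(
            f"sigma condition number {cond:.3g} exceeds {MAX_CONDITION_NUMBER:.0e}"
        )
    si_mu = np.linalg.solve(g.sigma, g.mu)
    si_y = np.linalg.solve(g.sigma, y)
    q1 = float(g.mu @ si_mu)
    q2 = float(g.mu @ si_y)
    q3 = float(y @ si_y)
    return q1, q2, q3


def radial_terms(g: GaussianParams, y: np.ndarray) -> RadialIntegralTerms:
    """The quadratic terms and radial moments entering the sphere density."""
    y = np.asarray(y, dtype=float)
    q1, q2, q3 = _solve_terms(g, y)
    alpha = q2 / np.sqrt(q3)
    return RadialIntegralTerms(
        q1=q1, q2=q2, q3=q3, alpha=alpha, m_values=m_recursion(alpha, g.n - 1)
    )


def pn_logpdf(g: GaussianParams, y: np.ndarray) -> float:
    """Log-density of the projected normal at a unit vector ``y``.

    The density with respect to the surface measure on the unit sphere is::

        p(y) = exp((q2**2/q3 - q1) / 2) * M_{n-1}(q2 / sqrt(q3))
               / ((2 pi)**((n-1)/2) * det(Sigma)**(1/2) * q3**(n/2))

    which is the radial integral ``int_0^inf r**(n-1) N(r y; mu, Sigma) dr``
    evaluated through the ``M_k`` recursion.  Evaluation combines the
    Gaussian prefactor with the scaled recursion so nothing underflows far
    from the mean direction.  ``y`` is renormalized to unit length.
    """
    y = np.asarray(y, dtype=float)
    norm = np.linalg.norm(y)
    if norm == 0 or not np.isfinite(norm):
        raise ValueError("y must be a nonzero finite vector")
    y = y / norm
    q1, q2, q3 = _solve_terms(g, y)
    n = g.n
    alpha = q2 / np.sqrt(q3)
    # exp((alpha**2 - q1)/2) * M_{n-1}(alpha) == exp(-q1/2) * Mhat_{n-1}(alpha)
    m_scaled = m_recursion(alpha, n - 1, scaled=True)[-1]
    sign, logdet = np.linalg.slogdet(g.sigma)
    return float(
        -0.5 * q1
        + np.log(m_scaled)
        - 0.5 * (n - 1) * np.log(2.0 * np.pi)
        - 0.5 * logdet
        - 0.5 * n * np.log(q3)
    )


def pn_pdf(g: GaussianParams, y: np.ndarray) -> float:
    """Density of the projected normal at ``y`` (surface measure on the sphere)."""
    return float(np.exp(pn_logpdf(g, y)))


def pn_moments_taylor(g: GaussianParams) -> MomentPair:
    """Taylor approximation of the moments of ``y = x / ||x||``.

    Invariant under the rescaling ``(mu, Sigma) -> (k mu, k**2 Sigma)``,
    matching the scale invariance of the distribution itself.
    """
    gamma, sm, psi = taylor_moments(g.mu, g.sigma, 0.0)
    return MomentPair(gamma=gamma, second_moment=sm, psi=psi)


def _hyp1f1(a: float, b: float, z: float) -> float:
    # scipy's hyp1f1 handles large negative z stably (internal Kummer-type
    # transformations); an explicit e**z * 1F1(b-a; b; -z) transform would
    # overflow past z ~ -709.
    return float(special.hyp1f1(a, b, z))


def pn_moments_isotropic_exact(mu: np.ndarray, sigma2: float) -> MomentPair:
    """Exact moments of ``PN(mu, sigma2 * I)``.

    For isotropic latent covariance the moments have closed forms::

        gamma = a * mu,     Psi = b * mu mu' + c * I

    with ``t = ||mu||**2 / (2 sigma2)`` and

    * ``a = Gamma((n+1)/2) / (sqrt(2 sigma2) Gamma(n/2 + 1))
      * 1F1(1/2; (n+2)/2; -t)``
    * ``b = 1F1(1; (n+4)/2; -t) / (sigma2 (n+2)) - a**2``
    * ``c = 1F1(1; (n+2)/2; -t) / n``

    where ``1F1`` is the confluent hypergeometric function.  The raw second
    moment has unit trace exactly (``||y|| = 1``).  ``n = 1`` reduces to
    ``E[y] = 2 Phi(mu/sigma) - 1`` for ``y = sign(x)``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    n = mu.shape[0]
    t = mu @ mu / (2.0 * sigma2)
    a = (
        np.exp(special.gammaln((n + 1) / 2.0) - special.gammaln(n / 2.0 + 1.0))
        / np.sqrt(2.0 * sigma2)
        * _hyp1f1(0.5, (n + 2) / 2.0, -t)
    )
    b = _hyp1f1(1.0, (n + 4) / 2.0, -t) / (sigma2 * (n + 2)) - a * a
    c_coef = _hyp1f1(1.0, (n + 2) / 2.0, -t) / n
    gamma = a * mu
    psi = b * np.outer(mu, mu) + c_coef * np.eye(n)
    return MomentPair(gamma=gamma, psi=psi)


def empirical_moments(samples: np.ndarray) -> MomentPair:
    """Sample moments of projected draws (mean, N-1 covariance).

    This is the Monte-Carlo ground truth against which the analytic
    approximations are judged.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise ValueError("need a 2-d sample matrix with at least 2 rows")
    gamma = samples.mean(axis=0)
    psi = np.cov(samples, rowvar=False, ddof=1)
    psi = np.atleast_2d(psi)
    return MomentPair(gamma=gamma, psi=psi)
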