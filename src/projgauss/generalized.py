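"""Generalizations of the projected normal with denominator ``sqrt(x'Bx + c)``.

Divisive-normalization models in neuroscience divide a Gaussian input
vector ``x`` by quadratic functions of its own magnitude.  The resulting
variable ``y = x / sqrt(x' B x + c)`` lives

* inside the unit ball when ``B = I, c > 0``  (``pnc_*`` routines),
* on the ellipsoid surface ``y'By = 1`` when ``c = 0``  (``pnb_*``),
* inside that ellipsoid when both are present  (``pnbc_*``).

The ``B`` cases reduce to the previous ones through the linear change of
variable ``x' = B^{1/2} x``: then ``y = B^{-1/2} y'`` where ``y'`` follows
the corresponding distribution with parameters ``mu' = B^{1/2} mu`` and
``Sigma' = B^{1/2} Sigma B^{1/2}``.  Moments transform back as
``gamma = B^{-1/2} gamma'`` and ``Psi = B^{-1/2} Psi' B^{-1/2}``.

The density on the ellipsoid *surface* (``c = 0``, ``B != I``) is not
provided: mapping the sphere's surface measure through ``B^{-1/2}`` has no
simple closed form, so only samplers and moment approximations cover that
case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal

from ._taylor import taylor_moments
from .params import DenominatorSpec, GaussianParams, MomentPair, check_symmetric, symmetrize
from .projected_normal import pn_moments_taylor, pn_sample

__all__ = [
    "TransformedParams",
    "spd_sqrt",
    "transform_params",
    "gen_sample",
    "pnc_pdf",
    "pnc_logpdf",
    "pnc_moments_taylor",
    "pnb_moments",
    "pnbc_moments",
    "pnbc_pdf",
    "pnbc_logpdf",
]


@dataclass
class TransformedParams:
    """Parameters of ``x' = B^{1/2} x`` plus the back-transform matrix."""

    mu_prime: np.ndarray
    sigma_prime: np.ndarray
    b_inv_sqrt: np.ndarray


def spd_sqrt(B: np.ndarray):
    """Symmetric square root and inverse square root of an SPD matrix.

    Uses the eigendecomposition (not Cholesky) so that both outputs are
    themselves symmetric, as the transform algebra requires.
    """
    B = np.asarray(B, dtype=float)
    check_symmetric(B, "B")
    B = symmetrize(B)
    eigval, eigvec = np.linalg.eigh(B)
    if eigval.min() <= 0:
        raise ValueError(f"B must be SPD (min eigenvalue {eigval.min():.3g})")
    root = np.sqrt(eigval)
    b_sqrt = (eigvec * root) @ eigvec.T
    b_inv_sqrt = (eigvec / root) @ eigvec.T
    return b_sqrt, b_inv_sqrt


def transform_params(g: GaussianParams, B: np.ndarray) -> TransformedParams:
    """``mu' = B^{1/2} mu`` and ``Sigma' = B^{1/2} Sigma B^{1/2}``."""
    b_sqrt, b_inv_sqrt = spd_sqrt(B)
    return TransformedParams(
        mu_prime=b_sqrt @ g.mu,
        sigma_prime=symmetrize(b_sqrt @ g.sigma @ b_sqrt),
        b_inv_sqrt=b_inv_sqrt,
    )


def gen_sample(g: GaussianParams, den: DenominatorSpec, n_samples: int, seed: int) -> np.ndarray:
    """Draw samples of ``y = x / sqrt(x' B x + c)``.

    Rows satisfy ``y'By = 1`` exactly when ``c = 0`` and ``y'By < 1``
    strictly when ``c > 0``.  Reduces to :func:`.pn_sample` when ``B = I``
    and ``c = 0``.
    """
    if den.is_identity and den.c == 0.0:
        return pn_sample(g, n_samples, seed)
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    eigval, eigvec = np.linalg.eigh(g.sigma)
    fac = (eigvec * np.sqrt(eigval)) @ eigvec.T
    x = g.mu + rng.standard_normal((n_samples, g.n)) @ fac
    if den.is_identity:
        quad = np.einsum("ij,ij->i", x, x)
    else:
        quad = np.einsum("ij,jk,ik->i", x, den.matrix(g.n), x)
    return x / np.sqrt(quad + den.c)[:, None]


def pnc_logpdf(g: GaussianParams, c: float, y: np.ndarray) -> float:
    """Log-density of ``y = x / sqrt(x'x + c)`` on the open unit ball.

    The projection is invertible: ``x = h^{-1}(y) = y sqrt(c / (1 - r**2))``
    with ``r**2 = ||y||**2``, and the Jacobian of ``h^{-1}`` has
    determinant ``(c / (1 - r**2))**(n/2) / (1 - r**2)``.  The density is
    the Gaussian density at ``h^{-1}(y)`` times that determinant.

    Returns ``-inf`` for points outside the support (``||y|| >= 1``);
    raises on non-finite input and on ``c = 0`` (where the support
    degenerates to the sphere — use the sphere density instead).
    """
    if c <= 0:
        raise ValueError("c must be strictly positive; c = 0 lives on the sphere")
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    r2 = float(y @ y)
    if r2 >= 1.0:
        return -np.inf
    scale = np.sqrt(c / (1.0 - r2))
    x = y * scale
    log_det_j = 0.5 * g.n * np.log(c / (1.0 - r2)) - np.log1p(-r2)
    return float(log_det_j + multivariate_normal.logpdf(x, mean=g.mu, cov=g.sigma))


def pnc_pdf(g: GaussianParams, c: float, y: np.ndarray) -> float:
    """Density on the open unit ball; zero outside the support."""
    return float(np.exp(pnc_logpdf(g, c, y)))


def pnc_moments_taylor(g: GaussianParams, c: float) -> MomentPair:
    """Taylor moment approximation for ``y = x / sqrt(x'x + c)``.

    The constant only shifts the expected denominator terms
    (``zbar_i`` and ``dbar`` gain ``+c``); variances and covariances of the
    quadratic forms are unchanged.  ``c = 0`` is exactly the sphere case.
    """
    if c < 0:
        raise ValueError("c must be non-negative")
    gamma, sm, psi = taylor_moments(g.mu, g.sigma, float(c))
    return MomentPair(gamma=gamma, second_moment=sm, psi=psi)


def _back_transform(mom: MomentPair, b_inv_sqrt: np.ndarray) -> MomentPair:
    gamma = b_inv_sqrt @ mom.gamma
    psi = symmetrize(b_inv_sqrt @ mom.psi @ b_inv_sqrt)
    return MomentPair(gamma=gamma, psi=psi)


def pnb_moments(g: GaussianParams, B: np.ndarray) -> MomentPair:
    """Moment approximation on the ellipsoid surface ``y'By = 1``."""
    tp = transform_params(g, B)
    mom_prime = pn_moments_taylor(GaussianParams(tp.mu_prime, tp.sigma_prime))
    return _back_transform(mom_prime, tp.b_inv_sqrt)


def pnbc_moments(g: GaussianParams, den: DenominatorSpec) -> MomentPair:
    """Moment approximation on the ellipsoid interior ``y'By < 1``.

    Reduces to :func:`pnc_moments_taylor` for ``B = I`` and to
    :func:`pnb_moments` for ``c = 0``.
    """
    if den.is_identity:
        return pnc_moments_taylor(g, den.c)
    tp = transform_params(g, den.matrix(g.n))
    mom_prime = pnc_moments_taylor(GaussianParams(tp.mu_prime, tp.sigma_prime), den.c)
    return _back_transform(mom_prime, tp.b_inv_sqrt)


def pnbc_logpdf(g: GaussianParams, den: DenominatorSpec, y: np.ndarray) -> float:
    """Log-density on the ellipsoid interior.

    With ``y' = B^{1/2} y`` distributed on the unit ball with parameters
    ``(mu', Sigma', c)``, the linear change of variables gives
    ``p(y) = p_ball(B^{1/2} y; mu', Sigma', c) * det(B)**(1/2)``.
    """
    if den.c <= 0:
        raise ValueError("c must be strictly positive; c = 0 lives on the ellipsoid surface")
    y = np.asarray(y, dtype=float)
    B = den.matrix(y.shape[0])
    if den.is_identity:
        return pnc_logpdf(g, den.c, y)
    b_sqrt, _ = spd_sqrt(B)
    tp = transform_params(g, B)
    g_prime = GaussianParams(tp.mu_prime, tp.sigma_prime)
    sign, logdet_b = np.linalg.slogdet(B)
    return pnc_logpdf(g_prime, den.c, b_sqrt @ y) + 0.5 * logdet_b


def pnbc_pdf(g: GaussianParams, den: DenominatorSpec, y: np.ndarray) -> float:
    """Density on the ellipsoid interior; zero outside the support."""
    return float(np.exp(pnbc_logpdf(g, den, y)))
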