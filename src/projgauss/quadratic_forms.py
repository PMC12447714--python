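"""Closed-form moments of Gaussian quadratic forms.

For ``x ~ N(mu, Sigma)`` and symmetric ``A`` the quadratic form ``x' A x``
has known mean, variance, and cross-covariances:

* ``E[x' A x] = tr(A Sigma) + mu' A mu``
* ``var(x' A x) = 2 tr(A Sigma A Sigma) + 4 mu' A Sigma A mu``
* ``cov(x' A1 x, x' A2 x) = 2 tr(A1 Sigma A2 Sigma) + 4 mu' A1 Sigma A2 mu``

These are the raw material of every Taylor moment approximation in this
library.  :func:`residual_qf_stats` specializes them to the "residual norm"
``z_i = x' x - x_i**2 + c`` that appears in the first-moment expansion of
the projected normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import GaussianParams, check_symmetric, symmetrize

__all__ = [
    "QuadraticFormStats",
    "qf_mean",
    "qf_variance",
    "qf_covariance",
    "residual_qf_stats",
]


@dataclass
class QuadraticFormStats:
    """Mean and variance of a quadratic form, plus a cross-covariance.

    ``covariance_with_companion`` is context dependent: for
    :func:`residual_qf_stats` it is ``cov(x_i, z_i)``, the covariance of the
    coordinate with the residual squared norm.
    """

    mean: float
    variance: float
    covariance_with_companion: float


def _check_a(A: np.ndarray, g: GaussianParams, name: str = "A") -> np.ndarray:
    A = np.asarray(A, dtype=float)
    check_symmetric(A, name)
    if A.shape[0] != g.n:
        raise ValueError(f"{name} is {A.shape} but parameters have dimension {g.n}")
    return symmetrize(A)


def qf_mean(A: np.ndarray, g: GaussianParams) -> float:
    """``E[x' A x] = tr(A Sigma) + mu' A mu``."""
    A = _check_a(A, g)
    return float(np.trace(A @ g.sigma) + g.mu @ A @ g.mu)


def qf_variance(A: np.ndarray, g: GaussianParams) -> float:
    """``var(x' A x) = 2 tr(A Sigma A Sigma) + 4 mu' A Sigma A mu``."""
    A = _check_a(A, g)
    As = A @ g.sigma
    return float(2.0 * np.trace(As @ As) + 4.0 * g.mu @ A @ g.sigma @ A @ g.mu)


def qf_covariance(A1: np.ndarray, A2: np.ndarray, g: GaussianParams) -> float:
    """``cov(x' A1 x, x' A2 x) = 2 tr(A1 Sigma A2 Sigma) + 4 mu' A1 Sigma A2 mu``.

    Symmetric in ``(A1, A2)``; reduces to :func:`qf_variance` when
    ``A1 = A2``.
    """
    A1 = _check_a(A1, g, "A1")
    A2 = _check_a(A2, g, "A2")
    S = g.sigma

    def half(P, Q):
        return 2.0 * np.trace(P @ S @ Q @ S) + 4.0 * g.mu @ P @ S @ Q @ g.mu

    # evaluated both ways and averaged so the result is exactly symmetric
    # in (A1, A2) despite floating-point ordering
    return float(0.5 * (half(A1, A2) + half(A2, A1)))


def residual_qf_stats(i: int, g: GaussianParams, c: float = 0.0) -> QuadraticFormStats:
    """Moments of ``z_i = sum_{j != i} x_j**2 + c`` and ``cov(x_i, z_i)``.

    With ``mu_-i`` / ``Sigma_-i`` denoting the mean / covariance with entry
    (row and column) ``i`` deleted:

    * ``E[z_i] = tr(Sigma_-i) + mu_-i' mu_-i + c``
    * ``var(z_i) = 2 tr(Sigma_-i Sigma_-i) + 4 mu_-i' Sigma_-i mu_-i``
    * ``cov(x_i, z_i) = 2 (mu' col_i(Sigma) - mu_i Sigma_ii)``

    The covariance follows from ``cov(x_i, x_j**2) = 2 mu_j Sigma_ij`` for
    jointly Gaussian coordinates; the constant ``c`` shifts only the mean.
    """
    if not 0 <= i < g.n:
        raise IndexError(f"index {i} out of range for dimension {g.n}")
    if c < 0:
        raise ValueError(f"c must be non-negative, got {c}")
    keep = np.arange(g.n) != i
    mu_r = g.mu[keep]
    sigma_r = g.sigma[np.ix_(keep, keep)]
    mean = float(np.trace(sigma_r) + mu_r @ mu_r + c)
    variance = float(2.0 * np.sum(sigma_r * sigma_r) + 4.0 * mu_r @ sigma_r @ mu_r)
    cov_xz = float(2.0 * (g.mu @ g.sigma[:, i] - g.mu[i] * g.sigma[i, i]))
    return QuadraticFormStats(mean=mean, variance=variance, covariance_with_companion=cov_xz)
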