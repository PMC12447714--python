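"""Batched Taylor moment approximations for divisively normalized Gaussians.

This is the computational core shared by the public moment routines and the
moment-matching optimizer.  Everything here operates on stacked parameter
arrays — ``mu`` of shape ``(..., n)``, ``sigma`` of shape ``(..., n, n)``,
``c`` scalar or ``(...)`` — so that a finite-difference gradient (hundreds
of perturbed parameter vectors) costs one vectorized call instead of a
Python loop.

The approximated variable is ``y = x / sqrt(x' x + c)`` with
``x ~ N(mu, sigma)``.

First moment, per element: write ``y_i = f(x_i, z_i) = x_i / sqrt(x_i**2 +
z_i)`` with ``z_i = sum_{j != i} x_j**2 + c``.  A second-order Taylor
expansion of ``f`` around ``(mu_i, E[z_i])``, combined with the closed-form
moments of the Gaussian quadratic form ``z_i``, gives with
``u_i = mu_i**2 + zbar_i``::

    gamma_i ~= mu_i / sqrt(u_i)
             + [ Sigma_ii/2 * (-3 mu_i zbar_i)
               + var(z_i)/2 * (3 mu_i / 4)
               + cov(x_i, z_i) * (mu_i**2 - zbar_i/2) ] / u_i**(5/2)

The bracketed coefficients are the second derivatives of ``f``:
``d2f/dx2 = -3 x z (x**2+z)**(-5/2)``, ``d2f/dz2 = (3x/4) (x**2+z)**(-5/2)``
and ``d2f/dxdz = (x**2 - z/2) (x**2+z)**(-5/2)``.

Second moment: ``y_i y_j = n_ij / d`` with ``n_ij = x_i x_j`` and
``d = x' x + c`` is a ratio of quadratic forms, approximated by::

    E[n/d] ~= nbar/dbar * (1 - cov(n, d)/(nbar dbar) + var(d)/dbar**2)

evaluated in the expanded form ``nbar/dbar - cov(n,d)/dbar**2 +
nbar var(d)/dbar**3`` so that near-zero ``nbar`` entries never divide.
"""

from __future__ import annotations

import numpy as np


def taylor_gamma(mu: np.ndarray, sigma: np.ndarray, c=0.0) -> np.ndarray:
    """Approximate first moment ``E[y]``, batched over leading axes."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    diag = np.diagonal(sigma, axis1=-2, axis2=-1)
    tr = diag.sum(axis=-1)
    mu2 = mu * mu
    sig_mu = np.einsum("...ij,...j->...i", sigma, mu)
    mu_sig_mu = np.einsum("...i,...i->...", mu, sig_mu)
    # (Sigma @ Sigma)_ii = sum_j Sigma_ij**2 for symmetric Sigma
    sig2_diag = np.einsum("...ij,...ij->...i", sigma, sigma)
    tr_sig2 = sig2_diag.sum(axis=-1)

    c = np.asarray(c, dtype=float)
    zbar = (tr + mu2.sum(axis=-1) + c)[..., None] - diag - mu2
    var_z = 2.0 * (tr_sig2[..., None] - 2.0 * sig2_diag + diag * diag) + 4.0 * (
        mu_sig_mu[..., None] - 2.0 * mu * sig_mu + mu2 * diag
    )
    cov_xz = 2.0 * (sig_mu - mu * diag)

    u = mu2 + zbar
    correction = (
        0.5 * diag * (-3.0 * mu * zbar)
        + 0.5 * var_z * (0.75 * mu)
        + cov_xz * (mu2 - 0.5 * zbar)
    )
    return mu / np.sqrt(u) + correction / u ** 2.5


def taylor_second_moment(mu: np.ndarray, sigma: np.ndarray, c=0.0) -> np.ndarray:
    """Approximate raw second moment ``E[y y']``, batched over leading axes."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    sig_mu = np.einsum("...ij,...j->...i", sigma, mu)
    tr = np.trace(sigma, axis1=-2, axis2=-1)
    dbar = tr + np.einsum("...i,...i->...", mu, mu) + np.asarray(c, dtype=float)
    var_d = 2.0 * np.einsum("...ij,...ij->...", sigma, sigma) + 4.0 * np.einsum(
        "...i,...i->...", mu, sig_mu
    )
    nbar = sigma + mu[..., :, None] * mu[..., None, :]
    cov_nd = 2.0 * (sigma @ sigma) + 2.0 * (
        mu[..., :, None] * sig_mu[..., None, :] + sig_mu[..., :, None] * mu[..., None, :]
    )
    dbar_ = dbar[..., None, None]
    var_d_ = var_d[..., None, None]
    return nbar / dbar_ - cov_nd / dbar_**2 + nbar * var_d_ / dbar_**3


def taylor_moments(mu: np.ndarray, sigma: np.ndarray, c=0.0):
    """Return ``(gamma, second_moment, psi)``, batched over leading axes."""
    gamma = taylor_gamma(mu, sigma, c)
    sm = taylor_second_moment(mu, sigma, c)
    psi = sm - gamma[..., :, None] * gamma[..., None, :]
    return gamma, sm, psi
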