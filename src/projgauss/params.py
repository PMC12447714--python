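"""Core parameter and moment containers shared across the library.

The latent variable is Gaussian, ``x ~ N(mu, Sigma)``.  Dividing ``x`` by a
denominator ``sqrt(x' B x + c)`` produces a bounded random variable ``y``:

* ``B = I, c = 0`` — the projected normal (angular Gaussian) on the unit
  sphere,
* ``B = I, c > 0`` — a distribution on the interior of the unit ball,
* ``B`` SPD, ``c = 0`` — a distribution on the surface of the ellipsoid
  ``y' B y = 1``,
* ``B`` SPD, ``c > 0`` — a distribution on the ellipsoid interior.

:class:`GaussianParams` holds ``(mu, Sigma)``, :class:`DenominatorSpec`
holds ``(B, c)``, and :class:`MomentPair` holds the first moment ``gamma``,
the raw second moment ``E[y y']`` and the covariance ``Psi`` of ``y``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GaussianParams",
    "DenominatorSpec",
    "MomentPair",
    "SYMMETRY_RTOL",
    "symmetrize",
    "check_symmetric",
]

# Relative tolerance for accepting a nominally symmetric matrix.  Quadratic
# forms only see the symmetric part, so inputs within this band are
# symmetrized silently; beyond it we raise.
SYMMETRY_RTOL = 1e-8


def check_symmetric(m: np.ndarray, name: str = "matrix", rtol: float = SYMMETRY_RTOL) -> None:
    """Raise ``ValueError`` if ``m`` is not symmetric within ``rtol``."""
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    scale = np.abs(m).max()
    if scale == 0:
        return
    if np.abs(m - m.T).max() > rtol * scale:
        raise ValueError(f"{name} is not symmetric within tolerance {rtol}")


def symmetrize(m: np.ndarray) -> np.ndarray:
    """Return the symmetric part ``(M + M') / 2``."""
    m = np.asarray(m, dtype=float)
    return 0.5 * (m + m.T)


@dataclass
class GaussianParams:
    """The latent Gaussian ``x ~ N(mu, sigma)`` that gets projected.

    Parameters
    ----------
    mu : (n,) array_like
        Mean of the latent Gaussian.
    sigma : (n, n) array_like
        Covariance of the latent Gaussian.  Must be symmetric positive
        definite; near-symmetric input is symmetrized internally.
    """

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.ndim != 1:
            raise ValueError("mu must be a 1-d vector")
        check_symmetric(sigma, "sigma")
        self.sigma = symmetrize(sigma)
        if self.sigma.shape[0] != self.mu.shape[0]:
            raise ValueError(
                f"dimension mismatch: mu has length {self.mu.shape[0]}, "
                f"sigma is {self.sigma.shape}"
            )
        eigvals = np.linalg.eigvalsh(self.sigma)
        if eigvals.min() <= 0:
            raise ValueError(
                f"sigma must be positive definite (min eigenvalue {eigvals.min():.3g})"
            )

    @property
    def n(self) -> int:
        return self.mu.shape[0]


@dataclass
class DenominatorSpec:
    """Denominator ``sqrt(x' B x + c)`` of the projection.

    ``B = None`` means the identity.  ``(B=I, c=0)`` recovers the classic
    projected normal.
    """

    B: np.ndarray | None = None
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"c must be non-negative, got {self.c}")
        self.c = float(self.c)
        if self.B is not None:
            B = np.asarray(self.B, dtype=float)
            check_symmetric(B, "B")
            B = symmetrize(B)
            if np.linalg.eigvalsh(B).min() <= 0:
                raise ValueError("B must be symmetric positive definite")
            self.B = B

    def matrix(self, n: int) -> np.ndarray:
        """The denominator matrix as an explicit ``(n, n)`` array."""
        if self.B is None:
            return np.eye(n)
        if self.B.shape[0] != n:
            raise ValueError(f"B is {self.B.shape} but dimension is {n}")
        return self.B

    @property
    def is_identity(self) -> bool:
        return self.B is None


@dataclass
class MomentPair:
    """First and second moments of the projected variable ``y``.

    Attributes
    ----------
    gamma : (n,) ndarray
        First moment ``E[y]``.
    second_moment : (n, n) ndarray
        Raw second moment ``E[y y']``.
    psi : (n, n) ndarray
        Covariance ``E[(y - gamma)(y - gamma)'] = E[y y'] - gamma gamma'``.
    """

    gamma: np.ndarray
    second_moment: np.ndarray = field(default=None)  # type: ignore[assignment]
    psi: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.second_moment is None and self.psi is None:
            raise ValueError("provide at least one of second_moment, psi")
        outer = np.outer(self.gamma, self.gamma)
        if self.second_moment is None:
            self.psi = symmetrize(np.asarray(self.psi, dtype=float))
            self.second_moment = self.psi + outer
        elif self.psi is None:
            self.second_moment = symmetrize(np.asarray(self.second_moment, dtype=float))
            self.psi = self.second_moment - outer
        else:
            self.second_moment = symmetrize(np.asarray(self.second_moment, dtype=float))
            self.psi = symmetrize(np.asarray(self.psi, dtype=float))

    @property
    def n(self) -> int:
        return self.gamma.shape[0]
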