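"""Ball and ellipsoid generalizations: supports, densities, moment transforms."""

import numpy as np
import pytest
from scipy import integrate
from scipy.optimize import approx_fprime

from projgauss import (
    DenominatorSpec,
    GaussianParams,
    empirical_moments,
    gen_sample,
    pn_moments_taylor,
    pn_sample,
    pnb_moments,
    pnbc_moments,
    pnbc_pdf,
    pnc_moments_taylor,
    pnc_pdf,
    spd_sqrt,
    transform_params,
)
from conftest import random_gaussian


def random_spd(n, rng, floor=0.3):
    A = rng.standard_normal((n, n))
    return A @ A.T + floor * np.eye(n)


class TestSpdSqrt:
    def test_identity(self):
        r, ri = spd_sqrt(np.eye(3))
        assert np.allclose(r, np.eye(3)) and np.allclose(ri, np.eye(3))

    def test_diagonal(self):
        r, ri = spd_sqrt(np.diag([4.0, 9.0]))
        assert np.allclose(r, np.diag([2.0, 3.0]))
        assert np.allclose(ri, np.diag([0.5, 1 / 3]))

    def test_reconstruction_and_symmetry(self, rng):
        B = random_spd(6, rng)
        r, ri = spd_sqrt(B)
        assert np.linalg.norm(r @ r - B) / np.linalg.norm(B) < 1e-12
        assert np.allclose(r, r.T) and np.allclose(ri, ri.T)
        assert np.allclose(ri @ ri, np.linalg.inv(B), atol=1e-10)

    def test_rejects_indefinite(self):
        with pytest.raises(ValueError):
            spd_sqrt(np.diag([1.0, -0.1]))


class TestTransformParams:
    def test_identity_is_noop(self, rng):
        g = random_gaussian(3, rng)
        tp = transform_params(g, np.eye(3))
        assert np.allclose(tp.mu_prime, g.mu) and np.allclose(tp.sigma_prime, g.sigma)

    def test_diagonal_case_by_hand(self):
        g = GaussianParams([1.0, 1.0], np.eye(2))
        tp = transform_params(g, np.diag([4.0, 1.0]))
        assert np.allclose(tp.mu_prime, [2.0, 1.0])

    def test_round_trip(self, rng):
        g = random_gaussian(5, rng)
        B = random_spd(5, rng)
        tp = transform_params(g, B)
        assert np.allclose(tp.b_inv_sqrt @ tp.mu_prime, g.mu, atol=1e-10)

    def test_matches_transformed_sample_moments(self, rng):
        g = random_gaussian(5, rng)
        B = random_spd(5, rng)
        tp = transform_params(g, B)
        b_sqrt, _ = spd_sqrt(B)
        x = rng.multivariate_normal(g.mu, g.sigma, size=200_000) @ b_sqrt
        se = x.std(axis=0, ddof=1) / np.sqrt(200_000)
        assert np.all(np.abs(x.mean(axis=0) - tp.mu_prime) < 4 * se)
        assert np.abs(np.cov(x, rowvar=False) - tp.sigma_prime).max() < 0.05 * np.abs(
            tp.sigma_prime
        ).max()


class TestGenSample:
    def test_reduces_to_sphere_sampler(self, rng):
        g = random_gaussian(4, rng)
        a = gen_sample(g, DenominatorSpec(), 100, seed=5)
        b = pn_sample(g, 100, seed=5)
        assert np.array_equal(a, b)

    def test_ellipsoid_surface_constraint(self, rng):
        g = random_gaussian(4, rng)
        B = random_spd(4, rng)
        y = gen_sample(g, DenominatorSpec(B=B, c=0.0), 10_000, seed=6)
        assert np.abs(np.einsum("ij,jk,ik->i", y, B, y) - 1.0).max() < 1e-10

    def test_interior_constraint_strict(self, rng):
        g = random_gaussian(3, rng)
        y = gen_sample(g, DenominatorSpec(c=2.5), 10_000, seed=7)
        assert np.all(np.linalg.norm(y, axis=1) < 1.0)

    def test_ball_moments_match_approximation(self):
        g = GaussianParams([1.0, 0.0, 0.0], 0.04 * np.eye(3))
        den = DenominatorSpec(c=2.5)
        emp = empirical_moments(gen_sample(g, den, 10**6, seed=8))
        approx = pnc_moments_taylor(g, 2.5)
        assert 100 * np.sum((approx.gamma - emp.gamma) ** 2) / np.sum(emp.gamma**2) < 1.0
        assert 100 * np.sum((approx.psi - emp.psi) ** 2) / np.sum(emp.psi**2) < 5.0


class TestBallDensity:
    def test_rotational_symmetry_at_zero_mean(self):
        g = GaussianParams(np.zeros(2), np.eye(2))
        r = 0.4
        assert pnc_pdf(g, 1.3, np.array([r, 0.0])) == pytest.approx(
            pnc_pdf(g, 1.3, np.array([0.0, r])), rel=1e-12
        )

    def test_normalizes_on_unit_disk(self, rng):
        for _ in range(3):
            g = random_gaussian(2, rng)
            c = float(rng.uniform(0.3, 3.0))
            total, _ = integrate.dblquad(
                lambda r, t: r * pnc_pdf(g, c, np.array([r * np.cos(t), r * np.sin(t)])),
                0, 2 * np.pi, 0, 1,
            )
            assert total == pytest.approx(1.0, abs=1e-5)

    def test_jacobian_determinant_matches_finite_differences(self, rng):
        # det(J) of the inverse map x = y * sqrt(c/(1-|y|^2)) at random interior points
        n, c = 3, 1.7
        for _ in range(20):
            y = rng.uniform(-0.6, 0.6, size=n)
            if y @ y >= 0.9:
                continue

            def inv_map(v):
                return v * np.sqrt(c / (1.0 - v @ v))

            J = np.column_stack(
                [approx_fprime(y, lambda v, j=j: inv_map(v)[j], 1e-7) for j in range(n)]
            ).T
            r2 = y @ y
            det_closed = (c / (1 - r2)) ** (n / 2) / (1 - r2)
            assert np.linalg.det(J) == pytest.approx(det_closed, rel=1e-6)

    def test_outside_support_is_zero_and_c_zero_rejected(self, rng):
        g = random_gaussian(2, rng)
        assert pnc_pdf(g, 1.0, np.array([0.8, 0.7])) == 0.0
        with pytest.raises(ValueError):
            pnc_pdf(g, 0.0, np.array([0.1, 0.1]))
        with pytest.raises(ValueError):
            pnc_pdf(g, 1.0, np.array([np.nan, 0.0]))


class TestEllipsoidDensity:
    def test_identity_reduces_to_ball(self, rng):
        g = random_gaussian(3, rng)
        y = np.array([0.2, -0.3, 0.1])
        assert pnbc_pdf(g, DenominatorSpec(c=0.9), y) == pytest.approx(
            pnc_pdf(g, 0.9, y), rel=1e-12
        )

    def test_normalizes_on_ellipse_interior(self, rng):
        g = random_gaussian(2, rng)
        B = random_spd(2, rng)
        den = DenominatorSpec(B=B, c=0.8)
        _, b_inv_sqrt = spd_sqrt(B)
        jac = np.linalg.det(b_inv_sqrt)
        total, _ = integrate.dblquad(
            lambda r, t: r * jac * pnbc_pdf(
                g, den, b_inv_sqrt @ np.array([r * np.cos(t), r * np.sin(t)])
            ),
            0, 2 * np.pi, 0, 1,
        )
        assert total == pytest.approx(1.0, abs=1e-5)

    def test_histogram_agrees_with_density(self, rng):
        g = GaussianParams([0.7, -0.2], 0.2 * np.eye(2))
        B = np.array([[1.5, 0.3], [0.3, 0.9]])
        den = DenominatorSpec(B=B, c=0.6)
        y = gen_sample(g, den, 10**6, seed=9)
        H, xe, ye = np.histogram2d(y[:, 0], y[:, 1], bins=20, range=[[-1.2, 1.2], [-1.2, 1.2]])
        area = (xe[1] - xe[0]) * (ye[1] - ye[0])
        # integrate the density over each bin on a 5x5 sub-grid (a bin-center
        # evaluation is biased where the density is strongly curved)
        offsets = (np.arange(5) + 0.5) / 5
        expected = np.zeros_like(H)
        for i in range(20):
            for j in range(20):
                xs = xe[i] + offsets * (xe[1] - xe[0])
                ys = ye[j] + offsets * (ye[1] - ye[0])
                vals = [pnbc_pdf(g, den, np.array([a, b])) for a in xs for b in ys]
                expected[i, j] = np.mean(vals) * area * 10**6
        mask = expected > 500  # compare well-populated bins only
        assert np.all(np.abs(H[mask] - expected[mask]) < 5 * np.sqrt(expected[mask]) + 50)


class TestMomentReductions:
    def test_pnc_at_zero_c_equals_sphere_taylor(self, rng):
        g = random_gaussian(4, rng)
        a = pnc_moments_taylor(g, 0.0)
        b = pn_moments_taylor(g)
        assert np.array_equal(a.gamma, b.gamma)
        assert np.array_equal(a.second_moment, b.second_moment)

    def test_large_c_shrinks_first_moment(self, rng):
        g = random_gaussian(4, rng)
        c = 1e6 * (np.trace(g.sigma) + g.mu @ g.mu)
        m = pnc_moments_taylor(g, c)
        assert np.allclose(m.gamma, g.mu / np.sqrt(c), rtol=1e-3)

    def test_pnb_identity_reduces_to_sphere(self, rng):
        g = random_gaussian(4, rng)
        a = pnb_moments(g, np.eye(4))
        b = pn_moments_taylor(g)
        assert np.allclose(a.gamma, b.gamma, atol=1e-14)
        assert np.allclose(a.psi, b.psi, atol=1e-14)

    def test_pnb_scalar_matrix_rescales_moments(self, rng):
        g = random_gaussian(3, rng)
        k = 4.0
        a = pnb_moments(g, np.eye(3))
        b = pnb_moments(g, k * np.eye(3))
        assert np.allclose(b.gamma, a.gamma / np.sqrt(k), rtol=1e-10)
        assert np.allclose(b.psi, a.psi / k, rtol=1e-8, atol=1e-15)

    def test_pnbc_reduction_chain(self, rng):
        g = random_gaussian(4, rng)
        B = random_spd(4, rng)
        bc0 = pnbc_moments(g, DenominatorSpec(B=B, c=0.0))
        b_only = pnb_moments(g, B)
        assert np.allclose(bc0.gamma, b_only.gamma, atol=1e-14)
        ball = pnbc_moments(g, DenominatorSpec(c=0.8))
        direct = pnc_moments_taylor(g, 0.8)
        assert np.array_equal(ball.gamma, direct.gamma)

    def test_pnb_matches_monte_carlo(self, rng):
        from projgauss import sample_mu, sample_sigma

        n = 6
        g = GaussianParams(sample_mu(n, rng), sample_sigma(n, 0.25, rng))
        B = random_spd(n, rng)
        approx = pnb_moments(g, B)
        emp = empirical_moments(gen_sample(g, DenominatorSpec(B=B, c=0.0), 10**6, seed=10))
        assert 100 * np.sum((approx.gamma - emp.gamma) ** 2) / np.sum(emp.gamma**2) < 1.0

    def test_negative_c_rejected(self, rng):
        with pytest.raises(ValueError):
            pnc_moments_taylor(random_gaussian(3, rng), -0.1)
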