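import numpy as np
import pytest
from scipy.integrate import quad

from dyntopo import (
    CuspFit,
    cobb_r2,
    cusp_density,
    cusp_normalizer,
    fit_cusp_mle,
    linear_r2,
    sample_cusp,
    stationary_points,
)
from dyntopo.cuspfit import nearest_stationary_points

SHAPES = [(0.0, -1.0), (0.0, 0.0), (0.0, 2.0), (0.5, 1.5), (-0.8, 3.0), (2.0, -2.0)]


class TestDensity:
    @pytest.mark.parametrize("alpha,beta", SHAPES)
    def test_density_integrates_to_one(self, alpha, beta):
        total, err = quad(lambda x: cusp_density(x, alpha, beta), -np.inf, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_normalizer_matches_quadrature_oracle(self):
        alpha, beta = 0.3, 1.2
        integral, _ = quad(
            lambda x: np.exp(alpha * x + beta * x**2 / 2 - x**4 / 4), -np.inf, np.inf
        )
        assert cusp_normalizer(alpha, beta) == pytest.approx(1.0 / integral, rel=1e-8)

    def test_symmetric_density_is_even(self):
        y = np.linspace(-2, 2, 41)
        f = cusp_density(y, 0.0, 1.0)
        np.testing.assert_allclose(f, f[::-1], rtol=1e-10)

    def test_bimodal_when_beta_positive(self):
        y = np.linspace(-2.5, 2.5, 1001)
        f = cusp_density(y, 0.0, 2.0)
        mid = f[len(y) // 2]
        assert f.max() > 1.5 * mid  # two modes flanking a central dip
        assert f[np.argmin(np.abs(y - np.sqrt(2)))] == f.max()

    def test_unimodal_when_beta_negative(self):
        y = np.linspace(-2.5, 2.5, 1001)
        f = cusp_density(y, 0.0, -1.0)
        assert np.argmax(f) == len(y) // 2
        assert np.all(np.diff(f[: len(y) // 2]) > 0)


class TestStationaryPoints:
    @pytest.mark.parametrize("alpha,beta", SHAPES)
    def test_roots_solve_cubic(self, alpha, beta):
        r = stationary_points(alpha, beta)
        np.testing.assert_allclose(alpha + beta * r - r**3, 0.0, atol=1e-8)
        # sorted; repeated roots (degenerate cusp point) are allowed
        assert np.all(np.diff(r) >= -1e-12)

    def test_root_count_matches_fold_condition(self):
        # the cubic has 3 real roots iff 27*alpha^2 < 4*beta^3
        assert len(stationary_points(0.0, 2.0)) == 3
        assert len(stationary_points(0.0, -1.0)) == 1
        assert len(stationary_points(2.0, 1.0)) == 1

    def test_symmetric_bimodal_roots(self):
        np.testing.assert_allclose(
            stationary_points(0.0, 1.0), [-1.0, 0.0, 1.0], atol=1e-10
        )

    def test_nearest_picks_own_branch(self):
        y = np.array([-1.1, -0.1, 0.2, 0.9])
        alpha = np.zeros(4)
        beta = np.ones(4)
        np.testing.assert_allclose(
            nearest_stationary_points(y, alpha, beta), [-1.0, 0.0, 0.0, 1.0], atol=1e-10
        )


class TestSampling:
    def test_sample_moments_match_quadrature(self):
        alpha, beta = 0.4, 1.0
        n = 4000
        rng = np.random.default_rng(0)
        draws = sample_cusp(np.full(n, alpha), np.full(n, beta), rng)
        m1, _ = quad(lambda x: x * cusp_density(x, alpha, beta), -np.inf, np.inf)
        m2, _ = quad(lambda x: x**2 * cusp_density(x, alpha, beta), -np.inf, np.inf)
        assert draws.mean() == pytest.approx(m1, abs=0.06)
        assert (draws**2).mean() == pytest.approx(m2, abs=0.08)

    def test_sample_seed_reproducible(self):
        alpha = np.linspace(-1, 1, 50)
        beta = np.linspace(-1, 2, 50)
        d1 = sample_cusp(alpha, beta, np.random.default_rng(3))
        d2 = sample_cusp(alpha, beta, np.random.default_rng(3))
        np.testing.assert_array_equal(d1, d2)


class TestFit:
    def test_recovers_generating_coefficients(self):
        # alpha = 2A, beta = 0.5 + 2B, state observed directly (w = Y)
        rng = np.random.default_rng(7)
        n = 1500
        A = rng.uniform(-1, 1, n)
        B = rng.uniform(-1, 1, n)
        Y = sample_cusp(2.0 * A, 0.5 + 2.0 * B, rng)
        fit = fit_cusp_mle(Y, A, B)
        assert fit.converged
        assert fit.alpha_coefs[0] == pytest.approx(0.0, abs=0.25)
        assert fit.alpha_coefs[1] == pytest.approx(2.0, abs=0.25)
        assert fit.beta_coefs[0] == pytest.approx(0.5, abs=0.3)
        assert fit.beta_coefs[1] == pytest.approx(2.0, abs=0.3)
        assert fit.w_coefs[0] == pytest.approx(0.0, abs=0.15)
        assert fit.w_coefs[1] == pytest.approx(1.0, abs=0.15)

    def test_transform_applies_linear_links(self):
        fit = CuspFit((0.5, 2.0), (-0.2, 1.0), (0.1, 3.0), 0.0, True)
        w, al, be = fit.transform([1.0], [0.25], [0.5])
        assert w[0] == pytest.approx(3.1)
        assert al[0] == pytest.approx(1.0)
        assert be[0] == pytest.approx(0.3)

    def test_constant_state_flagged_unconverged(self):
        fit = fit_cusp_mle(np.ones(50), np.linspace(-1, 1, 50), np.linspace(-1, 1, 50))
        assert not fit.converged

    def test_too_few_observations_raise(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_cusp_mle(np.arange(5.0), np.arange(5.0), np.arange(5.0))


class TestFitIndices:
    def test_linear_r2_exact_plane_is_one(self):
        rng = np.random.default_rng(2)
        A = rng.uniform(-1, 1, 60)
        B = rng.uniform(-1, 1, 60)
        Y = 0.3 + 1.2 * A - 0.7 * B
        assert linear_r2(Y, A, B) == pytest.approx(1.0, abs=1e-12)

    def test_linear_r2_pure_noise_near_zero(self):
        rng = np.random.default_rng(4)
        A = rng.uniform(-1, 1, 500)
        B = rng.uniform(-1, 1, 500)
        Y = rng.normal(size=500)
        assert abs(linear_r2(Y, A, B)) < 0.05

    def test_linear_r2_validation(self):
        with pytest.raises(ValueError, match="at least 4"):
            linear_r2([1.0, 2.0], [0.0, 1.0], [0.0, 1.0])
        with pytest.raises(ValueError, match="rank"):
            linear_r2(np.arange(10.0), np.ones(10), np.ones(10))
        with pytest.raises(ValueError, match="constant Y"):
            linear_r2(np.ones(10), np.arange(10.0), np.linspace(0, 1, 10) ** 2)

    def test_cobb_r2_near_one_on_equilibrium_surface(self):
        # points sitting on the surface alpha + beta*y - y^3 = 0 with the
        # identity links: every observation is at a stationary point
        rng = np.random.default_rng(9)
        pts = []
        while len(pts) < 300:
            a = rng.uniform(-0.5, 0.5)
            b = rng.uniform(-0.5, 0.5)
            roots = stationary_points(a, b)
            pts.append((float(rng.choice(roots)), a, b))
        Y, A, B = map(np.array, zip(*pts))
        ident = CuspFit((0.0, 1.0), (0.0, 1.0), (0.0, 1.0), 0.0, True)
        jittered = Y + rng.normal(0, 0.01, len(Y))
        assert cobb_r2(jittered, A, B, ident) > 0.97

    def test_cobb_r2_constant_state_raises(self):
        ident = CuspFit((0.0, 1.0), (0.0, 1.0), (0.0, 0.0), 0.0, True)
        with pytest.raises(ValueError, match="constant state"):
            cobb_r2(np.arange(10.0), np.zeros(10), np.zeros(10), ident)
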