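import numpy as np
import pytest

from latentcorr import (
    TableError,
    bound_copulas,
    comonotone_copula,
    gaussian_copula,
    grid_correlation,
    hoeffding_correlation,
    independence_copula,
    polyserial_interval,
    problem_from_copula,
    problem_from_sample,
)


class TestProblemConstruction:
    def test_independence_curve_value(self):
        p = problem_from_copula(independence_copula(), [0.5])
        assert p.curve(0, 0.5) == pytest.approx(0.25)
        p.validate()

    def test_comonotone_curves_are_min(self):
        p = problem_from_copula(comonotone_copula(), [0.5])
        v = np.linspace(0, 1, 11)
        assert np.allclose(p.curve(0, v), np.minimum(0.5, v))

    def test_gaussian_curves_satisfy_frechet_consistency(self):
        p = problem_from_copula(gaussian_copula(0.35), [0.2, 0.5, 0.8])
        p.validate()

    def test_bad_cuts_rejected(self):
        with pytest.raises(TableError):
            problem_from_copula(independence_copula(), [0.5, 0.4])

    def test_two_point_sample(self):
        p = problem_from_sample(np.array([1, 2]), np.array([0.1, 0.9]))
        assert np.allclose(p.cuts, [0.5])
        assert p.curve(0, 0.5) == pytest.approx(0.5)
        assert p.curve(0, 1.0) == pytest.approx(0.5)

    def test_constant_x_gives_frechet_problem(self, std_normal):
        p = problem_from_sample(np.ones(10), np.arange(10.0))
        assert p.cuts.size == 0
        iv = polyserial_interval(p, std_normal, std_normal)
        assert iv.lower == pytest.approx(-1, abs=1e-3)
        assert iv.upper == pytest.approx(1, abs=1e-3)

    def test_constant_z_rejected(self):
        with pytest.raises(TableError, match="constant"):
            problem_from_sample(np.array([1, 2, 1]), np.ones(3))

    def test_empirical_curves_converge_to_population(self):
        """Mid-rank step curves from a large Gaussian-copula sample track
        the population curves C(c_i, v)."""
        rho, n = 0.35, 100_000
        rng = np.random.default_rng(2024)
        C = gaussian_copula(rho)
        uv = C.sampler(n, rng)
        cuts = np.array([0.2, 0.5, 0.8])
        x = 1 + np.searchsorted(cuts, uv[:, 0])
        emp = problem_from_sample(x, uv[:, 1])
        pop = problem_from_copula(C, cuts)
        v = np.linspace(0.01, 0.99, 50)
        for i in range(3):
            assert np.max(np.abs(emp.curve(i, v) - pop.curve(i, v))) < 0.01


class TestBoundCopulas:
    def test_no_cuts_gives_frechet_bounds(self):
        M, W = bound_copulas(problem_from_copula(independence_copula(), []))
        u, v = np.meshgrid(np.linspace(0, 1, 9), np.linspace(0, 1, 9))
        assert np.allclose(M(u, v), np.minimum(u, v))
        assert np.allclose(W(u, v), np.maximum(u + v - 1, 0))

    def test_independence_curve_arithmetic(self):
        M, W = bound_copulas(problem_from_copula(independence_copula(), [0.5]))
        assert M(0.6, 0.5) == pytest.approx(0.35)
        assert W(0.4, 0.5) == pytest.approx(0.15)

    @pytest.mark.parametrize("rho", [-0.5, 0.35, 0.8])
    def test_W_below_C_below_M(self, rho):
        C = gaussian_copula(rho)
        M, W = bound_copulas(problem_from_copula(C, [0.2, 0.5, 0.8]))
        g = np.linspace(0.01, 0.99, 25)
        U, V = np.meshgrid(g, g)
        cv = C.evaluate(U, V)
        assert np.all(W(U, V) <= cv + 1e-9)
        assert np.all(cv <= M(U, V) + 1e-9)


class TestHoeffdingCorrelation:
    def test_independence_is_zero(self, uniform01, std_normal):
        assert hoeffding_correlation(independence_copula(), uniform01, std_normal) == (
            pytest.approx(0, abs=1e-10)
        )

    def test_comonotone_uniform_is_one(self, uniform01):
        val = hoeffding_correlation(comonotone_copula(), uniform01, uniform01)
        assert val == pytest.approx(1, abs=2e-4)

    @pytest.mark.parametrize("rho", [-0.9, -0.5, -0.1, 0.3, 0.7, 0.9])
    def test_gaussian_uniform_closed_form(self, rho, uniform01):
        """Gaussian copula + uniform marginals: rho_F = (6/pi) arcsin(rho/2)."""
        val = hoeffding_correlation(gaussian_copula(rho), uniform01, uniform01)
        assert val == pytest.approx(6 / np.pi * np.arcsin(rho / 2), abs=1e-4)


class TestInterval:
    def test_frechet_case_normal(self, std_normal):
        p = problem_from_copula(independence_copula(), [])
        iv = polyserial_interval(p, std_normal, std_normal)
        assert iv.lower == pytest.approx(-1, abs=1e-3)
        assert iv.upper == pytest.approx(1, abs=1e-3)

    def test_interval_contains_generating_correlation(self, std_normal):
        rho = 0.35
        p = problem_from_copula(gaussian_copula(rho), [0.2, 0.5, 0.8])
        iv = polyserial_interval(p, std_normal, std_normal)
        assert iv.lower <= rho <= iv.upper
        assert iv.width < 1.0  # the cuts are informative

    def test_symmetric_interval_matches_grid_oracle(self, uniform01):
        """Independence curves with one median cut, uniform marginals: the
        interval is symmetric and matches a Riemann evaluation of the
        covariance functional of the bound copulas."""
        p = problem_from_copula(independence_copula(), [0.5])
        iv = polyserial_interval(p, uniform01, uniform01)
        assert iv.lower == pytest.approx(-iv.upper, abs=1e-4)
        M, W = bound_copulas(p)
        assert iv.upper == pytest.approx(
            grid_correlation(M, uniform01, uniform01, n=2000), abs=1e-3
        )
        assert iv.lower == pytest.approx(
            grid_correlation(W, uniform01, uniform01, n=2000), abs=1e-3
        )

    def test_adding_a_cut_never_widens(self, uniform01):
        C = gaussian_copula(0.4)
        a = polyserial_interval(problem_from_copula(C, [0.5]), uniform01, uniform01)
        b = polyserial_interval(problem_from_copula(C, [0.3, 0.5]), uniform01, uniform01)
        assert b.lower >= a.lower - 1e-3
        assert b.upper <= a.upper + 1e-3
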