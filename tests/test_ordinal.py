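import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latentcorr import (
    CumulativeProbMatrix,
    aux_matrices,
    collapse,
    discretize,
    from_pmf,
    gaussian_copula,
    hoeffding_correlation,
    ordinal_interval,
    pmf_of,
    support_vectors,
)
from tests.conftest import random_table


class TestAuxMatrices:
    def test_2x2_independence_values(self, indep_2x2):
        A = aux_matrices(indep_2x2)
        assert np.allclose(A.alpha, [[0, 0.25], [0.5, 0.75]])
        assert np.allclose(A.beta, [[0, 0.5], [0.25, 0.75]])
        assert np.allclose(A.gamma, [[0, 0.25], [0.5, 0.75]])
        assert np.allclose(A.delta, [[0.75, 0.25], [0.5, 0]])

    def test_structural_zeros(self, indep_2x2):
        A = aux_matrices(indep_2x2)
        assert A.alpha[0, 0] == 0  # alpha_11 = 0 always
        assert A.delta.ravel()[-1] == 0  # terminal countermonotone segment hits v=0

    def test_1x1_degenerate(self):
        A = aux_matrices(CumulativeProbMatrix(np.array([[1.0]])))
        assert A.alpha[0, 0] == A.beta[0, 0] == A.gamma[0, 0] == A.delta[0, 0] == 0


class TestSegmentSystem:
    def test_2x2_independence_support_vectors(self, indep_2x2):
        seg = support_vectors(aux_matrices(indep_2x2))
        assert np.allclose(seg.uU, [0, 0.25, 0.5, 0.75, 1])
        assert np.allclose(seg.vU, [0, 0.5, 0.25, 0.75])
        assert np.allclose(seg.uL, [0, 0.25, 0.5, 0.75, 1])
        assert np.allclose(seg.vL, [0.75, 0.25, 0.5, 0])

    def test_1x1_is_frechet_coupling(self):
        seg = support_vectors(aux_matrices(CumulativeProbMatrix(np.array([[1.0]]))))
        assert np.allclose(seg.uU, [0, 1]) and np.allclose(seg.vU, [0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(1, 4), st.integers(1, 4), st.integers(0, 10_000))
    def test_invariants_on_random_tables(self, I, J, seed):
        """u-grids partition [0,1]; v-intervals tile [0,1]; each system
        reproduces the table's cell masses (compatibility with Pi)."""
        Pi = collapse(random_table(np.random.default_rng(seed), I, J))
        seg = support_vectors(aux_matrices(Pi))
        for u, v in ((seg.uU, seg.vU), (seg.uL, seg.vL)):
            assert u[0] == pytest.approx(0) and u[-1] == pytest.approx(1)
            lengths = np.diff(u)
            assert np.all(lengths >= -1e-12)
            assert lengths.sum() == pytest.approx(1, abs=1e-9)
            # v-intervals [v_k, v_k + len_k] tile [0,1]
            order = np.argsort(v)
            starts, stops = v[order], (v + lengths)[order]
            assert starts[0] == pytest.approx(0, abs=1e-9)
            assert stops[-1] == pytest.approx(1, abs=1e-9)
            assert np.allclose(starts[1:], stops[:-1], atol=1e-9)
        p = pmf_of(Pi)
        assert np.allclose(seg.cell_masses(Pi.xcdf, Pi.ycdf, "upper"), p, atol=1e-9)
        assert np.allclose(seg.cell_masses(Pi.xcdf, Pi.ycdf, "lower"), p, atol=1e-9)


class TestInterval:
    def test_2x2_independence_uniform_exact(self, indep_2x2, uniform01):
        iv = ordinal_interval(indep_2x2, uniform01, uniform01)
        assert iv.lower == pytest.approx(-0.8125, abs=1e-6)
        assert iv.upper == pytest.approx(0.8125, abs=1e-6)

    def test_1x1_normal_frechet_endpoints(self, std_normal):
        iv = ordinal_interval(
            CumulativeProbMatrix(np.array([[1.0]])), std_normal, std_normal
        )
        assert iv.lower == pytest.approx(-1, abs=1e-6)
        assert iv.upper == pytest.approx(1, abs=1e-6)

    def test_zero_mass_categories_do_not_change_the_interval(self, uniform01):
        padded = from_pmf([[0.25, 0.0, 0.25], [0.0, 0.0, 0.0], [0.25, 0.0, 0.25]])
        plain = from_pmf([[0.25, 0.25], [0.25, 0.25]])
        a = ordinal_interval(padded, uniform01, uniform01)
        b = ordinal_interval(plain, uniform01, uniform01)
        assert a.lower == pytest.approx(b.lower, abs=1e-10)
        assert a.upper == pytest.approx(b.upper, abs=1e-10)

    def test_reflection_of_y_negates_interval(self, std_normal):
        """Reversing Y's category order maps [L, U] to [-U, -L] for
        marginals symmetric about their means."""
        rng = np.random.default_rng(7)
        Pi = random_table(rng, 3, 4)
        rev = from_pmf(pmf_of(Pi)[:, ::-1])
        a = ordinal_interval(Pi, std_normal, std_normal)
        b = ordinal_interval(rev, std_normal, std_normal)
        assert a.lower == pytest.approx(-b.upper, abs=1e-7)
        assert a.upper == pytest.approx(-b.lower, abs=1e-7)

    def test_refinement_never_widens(self, std_normal):
        C = gaussian_copula(0.5)
        coarse = discretize(C, [0.4], [0.5])
        fine = discretize(C, [0.2, 0.4], [0.5])
        a = ordinal_interval(coarse, std_normal, std_normal)
        b = ordinal_interval(fine, std_normal, std_normal)
        assert b.lower >= a.lower - 1e-9
        assert b.upper <= a.upper + 1e-9

    @pytest.mark.parametrize("rho", [-0.6, 0.0, 0.7])
    def test_sharpness_contains_generating_correlation(self, rho, std_normal):
        """rho(C; F1, F2) always lies inside the interval of any
        discretization of C; for the Gaussian copula with standard normal
        marginals that correlation is rho itself."""
        Pi = discretize(gaussian_copula(rho), [0.3, 0.6], [0.25, 0.5, 0.75])
        iv = ordinal_interval(Pi, std_normal, std_normal)
        assert iv.lower <= rho <= iv.upper

    def test_diagnostics_reported(self, indep_2x2, uniform01):
        iv = ordinal_interval(indep_2x2, uniform01, uniform01)
        assert iv.n_segments == 4
        assert 0 <= iv.quad_error < 1e-6
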