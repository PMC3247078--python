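"""Absorbing Markov model: enumeration, generator, spectrum, transients."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given
from hypothesis import strategies as st

from switchpool import (
    SwitchParameters,
    build_generator,
    dominant_mode,
    enumerate_states,
    initial_distribution,
    pon_curve,
    pon_tail_fit,
    solve_cme,
)
from switchpool.units import MINUTES_PER_YEAR


class TestEnumeration:
    def test_small_space(self):
        space = enumerate_states(1)
        assert space.states.tolist() == [[0, 0], [1, 0], [0, 1]]
        assert space.n == 4
        assert space.absorbing_index == 3
        assert space.state_index(0, 0) == 0

    def test_ordering_rule(self):
        space = enumerate_states(2)
        assert space.states.tolist() == [[0, 0], [1, 0], [0, 1], [2, 0], [1, 1], [0, 2]]

    def test_nominal_count(self, space55):
        assert space55.n_off == 56 * 57 // 2 == 1596
        assert space55.n == 1597

    @given(B=st.integers(0, 25))
    def test_bijection_and_count(self, B):
        space = enumerate_states(B)
        assert space.n_off == (B + 1) * (B + 2) // 2
        assert len(space.index) == space.n_off
        for i, (x, y) in enumerate(space.states):
            assert space.state_index(int(x), int(y)) == i

    def test_degenerate_and_invalid(self):
        assert enumerate_states(0).states.tolist() == [[0, 0]]
        with pytest.raises(ValueError):
            enumerate_states(-1)


class TestGenerator:
    def test_origin_column_b1(self, nominal):
        """At (0,0) only basal production fires: diagonal -k1, rate k1
        into (1,0)."""
        space = enumerate_states(1)
        A = build_generator(nominal, space).A.toarray()
        col = A[:, 0]
        assert col[0] == pytest.approx(-nominal.k1)
        assert col[1] == pytest.approx(nominal.k1)
        assert col[2] == col[3] == 0.0

    @pytest.mark.parametrize("B", [1, 12, 55])
    def test_columns_sum_to_zero(self, nominal, B):
        A = build_generator(nominal, enumerate_states(B)).A
        assert np.abs(np.asarray(A.sum(axis=0))).max() < 1e-13

    def test_offdiagonals_nonnegative(self, gen55):
        A = gen55.A.tocoo()
        off = A.data[A.row != A.col]
        assert off.min() >= 0

    def test_absorption_only_from_boundary(self, gen55, space55):
        a = gen55.a_abs
        sums = space55.states.sum(axis=1)
        assert np.all(a[sums == 55] > 0)
        assert np.all(a[sums < 55] == 0)

    def test_absorbing_column_zero(self, gen55):
        assert gen55.A[:, -1].nnz == 0

    def test_diagonal_dominance(self, gen55):
        """Column sums of |off-diagonal| bounded by the diagonal in A_rev."""
        Ar = gen55.A_rev.tocsc()
        d = -Ar.diagonal()
        offsum = np.asarray(np.abs(Ar).sum(axis=0)).ravel() - d
        assert np.all(offsum <= d + 1e-12)


class TestDominantMode:
    def test_degenerate_single_state(self, nominal):
        G = build_generator(nominal, enumerate_states(0))
        s = dominant_mode(G)
        assert s.lambda1_per_min == pytest.approx(-nominal.k1, rel=1e-14)

    def test_spectrum_negative_and_perron(self, nominal):
        """All eigenvalues strictly in the left half-plane; the rightmost
        is real, simple, with a strictly positive eigenvector."""
        G = build_generator(nominal, enumerate_states(12))
        w = scipy.linalg.eigvals(G.A_rev.toarray())
        assert w.real.max() < 0
        order = np.argsort(w.real)[::-1]
        lam1, lam2 = w[order[0]], w[order[1]]
        assert abs(lam1.imag) < 1e-14
        assert lam2.real < lam1.real - 1e-12  # simple, strictly rightmost
        # the true eigenvector is strictly positive but its entries span
        # >20 orders of magnitude; below the solver's absolute resolution
        # (~eps * max entry) they underflow to 0, so positivity is
        # asserted on every resolvable entry
        s = dominant_mode(G, method="dense")
        v = s.eigvec
        assert v.min() >= 0
        assert np.all(v[v > 1e-15 * v.max()] > 0)
        assert (v == 0).sum() <= 2
        assert s.lambda1_per_min == pytest.approx(lam1.real, rel=1e-10)

    def test_sparse_matches_dense_full_space(self, gen55, summary55):
        dense = dominant_mode(gen55, method="dense")
        assert summary55.lambda1_per_min == pytest.approx(dense.lambda1_per_min, rel=1e-12)

    def test_unit_roundtrip(self, summary55):
        assert summary55.lambda1_per_year / MINUTES_PER_YEAR == summary55.lambda1_per_min


class TestSolveCme:
    def test_point_mass_on_absorbing(self, nominal):
        space = enumerate_states(3)
        G = build_generator(nominal, space)
        p0 = np.zeros(space.n)
        p0[-1] = 1.0
        sol = solve_cme(G, p0, np.array([1.0, 10.0, 100.0]))
        assert np.allclose(sol.p_on, 1.0, atol=1e-12)

    def test_initial_time_returns_p0(self, nominal):
        space = enumerate_states(3)
        G = build_generator(nominal, space)
        p0 = np.zeros(space.n)
        p0[0] = 1.0
        sol = solve_cme(G, p0, np.array([0.0, 5.0]))
        assert np.allclose(sol.P[:, 0], p0)

    def test_b1_against_spectral_oracle(self, nominal):
        """4-state chain: transient from an independent eigen-expansion
        of the dense generator."""
        space = enumerate_states(1)
        G = build_generator(nominal, space)
        p0 = np.zeros(4)
        p0[0] = 1.0
        times = np.linspace(1.0, 2000.0, 40)
        sol = solve_cme(G, p0, times, method="bdf", rtol=1e-10, atol=1e-14)
        A = G.A.toarray()
        w, V = np.linalg.eig(A)
        c = np.linalg.solve(V, p0)
        for k, t in enumerate(times):
            oracle = (V * np.exp(w * t)) @ c
            assert np.allclose(sol.P[:, k], oracle.real, atol=1e-7)

    def test_expm_and_bdf_agree(self, nominal):
        space = enumerate_states(12)
        G = build_generator(nominal, space)
        p0 = initial_distribution(nominal, space)
        times = np.logspace(1, 7, 25)
        se = solve_cme(G, p0, times, method="expm")
        sb = solve_cme(G, p0, times, method="bdf")
        assert np.abs(se.P - sb.P).max() < 1e-6

    def test_conservation_and_monotone_absorption(self, sol55):
        total = sol55.P.sum(axis=0)
        assert np.abs(total - 1.0).max() < 1e-8
        assert np.all(np.diff(sol55.p_on) >= -1e-9)
        assert sol55.p_on[-1] > 0.9999  # 200 y >> half-life: absorption nearly complete

    def test_bad_inputs(self, nominal):
        space = enumerate_states(2)
        G = build_generator(nominal, space)
        with pytest.raises(ValueError):
            solve_cme(G, np.ones(space.n), np.array([1.0, 2.0]))  # not a distribution
        p0 = np.zeros(space.n)
        p0[0] = 1.0
        with pytest.raises(ValueError):
            solve_cme(G, p0, np.array([2.0, 1.0]))


class TestTailFit:
    def test_slope_matches_lambda1(self, sol55, summary55):
        fit = pon_tail_fit(sol55, summary55)
        assert 0.99 < fit.slope_ratio < 1.01
        assert fit.c1 > 0

    def test_degenerate_pure_exponential(self, nominal):
        G = build_generator(nominal, enumerate_states(0))
        s = dominant_mode(G)
        t_half = np.log(2) / nominal.k1
        times = np.linspace(t_half / 10, 8 * t_half, 60)
        p0 = np.array([1.0, 0.0])
        sol = solve_cme(G, p0, times, method="expm")
        fit = pon_tail_fit(sol, s)
        assert fit.c1 == pytest.approx(1.0, rel=1e-6)
        assert fit.slope_ratio == pytest.approx(1.0, rel=1e-8)

    def test_requires_three_half_lives(self, nominal, summary55):
        sol = pon_curve(nominal, B=55, t_max_years=1.0, n_times=30)
        with pytest.raises(ValueError):
            pon_tail_fit(sol, summary55)


def test_initial_distribution_near_low_attractor(nominal, space55):
    p0 = initial_distribution(nominal, space55)
    assert p0.sum() == 1.0
    idx = int(np.nonzero(p0)[0][0])
    x, y = space55.states[idx]
    assert (x, y) == (6, 1)  # nearest integer state to the off attractor (5.50, 0.58)
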