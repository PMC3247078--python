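"""Deterministic switch: rates, equilibria, trajectories, macrostates."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from switchpool import (
    SwitchParameters,
    classify_macrostate,
    evaluate_rates,
    find_equilibria,
    simulate_ode,
)
from switchpool.switch import jacobian, rhs


@pytest.mark.parametrize(
    "state, expected",
    [
        ((0, 0), [0.055, 0.0, 0.0, 0.0, 0.0]),  # only basal production at the origin
        ((0, 25), [0.055, 0.275, 0.0, 0.0, 0.25]),  # y at half-saturation: v2 = V1/2
        ((10, 0), [0.055, 0.0, 0.10, None, 0.0]),  # v3 = u1 * x
    ],
)
def test_rate_law_values(nominal, state, expected):
    rates = evaluate_rates(state, nominal)
    for i, e in enumerate(expected):
        if e is not None:
            assert rates[i] == pytest.approx(e, abs=1e-12)


@given(
    x=st.floats(0, 200),
    y=st.floats(0, 200),
    scale=st.floats(0.5, 2.0),
)
def test_rates_finite_nonnegative(x, y, scale):
    params = SwitchParameters.nominal().scaled("V", scale).scaled("u", scale)
    rates = evaluate_rates((x, y), params)
    assert np.all(np.isfinite(rates)) and np.all(rates >= 0)


def test_rate_domain_errors(nominal):
    with pytest.raises(ValueError):
        evaluate_rates((-1, 0), nominal)
    with pytest.raises(ValueError):
        SwitchParameters(k1=0.0)
    with pytest.raises(ValueError):
        SwitchParameters(u1=-0.01)


def test_zero_feedback_allowed():
    p = SwitchParameters(V1=0.0, V2=0.0)
    assert evaluate_rates((5, 5), p)[1] == 0.0


def test_scaled_groups(nominal):
    s = nominal.scaled("V", 1.3)
    assert s.V1 == pytest.approx(0.55 * 1.3) and s.V2 == pytest.approx(0.55 * 1.3)
    assert s.k1 == nominal.k1
    with pytest.raises(KeyError):
        nominal.scaled("V1", 2.0)


class TestEquilibria:
    def test_three_equilibria_bistable(self, nominal):
        eqs = find_equilibria(nominal)
        assert len(eqs) == 3
        assert [e.stability for e in eqs] == ["stable", "saddle", "stable"]
        # saddle certificate: mixed-sign Jacobian spectrum
        mid = eqs[1]
        re = sorted(ev.real for ev in mid.eigenvalues)
        assert re[0] < 0 < re[1]
        for e in eqs:
            assert np.linalg.norm(rhs(0.0, e.state, nominal)) < 1e-8
        assert eqs[0].total < eqs[1].total < eqs[2].total

    def test_matches_nullcline_scan(self, nominal):
        """Brute-force oracle: compose the two nullclines and count sign
        changes of the mismatch on a 0.05-copy grid."""
        p = nominal

        def x_null(y):
            return (p.k1 + p.V1 * y**p.h / (p.M1**p.h + y**p.h)) / p.u1

        def y_null(x):
            return p.V2 * x**p.h / (p.M2**p.h + x**p.h) / p.u2

        ys = np.arange(0.0, p.V2 / p.u2 + 1.0, 0.05)
        g = y_null(x_null(ys)) - ys
        crossings = ys[:-1][np.sign(g[:-1]) != np.sign(g[1:])]
        eqs = find_equilibria(p)
        assert len(crossings) == len(eqs)
        for yc, eq in zip(np.sort(crossings), eqs):
            assert abs(yc - eq.state[1]) < 0.1

    def test_monostable_at_high_basal_rate(self, nominal):
        eqs = find_equilibria(nominal.replace(k1=0.55))
        assert len(eqs) == 1
        assert eqs[0].stability == "stable"


class TestOde:
    def test_fixed_point_stays(self, nominal):
        eq = find_equilibria(nominal)[0]
        traj = simulate_ode(nominal, eq.state, np.linspace(0, 50000, 50))
        assert np.allclose(traj, np.asarray(eq.state), atol=1e-5)

    def test_origin_approaches_low_attractor_monotonically(self, nominal):
        low = find_equilibria(nominal)[0]
        traj = simulate_ode(nominal, (0, 0), np.linspace(0, 20000, 200))
        assert np.allclose(traj[-1], low.state, atol=1e-4)
        assert np.all(np.diff(traj[:, 0]) > -1e-9)

    def test_random_starts_land_on_an_attractor(self, nominal, rng):
        """The saddle's stable manifold has measure zero: every random
        start converges to one of the two attractors, staying non-negative."""
        eqs = find_equilibria(nominal)
        low, high = eqs[0], eqs[2]
        t = np.linspace(0, 2e5, 30)
        hits = {"low": 0, "high": 0}
        for _ in range(100):
            init = rng.uniform(0, 70, size=2)
            traj = simulate_ode(nominal, init, t, rtol=1e-8, atol=1e-10)
            assert traj.min() > -1e-9
            end = traj[-1]
            if np.hypot(*(end - low.state)) < 0.05:
                hits["low"] += 1
            elif np.hypot(*(end - high.state)) < 0.05:
                hits["high"] += 1
        assert hits["low"] + hits["high"] == 100
        assert min(hits.values()) > 0  # both basins sampled

    def test_bad_grid_rejected(self, nominal):
        with pytest.raises(ValueError):
            simulate_ode(nominal, (0, 0), [0.0, 0.0, 1.0])


class TestMacrostate:
    @pytest.mark.parametrize(
        "state, label",
        [((0, 0), "off"), ((30, 30), "on"), ((27, 28), "on"), ((27, 27), "off")],
    )
    def test_examples(self, state, label):
        assert classify_macrostate(state, L=55) == label

    @given(x=st.integers(0, 120), y=st.integers(0, 120))
    def test_threshold_rule(self, x, y):
        assert classify_macrostate((x, y), L=55) == ("on" if x + y >= 55 else "off")

    def test_domain(self):
        with pytest.raises(ValueError):
            classify_macrostate((-1, 0), L=55)
        with pytest.raises(ValueError):
            classify_macrostate((1, 1), L=0)


def test_jacobian_matches_finite_differences(nominal):
    xy = np.array([12.0, 7.0])
    J = jacobian(xy, nominal)
    eps = 1e-6
    for j in range(2):
        d = np.zeros(2)
        d[j] = eps
        fd = (rhs(0, xy + d, nominal) - rhs(0, xy - d, nominal)) / (2 * eps)
        assert np.allclose(J[:, j], fd, rtol=1e-5, atol=1e-8)
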