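"""Delayed-feedback population model: rate map and DDE integration."""

import numpy as np
import pytest

from switchpool import (
    FeedbackParameters,
    PopulationTrajectory,
    build_rate_map,
    depletion_time_from_trajectory,
    k1_of_n2,
    lambda1,
    simulate_dde,
)


class TestSuppression:
    def test_unsuppressed_and_half_suppressed(self, feedback_nominal):
        p = feedback_nominal
        assert k1_of_n2(0.0, p) == p.k1_max
        assert k1_of_n2(p.Kn, p) == pytest.approx(p.k1_max / 2)
        # nominal half-suppression point: 8.2e4 growing follicles halve k1
        assert k1_of_n2(8.2e4, p) == pytest.approx(0.03)

    def test_strictly_decreasing(self, feedback_nominal):
        n2 = np.linspace(0, 1e6, 50)
        k = np.array([k1_of_n2(v, feedback_nominal) for v in n2])
        assert np.all(np.diff(k) < 0)

    def test_negative_rejected(self, feedback_nominal):
        with pytest.raises(ValueError):
            k1_of_n2(-1.0, feedback_nominal)


class TestRateMap:
    def test_endpoint_equals_direct_eigensolve(self, feedback_nominal, rate_map55):
        direct = lambda1(feedback_nominal.switch_at(0.0), B=55)
        assert rate_map55.lambda1_per_year[0] == pytest.approx(
            direct.lambda1_per_year, rel=1e-9
        )
        assert rate_map55(0.0) == pytest.approx(direct.lambda1_per_year, rel=1e-6)

    def test_suppression_slows_switching(self, rate_map55):
        mags = -rate_map55.lambda1_per_year
        assert np.all(np.diff(mags) <= 1e-12)
        assert np.all(rate_map55.lambda1_per_year < 0)

    def test_interpolation_against_held_out_eigensolve(self, feedback_nominal, rate_map55):
        """Leave-one-out style check: interpolated lambda1 at off-grid n2
        within 1% of a direct eigensolve."""
        for n2 in (3.3e3, 4.7e4, 1.9e5):
            direct = lambda1(feedback_nominal.switch_at(n2), B=55).lambda1_per_year
            assert float(rate_map55(n2)) == pytest.approx(direct, rel=0.01)


class TestDde:
    def test_zero_delay_is_pure_exponential(self, feedback_nominal, rate_map55):
        """tau = 0: outflow cancels inflow instantly, n2 stays 0 and the
        pool declines as a single exponential at the unsuppressed rate."""
        p = feedback_nominal.replace(tau_years=0.0)
        traj0 = simulate_dde(p, 5.0, rate_map=rate_map55)
        lam0 = float(rate_map55(0.0))
        expect = feedback_nominal.N0 * np.exp(lam0 * traj0.times_years)
        assert np.allclose(traj0.n1, expect, rtol=1e-12)
        assert np.all(traj0.n2 == 0)

    def test_huge_kn_removes_feedback(self, feedback_nominal):
        """Kn >> N0: k1 stays at k1_max, so depletion matches the
        no-feedback exponential despite the delay machinery."""
        p = feedback_nominal.replace(Kn=1e15)
        rm = build_rate_map(p, B=55, n_points=6)
        traj = simulate_dde(p, 30.0, rate_map=rm, stop_below=500.0)
        td = depletion_time_from_trajectory(traj, 1e3)
        expect = np.log(p.N0 / 1e3) / rm.rate(0.0)
        assert td == pytest.approx(float(expect), rel=0.01)

    def test_conservation_before_delay_elapses(self, feedback_nominal, rate_map55):
        traj = simulate_dde(feedback_nominal, 1.0, rate_map=rate_map55)
        pre = traj.times_years < feedback_nominal.tau_years - 1e-12
        total = traj.n1[pre] + traj.n2[pre]
        assert np.allclose(total, feedback_nominal.N0, rtol=1e-9)

    def test_mass_accounting(self, feedback_nominal, rate_map55):
        """Cells leaving the growing compartment accumulate: N0 - n1 - n2
        is non-negative and non-decreasing."""
        traj = simulate_dde(feedback_nominal, 20.0, rate_map=rate_map55)
        exited = feedback_nominal.N0 - traj.n1 - traj.n2
        assert exited.min() > -1e-6 * feedback_nominal.N0
        assert np.all(np.diff(exited) >= -1e-6 * feedback_nominal.N0)

    def test_primordial_pool_never_grows(self, feedback_nominal, rate_map55):
        traj = simulate_dde(feedback_nominal, 30.0, rate_map=rate_map55)
        assert np.all(np.diff(traj.n1) < 0)
        assert traj.n2.min() >= 0

    def test_step_halving_converged(self, feedback_nominal, rate_map55):
        td1 = depletion_time_from_trajectory(
            simulate_dde(feedback_nominal, 80.0, rate_map=rate_map55, stop_below=500.0), 1e3
        )
        td2 = depletion_time_from_trajectory(
            simulate_dde(
                feedback_nominal, 80.0, rate_map=rate_map55, step_years=0.01, stop_below=500.0
            ),
            1e3,
        )
        assert abs(td1 - td2) < 0.1

    def test_feedback_delays_depletion(self, feedback_nominal, rate_map55):
        td = depletion_time_from_trajectory(
            simulate_dde(feedback_nominal, 80.0, rate_map=rate_map55, stop_below=500.0), 1e3
        )
        no_feedback = np.log(feedback_nominal.N0 / 1e3) / float(rate_map55.rate(0.0))
        assert td > no_feedback

    def test_step_larger_than_delay_rejected(self, feedback_nominal, rate_map55):
        with pytest.raises(ValueError):
            simulate_dde(feedback_nominal, 1.0, rate_map=rate_map55, step_years=1.0)


class TestDepletionCrossing:
    def _analytic(self, r, N0=1e6, n=2001, t_end=80.0):
        t = np.linspace(0, t_end, n)
        return PopulationTrajectory(
            times_years=t,
            n1=N0 * np.exp(-r * t),
            n2=np.zeros_like(t),
            lambda1_used_per_year=np.full_like(t, -r),
            tau_years=0.0,
            N0=N0,
        )

    def test_exponential_crossing(self):
        r = 0.2
        td = depletion_time_from_trajectory(self._analytic(r), 1e3)
        assert td == pytest.approx(np.log(1e3) / r, rel=1e-4)

    def test_grid_refinement_invariance(self):
        r = 0.2
        td_a = depletion_time_from_trajectory(self._analytic(r, n=2001), 1e3)
        td_b = depletion_time_from_trajectory(self._analytic(r, n=4001), 1e3)
        assert abs(td_a - td_b) < 80.0 / 2000

    def test_no_crossing_reports_final_state(self):
        traj = self._analytic(0.001, t_end=5.0)
        with pytest.raises(ValueError, match="final n1"):
            depletion_time_from_trajectory(traj, 1e3)
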