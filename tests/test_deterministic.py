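"""Closed-form equilibria and the exact piecewise ODE solver."""

import numpy as np
import pytest

import twostate as ts
from twostate import deterministic as det


class TestEquilibrium:
    def test_perfect_adaptation_output_independent_of_signal(self):
        """With dP = 0, Pm* = ks/dPm = 0.01 uM at any signal level."""
        rates = ts.RateSet(dP=0.0)
        for A in (0.0, 1.0, 10.0, 100.0):
            assert det.equilibrium(rates, A).Pm == pytest.approx(0.01, rel=1e-12)

    def test_baseline_equilibria_match_closed_forms(self):
        assert det.equilibrium(ts.RateSet(dP=0.0), 0.0).P == pytest.approx(0.11)
        assert det.equilibrium(ts.RateSet(), 0.0).Pm == pytest.approx(0.01 / 1.11)

    def test_symmetric_independence_when_dpm_vanishes(self):
        """With dPm = 0, P* = ks/dP regardless of the signal."""
        rates = ts.RateSet(dPm=0.0)
        for A in np.linspace(0, 50, 11):
            assert det.equilibrium(rates, A).P == pytest.approx(1.0, rel=1e-12)

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ZeroDivisionError):
            det.equilibrium(ts.RateSet(ks=0, ka=0, kf=0, kr=0, dP=0, dPm=0), 0.0)


class TestSolvePiecewise:
    def test_fixed_point_stays_constant(self):
        rates = ts.RateSet(dP=0.0)
        sig = ts.StepSignal.from_levels([0.0, 0.0])
        x0 = det.equilibrium(rates, 0.0).as_array()
        traj = det.solve_piecewise(rates, sig, x0, np.linspace(0, 100, 33))
        np.testing.assert_allclose(traj.values, np.tile(x0, (33, 1)), rtol=1e-9)

    def test_transient_returns_toward_adapted_level(self):
        """Pm rises after the step at t=50 and relaxes back before t=100."""
        rates = ts.RateSet(dP=0.0)
        sig = ts.paper_step_signal(1.0)
        x0 = det.equilibrium(rates, 0.0).as_array()
        traj = det.solve_piecewise(rates, sig, x0, det.dense_times(sig, 2000))
        pm = traj.series("Pm")
        sel = (traj.times >= 50) & (traj.times < 100)
        assert pm[sel].max() > 1.5 * 0.01
        assert abs(pm[sel][-1] - 0.01) < 0.001

    def test_long_constant_signal_reaches_equilibrium(self):
        rates = ts.RateSet()
        sig = ts.StepSignal.from_levels([1.0], duration=500.0)
        traj = det.solve_piecewise(rates, sig, np.array([0.2, 0.0]), np.array([500.0]))
        eq = det.equilibrium(rates, 1.0)
        np.testing.assert_allclose(traj.values[-1], eq.as_array(), atol=1e-10)

    def test_matches_adaptive_integrator(self):
        """The per-interval exact solution agrees with solve_ivp to 1e-8."""
        from scipy.integrate import solve_ivp

        rates = ts.RateSet()
        sig = ts.paper_step_signal(1.0)
        x0 = det.equilibrium(rates, 0.0).as_array()
        times = ts.paper_time_grid().absolute_times(sig)
        traj = det.solve_piecewise(rates, sig, x0, times)

        # integrate interval by interval so switch discontinuities do not
        # degrade the reference accuracy
        ref_rows = []
        x = x0.copy()
        for t0, t1, lev in sig.intervals:
            M = det.coefficient_matrix(rates, lev)
            b = np.array([rates.ks, 0.0])
            t_eval = times[(times >= t0) & (times <= t1)]
            sol = solve_ivp(lambda t, y: M @ y + b, (t0, t1), x,
                            t_eval=t_eval, rtol=1e-12, atol=1e-16, method="DOP853")
            sel = sol.t < t1 - 1e-12 if t1 < sig.t_end else np.ones_like(sol.t, bool)
            ref_rows.append(sol.y.T[sel])
            x = sol.y[:, -1] if sol.t[-1] == t1 else solve_ivp(
                lambda t, y: M @ y + b, (t0, t1), x, rtol=1e-12, atol=1e-16,
                method="DOP853").y[:, -1]
        ref = np.concatenate(ref_rows)
        np.testing.assert_allclose(traj.values, ref, rtol=1e-8, atol=1e-12)

    def test_matches_brute_force_euler(self):
        """Fine-step explicit Euler reproduces the first stimulation episode."""
        rates = ts.RateSet(dP=0.0)
        sig = ts.paper_step_signal(1.0)
        x0 = det.equilibrium(rates, 0.0).as_array()
        dt = 1e-4
        tgrid = np.arange(0, 100 + dt / 2, dt)
        x = x0.copy()
        b = np.array([rates.ks, 0.0])
        out = {50.0: None, 100.0: None}
        for i, t in enumerate(tgrid[:-1]):
            A = sig.level_at(t)
            x = x + dt * (det.coefficient_matrix(rates, A) @ x + b)
            tn = tgrid[i + 1]
            if abs(tn - 50.0) < dt / 2:
                out[50.0] = x.copy()
            if abs(tn - 100.0) < dt / 2:
                out[100.0] = x.copy()
        traj = det.solve_piecewise(rates, sig, x0, np.array([50.0, 100.0]))
        for k, t in enumerate((50.0, 100.0)):
            np.testing.assert_allclose(traj.values[k], out[t], atol=1e-6)

    def test_times_outside_support_rejected(self):
        rates = ts.RateSet()
        sig = ts.paper_step_signal(1.0)
        with pytest.raises(ValueError):
            det.solve_piecewise(rates, sig, np.array([0.1, 0.01]), np.array([400.0]))


class TestIntervalPeaks:
    def test_constant_trajectory_peak_equals_boundaries(self):
        rates = ts.RateSet(dP=0.0)
        sig = ts.StepSignal.from_levels([1.0, 1.0])
        x0 = det.equilibrium(rates, 1.0).as_array()
        traj = det.solve_piecewise(rates, sig, x0, det.dense_times(sig, 500))
        m = det.interval_peaks(traj, sig)
        np.testing.assert_allclose(m.peaks, m.pre_values, rtol=1e-9)
        np.testing.assert_allclose(m.peaks, m.end_values, rtol=1e-9)

    def test_response_peak_exceeds_prestimulus_value(self):
        rates = ts.RateSet(dP=0.0)
        sig = ts.paper_step_signal(1.0)
        x0 = det.equilibrium(rates, 0.0).as_array()
        traj = det.solve_piecewise(rates, sig, x0, det.dense_times(sig, 2000))
        m = det.interval_peaks(traj, sig)
        assert m.peaks[0] > m.pre_values[0]

    def test_unknown_species_rejected(self):
        rates = ts.RateSet()
        sig = ts.StepSignal.from_levels([0.0])
        traj = det.solve_piecewise(rates, sig, np.array([0.1, 0.01]),
                                   det.dense_times(sig, 100))
        with pytest.raises(KeyError):
            det.interval_peaks(traj, sig, species="X")


class TestEquilibriumConvergence:
    def test_gap_shrinks_with_fold_level(self):
        """Near-perfect equilibria converge onto the dP=0 value as A grows."""
        a1, _ = ts.fold_profiles()
        rows = det.equilibrium_convergence(ts.RateSet(), ts.RateSet(dP=0.0), a1)
        gaps = np.array([r[3] for r in rows])
        assert np.all(np.diff(gaps) < 0)
        assert gaps[-1] < gaps[0] / 100

    def test_identical_rates_give_zero_gap(self):
        a1, _ = ts.fold_profiles()
        rows = det.equilibrium_convergence(ts.RateSet(), ts.RateSet(), a1)
        assert all(r[3] == 0.0 for r in rows)

    def test_gap_matches_closed_forms(self):
        a1, _ = ts.fold_profiles()
        rows = det.equilibrium_convergence(ts.RateSet(), ts.RateSet(dP=0.0), a1)
        A, pm_near, pm_perf, gap = rows[0]
        assert A == 1.0
        assert pm_perf == pytest.approx(0.01)
        expected_near = 0.01 * 2.0 / (0.01 * 10 + 1.0 * (0.01 + 2.0))
        assert pm_near == pytest.approx(expected_near, rel=1e-12)
        assert gap == pytest.approx(abs(expected_near - 0.01), rel=1e-12)
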