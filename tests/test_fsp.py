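"""State enumeration, generator assembly and FSP propagation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import twostate as ts
from twostate import fsp

SPACE = fsp.StateSpace(110, 30)


class TestStateEnumeration:
    @pytest.mark.parametrize("i, j, index", [(0, 0, 1), (110, 30, 3441), (1, 0, 2)])
    def test_enumeration_formula(self, i, j, index):
        assert fsp.state_index(i, j, SPACE) == index

    def test_total_state_count(self):
        assert SPACE.n_states == 3441

    def test_inverse_recovers_state(self):
        assert fsp.state_of_index(112, SPACE) == (0, 1)

    @given(st.integers(0, 110), st.integers(0, 30))
    def test_bijection_on_the_rectangle(self, i, j):
        assert fsp.state_of_index(fsp.state_index(i, j, SPACE), SPACE) == (i, j)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fsp.state_index(111, 0, SPACE)
        with pytest.raises(ValueError):
            fsp.state_of_index(0, SPACE)


class TestGenerator:
    def test_interior_columns_sum_to_zero(self):
        G = fsp.build_generator(ts.RateSet(dP=0.0), 1.0, SPACE)
        sums = np.asarray(G.sum(axis=0)).ravel()
        n = np.tile(np.arange(111), 31)
        m = np.repeat(np.arange(31), 111)
        # states leak iff a reachable jump leaves the rectangle: synthesis
        # or the reverse conversion at n = 110, the conversion at m = 30
        leaky = (n == 110) | ((m == 30) & (n > 0))
        np.testing.assert_allclose(sums[~leaky], 0.0, atol=1e-10)
        assert np.all(sums[leaky] < 0)

    def test_forward_conversion_entry(self):
        """The kf channel feeds (n, m) from (n+1, m-1) at rate (n+1)*kf."""
        rates = ts.RateSet(dP=0.0)
        space = fsp.StateSpace(8, 5)
        G = fsp.build_generator(rates, 0.0, space).toarray()
        n, m = 3, 2
        src = fsp.state_index(n + 1, m - 1, space) - 1
        dst = fsp.state_index(n, m, space) - 1
        assert G[dst, src] == pytest.approx((n + 1) * rates.kf)

    def test_zero_signal_level_removes_ka_dependence(self):
        space = fsp.StateSpace(10, 5)
        g1 = fsp.build_generator(ts.RateSet(ka=1.0), 0.0, space)
        g2 = fsp.build_generator(ts.RateSet(ka=123.0), 0.0, space)
        assert (g1 != g2).nnz == 0

    def test_off_diagonal_entries_non_negative(self):
        G = fsp.build_generator(ts.RateSet(), 2.0, fsp.StateSpace(12, 6)).toarray()
        off = G - np.diag(np.diag(G))
        assert off.min() >= 0.0


class TestPropagation:
    def test_zero_elapsed_time_is_identity(self):
        p0 = fsp.point_mass_vector(SPACE, 60, 6)
        sig = ts.StepSignal.from_levels([0.0])
        out = fsp.propagate(p0, ts.RateSet(dP=0.0), sig, np.array([0.0]))
        np.testing.assert_allclose(out[0].p, p0.p, atol=1e-14)

    def test_matches_dense_euler_on_reduced_space(self):
        """expm propagation equals brute-force Euler (dt=1e-5) per entry."""
        rates = ts.RateSet(ks=0.0005, dP=0.0)
        space = fsp.StateSpace(6, 4)
        p0 = fsp.point_mass_vector(space, 3, 0)
        sig = ts.StepSignal.from_levels([1.0], duration=1.0)
        out = fsp.propagate(p0, rates, sig, np.array([1.0]), mass_threshold=0.9)
        G = fsp.build_generator(rates, 1.0, space).toarray()
        dt = 1e-5
        M = np.eye(space.n_states) + dt * G
        p = p0.p.copy()
        for _ in range(int(round(1.0 / dt))):
            p = M @ p
        np.testing.assert_allclose(out[0].p, p, atol=1e-6)

    def test_mass_monotone_and_threshold_enforced(self, fsp_solution):
        masses = np.array([pv.mass for pv in fsp_solution])
        assert np.all(np.diff(masses) <= 1e-12)
        p0 = fsp.point_mass_vector(fsp.StateSpace(30, 10), 25, 6)
        sig = ts.paper_step_signal(1.0)
        with pytest.raises(fsp.TruncationError):
            fsp.propagate(p0, ts.RateSet(dP=0.0), sig, np.array([50.0]),
                          mass_threshold=0.9999)

    def test_larger_space_retains_more_mass(self):
        rates = ts.RateSet(dP=0.0)
        sig = ts.StepSignal.from_levels([1.0], duration=50.0)
        masses = []
        for mp, mpm in ((80, 20), (110, 30)):
            space = fsp.StateSpace(mp, mpm)
            p0 = fsp.point_mass_vector(space, 60, 6)
            out = fsp.propagate(p0, rates, sig, np.array([50.0]), mass_threshold=0.5)
            masses.append(out[0].mass)
        assert masses[1] >= masses[0]

    def test_near_perfect_variant_keeps_printed_mass_bound(self):
        """With dP=0.01 the 110x30 box retains >= 99.99% through t=150."""
        sc = ts.paper_scenario("near_perfect")
        p0 = fsp.point_mass_vector(SPACE, 60, 6)
        times = sc.sample_times[sc.sample_times <= 150.0]
        out = fsp.propagate(p0, sc.rates, sc.signal, times, mass_threshold=0.9999)
        assert min(pv.mass for pv in out) >= 0.9999

    def test_first_moment_tracks_ode(self, fsp_solution, ode_solution, flagship_scenario):
        scale = flagship_scenario.context.molecules_per_micromolar
        mean_pm = np.array([fsp.first_moment(pv)[1] for pv in fsp_solution])
        ode_pm = ode_solution.series("Pm") * scale
        np.testing.assert_allclose(mean_pm, ode_pm, atol=0.02)


class TestDistributions:
    def test_point_mass_marginals(self):
        pv = fsp.point_mass_vector(SPACE, 60, 6)
        mp = fsp.marginal(pv, "P")
        mm = fsp.marginal(pv, "Pm")
        assert mp[60] == 1.0 and mp.sum() == 1.0
        assert mm[6] == 1.0

    def test_uniform_vector_has_uniform_marginals(self):
        space = fsp.StateSpace(4, 3)
        p = np.full(space.n_states, 1.0 / space.n_states)
        pv = fsp.ProbabilityVector(0.0, p, space)
        np.testing.assert_allclose(fsp.marginal(pv, "P"), 1 / 5, rtol=1e-12)
        np.testing.assert_allclose(fsp.marginal(pv, "Pm"), 1 / 4, rtol=1e-12)

    def test_set_probability_full_range_is_mass(self, fsp_solution):
        pv = fsp_solution[-1]
        assert fsp.set_probability(pv, "Pm", 0, 30) == pytest.approx(pv.mass)

    def test_probability_sets_partition_the_mass(self, fsp_solution):
        """The tracked sets 0-4, 5-6 and 7-30 molecules partition the mass."""
        pv = fsp_solution[17]  # t = 100
        parts = [fsp.set_probability(pv, "Pm", lo, hi)
                 for lo, hi in ((0, 4), (5, 6), (7, 30))]
        assert sum(parts) == pytest.approx(pv.mass, abs=1e-12)

    def test_inverted_bounds_rejected(self, fsp_solution):
        with pytest.raises(ValueError):
            fsp.set_probability(fsp_solution[0], "Pm", 6, 5)

    def test_first_moment_point_mass(self):
        pv = fsp.point_mass_vector(SPACE, 60, 6)
        assert fsp.first_moment(pv) == (60.0, 6.0)

    def test_first_moment_against_monte_carlo(self, fsp_solution):
        """Sampling 1e5 states from the PDF reproduces the first moment."""
        pv = fsp_solution[-1]
        rng = np.random.default_rng(42)
        idx = rng.choice(pv.space.n_states, size=100_000, p=pv.p / pv.mass)
        n = idx % (pv.space.max_p + 1)
        m = idx // (pv.space.max_p + 1)
        mean_p, mean_pm = fsp.first_moment(pv)
        for sample, mean in ((n, mean_p), (m, mean_pm)):
            se = sample.std() / np.sqrt(len(sample))
            assert abs(sample.mean() - mean) < 3 * se

    def test_poisson_distance_zero_cases(self):
        from scipy.stats import poisson

        assert fsp.poisson_distance(np.array([1.0]), 0.0) == 0.0
        marg = poisson.pmf(np.arange(31), 6.0)
        assert fsp.poisson_distance(marg, 6.0) == pytest.approx(
            1 - poisson.cdf(30, 6.0), abs=1e-12)

    def test_joint_factorizes_into_poisson_product(self, fsp_solution):
        """At interval endpoints the joint law is a product of Poissons."""
        pv = fsp_solution[17]  # t = 100, end of the first stimulation
        mean_p, mean_pm = fsp.first_moment(pv)
        ref = fsp.poisson_product_vector(pv.space, mean_p, mean_pm)
        tv = 0.5 * np.abs(pv.p / pv.mass - ref.p).sum() + 0.5 * (1 - ref.mass)
        assert tv < 0.02
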