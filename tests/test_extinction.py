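import math

import numpy as np
import pytest
from scipy import stats

from rescuekit import (
    DurationDistribution,
    ModelParams,
    end_of_harsh_distribution,
    harsh_phase_solution,
    mean_qF,
    p0_F,
    p0_H,
    qF_distribution,
    rapid_extinction_prob,
    total_extinction_time,
)
from rescuekit.extinction import (
    mean_extinction_time_constant,
    pure_death_mean_extinction_time,
)
from rescuekit.simulate import ensemble_records


class TestHarshPhaseSolution:
    def test_pure_death_extinction_mass_closed_form(self, baseline):
        sol = harsh_phase_solution(baseline, N0=1, t_max=10.0, n_times=11)
        assert sol.extinction_mass[-1] == pytest.approx(1 - math.exp(-1.0), abs=1e-10)

    def test_initial_condition_is_point_mass(self, baseline):
        sol = harsh_phase_solution(baseline, N0=90, t_max=10.0)
        assert sol.P[0, 90] == pytest.approx(1.0)
        assert sol.P[0].sum() == pytest.approx(1.0)

    def test_rows_are_distributions_and_extinction_monotone(self):
        p = ModelParams(b_WH=0.01)
        sol = harsh_phase_solution(p, N0=90, t_max=80.0, n_times=41)
        assert np.allclose(sol.P.sum(axis=1), 1.0, atol=1e-8)
        assert np.all(np.diff(sol.extinction_mass) >= -1e-12)

    def test_pure_death_marginal_is_binomial(self, baseline):
        sol = harsh_phase_solution(baseline, N0=90, t_max=30.0, n_times=4)
        p_surv = math.exp(-0.1 * 30.0)
        expected = stats.binom.pmf(np.arange(101), 90, p_surv)
        assert np.allclose(sol.P[-1], expected, atol=1e-10)

    def test_imperfect_harsh_matches_stochastic_simulation(self):
        # master equation vs SSA: extinction mass at t=60 under b_WH=0.01
        p = ModelParams(b_WH=0.01, mu=0.0)
        mass = harsh_phase_solution(p, N0=90, t_max=60.0, n_times=2).extinction_mass[-1]
        rec = ensemble_records(p, DurationDistribution(1e6), n_reps=3000, seed=11)
        phat = (rec.T0 <= 60.0).mean()
        se = np.sqrt(phat * (1 - phat) / len(rec))
        assert abs(mass - phat) < 3 * se

    def test_invalid_horizon(self, baseline):
        with pytest.raises(ValueError):
            harsh_phase_solution(baseline, N0=90, t_max=0.0)


class TestHarshExtinctionProbability:
    def test_vanishes_for_short_phases(self, baseline):
        assert p0_H(baseline, DurationDistribution(0.1)) < 1e-12

    def test_certain_for_very_long_phases(self, baseline, tau0h):
        assert p0_H(baseline, DurationDistribution(10 * tau0h)) >= 0.999

    def test_monotone_in_tau(self, baseline):
        taus = [20.0, 30.0, 45.0, 60.0, 90.0]
        vals = [p0_H(baseline, DurationDistribution(t)) for t in taus]
        assert np.all(np.diff(vals) > 0)

    def test_quadrature_matches_monte_carlo_over_durations(self, baseline, rng):
        d = DurationDistribution(45.0, 4.5)
        t = d.sample(rng, 100_000)
        mass = (-np.expm1(-0.1 * t)) ** 90  # pure-death closed form per draw
        se = mass.std() / np.sqrt(mass.size)
        assert abs(p0_H(baseline, d) - mass.mean()) < 3 * se

    def test_sigma_to_zero_limit_consistent(self, baseline):
        det = p0_H(baseline, DurationDistribution(45.0))
        near = p0_H(baseline, DurationDistribution(45.0, 45.0e-6))
        assert near == pytest.approx(det, rel=1e-4)


class TestEndOfHarshDistribution:
    def test_matches_conditioned_binomial(self, baseline):
        d = DurationDistribution(22.5)
        got = end_of_harsh_distribution(baseline, d)
        p_surv = math.exp(-0.1 * 22.5)
        pmf = stats.binom.pmf(np.arange(1, 101), 90, p_surv)
        pmf /= pmf.sum()
        assert np.allclose(got, pmf, atol=1e-10)
        assert got.sum() == pytest.approx(1.0, abs=1e-10)

    def test_short_phase_leaves_population_near_start(self, baseline):
        got = end_of_harsh_distribution(baseline, DurationDistribution(0.5))
        sizes = np.arange(1, 101)
        assert got[sizes >= 80].sum() > 0.99

    def test_conditioning_on_null_event_raises(self, baseline):
        with pytest.raises(ValueError, match="null event"):
            end_of_harsh_distribution(baseline, DurationDistribution(5000.0))


class TestRapidExtinction:
    def test_already_extinct(self, baseline):
        assert rapid_extinction_prob(baseline, 0) == 1.0

    def test_single_founder_close_to_branching_ratio(self, baseline):
        # low-density approximation d_W / b_WF
        assert rapid_extinction_prob(baseline, 1) == pytest.approx(0.1, rel=0.10)

    def test_gompertz_single_founder_approximation(self):
        from rescuekit import GrowthLaw

        p = ModelParams(growth=GrowthLaw("gompertz"))
        got = rapid_extinction_prob(p, 1)
        assert got == pytest.approx(0.1 / math.log(100), rel=0.10)

    def test_monotone_decreasing_in_founders(self, baseline):
        vals = [rapid_extinction_prob(baseline, n) for n in range(1, 40)]
        assert np.all(np.diff(vals) < 0)

    def test_matches_first_passage_monte_carlo(self, baseline, rng):
        # independent oracle: direct Gillespie of the favourable-phase chain
        # from n founders until absorption at 0 or recovery to ceil(N*)=90
        def ruin_once(n):
            while 0 < n < 90:
                lam = n * 1.0 * (1 - n / 100)
                mu = n * 0.1
                n += 1 if rng.random() < lam / (lam + mu) else -1
            return n == 0

        for n0 in (1, 3):
            hits = sum(ruin_once(n0) for _ in range(4000))
            phat = hits / 4000
            se = math.sqrt(phat * (1 - phat) / 4000)
            assert abs(rapid_extinction_prob(baseline, n0) - phat) < 3 * se


class TestCycleCountLaw:
    def test_certain_first_phase_death(self):
        assert qF_distribution(1.0, 0.0, 0) == 1.0
        assert mean_qF(1.0, 0.0) == 0.0

    def test_geometric_mean_example(self):
        assert mean_qF(0.5, 0.0) == pytest.approx(1.0)

    def test_distribution_sums_to_one_and_mean_matches(self):
        ph, pf = 0.3, 0.05
        s = (1 - ph) * (1 - pf)
        k = np.arange(0, 2000)
        pmf = np.array([qF_distribution(ph, pf, int(i)) for i in k])
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert (k * pmf).sum() == pytest.approx(mean_qF(ph, pf), abs=1e-12)

    def test_matches_bernoulli_cycle_monte_carlo(self, rng):
        ph, pf = 0.3, 0.05
        s = (1 - ph) * (1 - pf)
        # geometric number of survived cycles with per-cycle survival s
        qf = rng.geometric(1 - s, size=100_000) - 1
        se = qf.std() / np.sqrt(qf.size)
        assert abs(qf.mean() - mean_qF(ph, pf)) < 3 * se

    def test_no_absorption_raises(self):
        with pytest.raises(ValueError, match="absorption"):
            mean_qF(0.0, 0.0)


class TestTotalExtinctionTime:
    def test_slow_fluctuations_converge_to_harsh_survival_time(self, baseline, tau0h):
        pred = total_extinction_time(baseline, DurationDistribution(20 * tau0h))
        exact_tau0h = pure_death_mean_extinction_time(90, 0.1)
        assert pred.T0 == pytest.approx(exact_tau0h, rel=0.05)

    def test_environmental_stochasticity_shortens_persistence(self, baseline, tau0h):
        tau = 0.5 * tau0h
        det = total_extinction_time(baseline, DurationDistribution(tau)).T0
        sto = total_extinction_time(baseline, DurationDistribution(tau, 0.1 * tau)).T0
        assert sto < det

    def test_prediction_fields_consistent(self, baseline):
        pred = total_extinction_time(baseline, DurationDistribution(45.0))
        assert 0 <= pred.p0_H <= 1 and 0 <= pred.p0_F <= 1
        assert pred.omega_F == pytest.approx(
            pred.p0_F / (pred.p0_F + pred.p0_H), rel=1e-12
        )
        assert pred.tau_0F == pytest.approx(10.0)
        assert pred.T0 > 0

    def test_exact_harsh_survival_time_exceeds_log_approximation(self, baseline):
        # harmonic-sum mean vs log(N*)/d_W: gap ~ Euler gamma / d_W
        exact = pure_death_mean_extinction_time(90, 0.1)
        approx = math.log(90) / 0.1
        assert exact > approx
        assert exact - approx == pytest.approx(0.5772 / 0.1, rel=0.02)

    def test_constant_environment_solver_matches_pure_death(self):
        from rescuekit import GrowthLaw

        got = mean_extinction_time_constant(GrowthLaw("logistic"), 0.0, 0.1, 100, 90)
        assert got == pytest.approx(pure_death_mean_extinction_time(90, 0.1), rel=1e-9)


class TestFavourableExtinctionProbability:
    def test_negligible_for_short_harsh_phases(self, baseline):
        assert p0_F(baseline, DurationDistribution(1.0)) < 1e-6

    def test_matches_simulated_first_cycle_fates(self, baseline_no_mutation):
        # among realizations surviving the first harsh phase, the fraction
        # dying in the first favourable phase estimates p0_F
        d = DurationDistribution(45.0)
        rec = ensemble_records(baseline_no_mutation, d, n_reps=4000, seed=21)
        survived_first_harsh = rec[(rec.T0 > 45.0) | (rec.extinct_phase == "F")]
        died_fav_first = (
            (survived_first_harsh.T0 <= 90.0)
            & (survived_first_harsh.extinct_phase == "F")
        ).mean()
        analytic = p0_F(baseline_no_mutation, d)
        se = math.sqrt(died_fav_first * (1 - died_fav_first) / len(survived_first_harsh))
        assert abs(analytic - died_fav_first) < 3 * se + 1e-3
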