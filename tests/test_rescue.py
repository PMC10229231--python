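import math

import numpy as np
import pytest

from rescuekit import (
    DurationDistribution,
    GrowthLaw,
    ModelParams,
    RescueAnalytics,
    appearance_time,
    fast_limit,
    harsh_mutant_supply,
    mutant_supply_integrals,
    p_rescue_dn,
    p_rescue_total,
)
from rescuekit.extinction import p0_F, p0_H
from rescuekit.simulate import lineage_fixation_mc


@pytest.fixture(scope="module")
def analytics(baseline):
    return RescueAnalytics(baseline, DurationDistribution(22.5))


class TestFixationProbability:
    def test_critical_lineage_never_fixes(self):
        # constant environment at wild-type equilibrium with a neutral mutant:
        # beta = d_M exactly, so the lineage is critical branching
        p = ModelParams(b_WH=1.0, validate=False)
        ra = RescueAnalytics(p, DurationDistribution(45.0))
        assert ra.pfix(0.0) == 0.0
        assert ra.pfix(60.0) == 0.0

    def test_subcritical_mutant_never_fixes(self):
        p = ModelParams(b_M=0.05, d_M=0.2)
        ra = RescueAnalytics(p, DurationDistribution(45.0))
        assert np.all(ra.pfix_grid == 0.0)

    def test_periodic_in_cycle_time(self, analytics):
        assert analytics.pfix_grid[0] == pytest.approx(
            analytics.pfix_grid[-1], rel=1e-6
        )

    def test_domain_checked(self, analytics):
        with pytest.raises(ValueError):
            analytics.pfix(-1.0)
        with pytest.raises(ValueError):
            analytics.pfix(2 * 22.5 + 1.0)

    def test_matches_direct_lineage_simulation(self, baseline, analytics):
        # cheap smoke version of the lineage oracle (full grid in acceptance)
        d = DurationDistribution(22.5)
        mc = lineage_fixation_mc(baseline, d, t0=11.25, n_reps=3000, seed=2)
        se = math.sqrt(mc * (1 - mc) / 3000)
        assert abs(analytics.pfix(11.25) - mc) < 3 * se


class TestSupplyIntegrals:
    def test_no_mutation_no_supply(self):
        p = ModelParams(mu=0.0)
        assert mutant_supply_integrals(p, DurationDistribution(45.0)) == (0.0, 0.0)

    def test_perfect_harshness_has_no_harsh_supply(self, baseline):
        sh, sf = mutant_supply_integrals(baseline, DurationDistribution(45.0))
        assert sh == 0.0
        assert sf > 0.0

    def test_imperfect_harshness_adds_harsh_supply(self):
        p = ModelParams(b_WH=0.01)
        sh, sf = mutant_supply_integrals(p, DurationDistribution(45.0))
        assert sh > 0.0

    def test_quadrature_grid_converged(self, baseline):
        d = DurationDistribution(22.5)
        coarse = RescueAnalytics(baseline, d, n_grid=4096).supply_integrals[1]
        fine = RescueAnalytics(baseline, d, n_grid=65536).supply_integrals[1]
        assert coarse == pytest.approx(fine, rel=1e-6)


class TestRescueProbability:
    def test_no_mutation_no_de_novo_rescue(self):
        p = ModelParams(mu=0.0)
        assert p_rescue_dn(p, DurationDistribution(45.0)) == 0.0

    def test_saturating_supply_limit(self, tau0h):
        # huge mutant supply: every realization with >= 1 favourable phase is
        # rescued, so p_r_DN -> 1 - P_qF(0) = s
        p = ModelParams(mu=0.1)
        d = DurationDistribution(45.0)
        s = (1 - p0_H(p, d)) * (1 - p0_F(p, d))
        assert p_rescue_dn(p, d) == pytest.approx(s, abs=1e-5)

    def test_monotone_decreasing_in_environment_duration(self, baseline):
        taus = [11.25, 22.5, 45.0, 90.0, 180.0]
        vals = [p_rescue_dn(baseline, DurationDistribution(t)) for t in taus]
        assert np.all(np.diff(vals) < 0)

    def test_environmental_stochasticity_hinders_rescue(self, baseline, tau0h):
        tau = 0.5 * tau0h
        vals = [
            p_rescue_dn(baseline, DurationDistribution(tau, f * tau))
            for f in (0.0, 0.1, 1.0)
        ]
        assert vals[0] > vals[1] > vals[2]

    def test_total_rescue_composition(self, baseline):
        d = DurationDistribution(45.0)
        ra = RescueAnalytics(baseline, d)
        assert ra.p_r_total == pytest.approx(
            ra.p_r_SGV + (1 - ra.p_r_SGV) * ra.p_r_DN, abs=1e-15
        )
        assert ra.p_r_SGV <= ra.p_r_total <= 1.0

    def test_subcritical_mutant_leaves_only_de_novo_term(self):
        # pfix = 0 everywhere: standing variation contributes nothing
        p = ModelParams(b_M=0.05, d_M=0.2)
        d = DurationDistribution(45.0)
        assert p_rescue_total(p, d) == p_rescue_dn(p, d)


class TestAppearanceTime:
    def test_first_environment_algebra(self, baseline):
        q_af, t_af, tau_af = appearance_time(baseline, DurationDistribution(22.5))
        assert tau_af == pytest.approx((2 * q_af - 1) * 22.5 + t_af, rel=1e-12)
        assert 0 <= t_af <= 22.5

    def test_frequent_mutation_rescues_in_first_favourable_phases(self, tau0h):
        p = ModelParams(mu=1e-2)  # K mu = 1
        q_af_vals = [
            appearance_time(p, DurationDistribution(m * tau0h))[0]
            for m in (0.5, 1.0, 2.0)
        ]
        assert all(1.0 <= q < 1.5 for q in q_af_vals)
        assert q_af_vals[-1] == pytest.approx(1.0, abs=0.05)

    def test_undefined_without_de_novo_mutation(self):
        p = ModelParams(mu=0.0)
        with pytest.raises(ValueError, match="null event"):
            appearance_time(p, DurationDistribution(45.0))


class TestFastLimit:
    def test_averaged_birth_rate_and_selection(self, baseline):
        fl = fast_limit(baseline)
        assert fl.b_tilde == 0.5
        assert fl.N_tilde_star == pytest.approx(100 * (1 - 0.1 / 0.5))
        assert fl.s_tilde == pytest.approx(1.0)
        assert fl.tau_af_tilde == pytest.approx(
            1.0 / (1e-3 * 80.0 * 0.1 * 1.0), rel=1e-12
        )
        assert fl.T0_tilde > 1e6  # effectively persistent equilibrium

    def test_no_fluctuation_recovers_base_environment(self):
        p = ModelParams(b_WH=1.0, validate=False)
        fl = fast_limit(p)
        assert fl.b_tilde == 1.0
        assert fl.N_tilde_star == pytest.approx(90.0)

    def test_deleterious_effective_mutant_flagged(self):
        p = ModelParams(b_M=0.02, d_M=0.2, validate=False)
        assert fast_limit(p).tau_af_tilde is None


class TestHarshMutantSupply:
    def test_perfect_harshness(self, baseline):
        assert harsh_mutant_supply(baseline) == (0.0, 0.0)

    def test_printed_formula_values(self):
        p = ModelParams(b_WH=0.01)
        n_birth, p_one = harsh_mutant_supply(p)
        assert n_birth == pytest.approx(0.01 * 90 * (200 - 90) / (2 * 0.1 * 100))
        assert n_birth == pytest.approx(4.95)
        assert p_one == pytest.approx(1 - 0.999**4.95, rel=1e-12)
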