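"""Sweep-phase and standing-phase event probabilities."""

import numpy as np
import pytest
from scipy import integrate

from selfsweep import (
    LocusPair,
    PopulationConfig,
    SelectionConfig,
    dp_dt,
    effective_final_epsilon,
    effective_start_frequency,
    event_rates,
    p_mutation_origin,
    p_recombination_standing,
    p_recombination_standing_approx,
    sweep_phase_probabilities,
)

from .oracles import two_lineage_mc


@pytest.fixture
def outcrossing():
    pop = PopulationConfig(N=5000, sigma=0.0)
    sel = SelectionConfig(s=0.05, h=0.5, F=pop.F)
    return pop, sel


class TestEventRates:
    def test_rate_formulas(self):
        pop = PopulationConfig(N=5000, sigma=0.5)
        pair = LocusPair(r=0.01, N=5000, sigma=0.5)
        er = event_rates(pop, pair, 0.2, mu_b=1e-5)
        assert er.Pc == pytest.approx((1 + pop.F) / (2 * 5000 * 0.2))
        assert er.Pr == pytest.approx(2 * pair.r_eff * 0.8)
        assert er.Pm == pytest.approx(2 * 1e-5 * 0.8 / 0.2)
        assert er.total == pytest.approx(er.Pc + er.Pr + er.Pm)

    def test_frequency_domain(self):
        pop = PopulationConfig(N=5000)
        pair = LocusPair(r=0.01, N=5000)
        with pytest.raises(ValueError):
            event_rates(pop, pair, 0.0)


class TestSweepPhase:
    def test_tightly_linked_has_no_recombination(self, outcrossing):
        pop, sel = outcrossing
        pair = LocusPair(r=0.0, N=pop.N)
        ph = sweep_phase_probabilities(pop, sel, pair, p_lower=0.002)
        assert ph.P_R_sw == pytest.approx(0.0, abs=1e-12)
        assert ph.P_NE + ph.P_C_sw == pytest.approx(1.0, abs=1e-6)

    def test_full_selfing_leaves_only_coalescence(self):
        pop = PopulationConfig(N=5000, sigma=1.0)
        sel = SelectionConfig(s=0.05, h=0.5, F=pop.F)
        pair = LocusPair(r=0.01, N=5000, sigma=1.0)
        ph = sweep_phase_probabilities(pop, sel, pair, p_lower=0.002)
        assert ph.P_R_sw == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("sigma,h,R", [
        (0.0, 0.5, 100.0), (0.0, 0.1, 30.0), (0.5, 0.9, 300.0),
        (0.9, 0.5, 1000.0), (0.99, 0.3, 2000.0),
    ])
    def test_competing_risks_normalization(self, sigma, h, R):
        pop = PopulationConfig(N=5000, sigma=sigma)
        sel = SelectionConfig(s=0.05, h=h, F=pop.F)
        pair = LocusPair.from_scaled(R, 5000, sigma)
        p0a = effective_start_frequency(pop, sel)
        ph = sweep_phase_probabilities(pop, sel, pair, p_lower=p0a, mu_b=2e-5)
        total = ph.P_NE + ph.P_R_sw + ph.P_C_sw + ph.P_M_sw
        assert total == pytest.approx(1.0, abs=1e-6)
        for v in (ph.P_NE, ph.P_R_sw, ph.P_C_sw, ph.P_M_sw):
            assert 0.0 <= v <= 1.0

    def test_one_pass_matches_nested_quadrature(self, outcrossing):
        # the joint-ODE evaluation of the layered integral, cross-checked
        # against an explicit (and much slower) nested quadrature
        pop, sel = outcrossing
        eps = effective_final_epsilon(pop, sel)
        for R in (10.0, 100.0, 1000.0):
            pair = LocusPair.from_scaled(R, pop.N, 0.0)

            def g(p):
                return -dp_dt(p, sel.s, sel.h, pop.F)

            def hazard(p):
                return ((1 + pop.F) / (2 * pop.N * p)
                        + 2 * pair.r_eff * (1 - p)) / g(p)

            def integrand(pp):
                lam, _ = integrate.quad(hazard, pp, 1 - eps, limit=200)
                return np.exp(-lam) * 2 * pair.r_eff * (1 - pp) / g(pp)

            expected, _ = integrate.quad(integrand, 0.002, 1 - eps, limit=200)
            got = sweep_phase_probabilities(pop, sel, pair, 0.002).P_R_sw
            assert got == pytest.approx(expected, rel=1e-5)

    @pytest.mark.parametrize("sigma,h", [(0.0, 0.5), (0.95, 0.3)])
    def test_against_discrete_generation_oracle(self, sigma, h):
        # 1e5 stochastic two-lineage passes along the per-generation path;
        # s is kept small so the per-generation hazards stay well inside the
        # continuous-time regime the integrals assume
        N, s = 50_000, 0.005
        pop = PopulationConfig(N=N, sigma=sigma)
        sel = SelectionConfig(s=s, h=h, F=pop.F)
        r = 0.075 * s * sel.Hl
        pair = LocusPair(r=r, N=N, sigma=sigma)
        p0a = effective_start_frequency(pop, sel)
        ph = sweep_phase_probabilities(pop, sel, pair, p_lower=p0a)
        rng = np.random.default_rng(7)
        p_ne, se_ne, p_r, se_r = two_lineage_mc(N, sigma, s, h, r, p0a, 0.0,
                                                100_000, rng)
        assert abs(ph.P_NE - p_ne) < 3 * se_ne
        assert abs(ph.P_R_sw - p_r) < 3 * se_r


class TestStandingPhase:
    def test_no_recombination_at_zero_distance(self):
        pop = PopulationConfig(N=5000)
        pair = LocusPair(r=0.0, N=5000)
        assert p_recombination_standing(pop, pair, 0.05) == 0.0

    def test_half_point(self):
        # 2 R p0 (1 - p0) = 1 balances the two competing clocks
        pop = PopulationConfig(N=5000)
        R = 1.0 / (2 * 0.05 * 0.95)
        pair = LocusPair.from_scaled(R, 5000, 0.0)
        assert p_recombination_standing(pop, pair, 0.05) == pytest.approx(0.5)

    def test_exact_vs_sigma_approximation(self):
        # the (1-sigma) simplification tracks the exact two-clock ratio to
        # ~0.2% while recombination is loose (r <= 1e-3) and drifts to ~3%
        # by r ~ 0.1 at high selfing, where Phi ~ F starts failing
        for sigma in (0.0, 0.3, 0.6, 0.9, 0.95):
            pop = PopulationConfig(N=5000, sigma=sigma)
            for r in (1e-4, 1e-3, 0.01, 0.05, 0.099):
                pair = LocusPair(r=r, N=5000, sigma=sigma)
                exact = p_recombination_standing(pop, pair, 0.05)
                approx = p_recombination_standing_approx(pop, pair, 0.05)
                tol = 0.002 if r <= 1e-3 else 0.03
                assert approx == pytest.approx(exact, rel=tol, abs=1e-12)

    def test_monotone_in_distance(self):
        pop = PopulationConfig(N=5000, sigma=0.5)
        vals = [p_recombination_standing(
            pop, LocusPair.from_scaled(R, 5000, 0.5), 0.05)
            for R in np.logspace(-1, 3.5, 20)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestMutationOrigin:
    def test_no_mutation_no_softness(self):
        pop = PopulationConfig(N=5000)
        assert p_mutation_origin(pop, 0.0, 0.002) == 0.0

    def test_outcrossing_value(self):
        # Theta_b = 0.2, F = 0, p0A ~ 0: 0.4 / 1.4
        pop = PopulationConfig(N=5000)
        mu_b = 0.2 / (2 * 5000)
        assert p_mutation_origin(pop, mu_b, 1e-9) == pytest.approx(0.4 / 1.4, rel=1e-6)

    def test_selfing_favors_coalescence(self):
        vals = []
        for sigma in (0.0, 0.3, 0.6, 0.9, 0.99):
            pop = PopulationConfig(N=5000, sigma=sigma)
            mu_b = 0.2 / (2 * 5000)
            vals.append(p_mutation_origin(pop, mu_b, 0.002))
        assert all(b < a for a, b in zip(vals, vals[1:]))
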