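"""Tests for the cubic ternary complex model.

Conservation of the four component sums (receptor, Galpha, Gbetagamma,
Ste5) is the arbiter of correctness of the derivative terms; the
ligand-binding sub-network is additionally checked against its closed-form
two-state relaxation.
"""

import dataclasses
import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import gpcrtune.ternary as T
from gpcrtune.ternary import (
    CONSERVATION_GROUPS,
    SPECIES,
    TernaryRateSet,
    TernaryState,
    TernaryTotals,
    default_ternary_rates,
    equilibrate,
    initial_ternary_state,
    sweep_component,
    ternary_dose_response,
    ternary_rhs,
)


def conservation_sums(x: np.ndarray) -> np.ndarray:
    return np.array([x[list(g)].sum() for _, g in CONSERVATION_GROUPS])


class TestDefaults:
    def test_tabulated_base_values(self, base_ternary):
        rates, totals = base_ternary
        assert rates.kL_plus == 4e7
        assert rates.zeta_plus == 1e3
        assert rates.mu_plus == 1.0
        assert totals.R_tot == 4.15e-10
        assert totals.Ga_tot == 4.15e-10
        assert totals.Gbg_tot == totals.Ga_tot

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            TernaryRateSet(kL_plus=-1.0)
        with pytest.raises(ValueError):
            TernaryRateSet(zeta_plus=0.0)  # cooperativity must be > 0


class TestInitialState:
    def test_equal_totals_partition(self):
        t = TernaryTotals(Ste5_tot=2e-10)
        s = initial_ternary_state(t)
        assert s.R == t.R_tot
        assert s.G == t.Ga_tot
        assert s.STE5 == 2e-10
        assert s.aGDP == 0.0 and s.bg == 0.0

    def test_excess_dimer_partition(self):
        t = TernaryTotals(Ga_tot=1e-10, Gbg_tot=2e-10)
        s = initial_ternary_state(t)
        assert s.G == 1e-10 and s.bg == 1e-10 and s.aGDP == 0.0

    def test_zero_totals_give_zero_state(self):
        s = initial_ternary_state(TernaryTotals(0.0, 0.0, 0.0, 0.0, 0.0))
        assert not np.any(s.as_array())

    def test_conservation_sums_match_totals_exactly(self):
        t = TernaryTotals(Ga_tot=3e-10, Gbg_tot=5e-10, Ste5_tot=1e-10)
        x = initial_ternary_state(t).as_array()
        assert conservation_sums(x) == pytest.approx(
            [t.R_tot, t.Ga_tot, t.Gbg_tot, t.Ste5_tot], rel=0, abs=0
        )


class TestRhs:
    def test_zero_state_has_zero_derivative(self, base_ternary):
        rates, _ = base_ternary
        d = ternary_rhs(TernaryState(), rates, 0.0)
        assert not np.any(d.as_array())

    def test_lone_aGTP_hydrolyses(self, base_ternary):
        rates, _ = base_ternary
        c = 2e-10
        d = ternary_rhs(TernaryState(aGTP=c), rates, 0.0)
        assert d.aGDP == pytest.approx(rates.khyd_plus * c)
        assert d.aGTP == pytest.approx(-rates.khyd_plus * c)

    def test_conservation_of_random_states(self, base_ternary, rng):
        rates, _ = base_ternary
        for _ in range(50):
            x = 10.0 ** rng.uniform(-12, -8, len(SPECIES))
            d = T._rhs_vec(x, rates, L=10.0 ** rng.uniform(-10, -4))
            sums = conservation_sums(d)
            scale = np.max(np.abs(d))
            assert np.all(np.abs(sums) <= 1e-12 * scale)

    def test_receptor_group_closes_under_random_rates(self, rng):
        for _ in range(20):
            fields = {
                f.name: 10.0 ** rng.uniform(-4, 4)
                for f in dataclasses.fields(TernaryRateSet)
            }
            rates = TernaryRateSet(**fields)
            x = 10.0 ** rng.uniform(-12, -8, len(SPECIES))
            d = T._rhs_vec(x, rates, 1e-7)
            assert np.all(np.abs(conservation_sums(d)) <= 1e-12 * np.max(np.abs(d)))


class TestEquilibrate:
    def test_frozen_network_stays_at_initial_partition(self, base_ternary):
        # with activation, G binding, dissociation and constitutive routes
        # all off, no reaction can fire from the initial partition at L = 0
        rates, totals = base_ternary
        frozen = rates.replace(
            kact_plus=0.0, kG_plus=0.0, kGRA_minus=0.0, kconact=0.0
        )
        eq = equilibrate(frozen, totals)
        assert eq.converged
        assert eq.state.R == pytest.approx(totals.R_tot, rel=1e-8)
        assert eq.state.G == pytest.approx(totals.Ga_tot, rel=1e-8)

    def test_quiet_g_cycle_still_reaches_binding_equilibrium(self, base_ternary):
        # same setup but with G binding left on: the only reachable motion is
        # R + G <-> RG, which must equilibrate at K = kG_plus/kG_minus
        rates, totals = base_ternary
        frozen = rates.replace(kact_plus=0.0, kGRA_minus=0.0, kconact=0.0)
        eq = equilibrate(frozen, totals)
        s = eq.state
        assert eq.converged
        assert s.bgStarSTE5 == 0.0 and s.aGDP == 0.0
        assert s.RG / (s.R * s.G) == pytest.approx(
            rates.kG_plus / rates.kG_minus, rel=1e-6
        )

    def test_default_parameters_converge_below_tolerance(self, base_ternary):
        rates, totals = base_ternary
        eq = equilibrate(rates, totals)
        assert eq.converged
        assert eq.max_rate < T.DEFAULT_ABS_TOL

    def test_basal_readout_positive_from_constitutive_routes(self, base_ternary):
        rates, totals = base_ternary
        eq = equilibrate(rates, totals)
        assert eq.state.bgStarSTE5 > 0.0

    def test_conservation_held_through_equilibration(self, base_ternary):
        rates, totals = base_ternary
        eq = equilibrate(rates, totals)
        sums = conservation_sums(eq.state.as_array())
        targets = np.array([totals.R_tot, totals.Ga_tot, totals.Gbg_tot, totals.Ste5_tot])
        assert sums == pytest.approx(targets, rel=1e-8)


class TestLigandBindingOracle:
    def test_matches_closed_form_two_state_relaxation(self, base_ternary):
        """With every non-binding reaction off, [LR](t) follows the textbook
        relaxation L*R_tot*kon/(L*kon+koff) * (1 - exp(-(L*kon+koff)t))."""
        rates, totals = base_ternary
        sub = rates.replace(
            kact_plus=0.0, kact_minus=0.0, kG_plus=0.0, kG_minus=0.0,
            kGRA_plus=0.0, kGRA_minus=0.0, khyd_plus=0.0, khyd_minus=0.0,
            kGTP_plus=0.0, kconact=0.0, krev=0.0,
        )
        L = 1e-8
        x0 = initial_ternary_state(totals).as_array()
        k_obs = L * sub.kL_plus + sub.kL_minus
        t_eval = np.linspace(0.0, 3.0 / k_obs, 7)[1:]
        sol = solve_ivp(
            lambda t, x: T._rhs_vec(x, sub, L), (0, t_eval[-1]), x0,
            method="BDF", rtol=1e-12, atol=1e-24, t_eval=t_eval,
        )
        lr = sol.y[SPECIES.index("LR")]
        expected = (
            L * totals.R_tot * sub.kL_plus / k_obs * (1.0 - np.exp(-k_obs * t_eval))
        )
        assert lr == pytest.approx(expected, rel=1e-6)


class TestDoseResponse:
    @pytest.fixture(scope="class")
    def base_curve(self, base_ternary):
        rates, totals = base_ternary
        return ternary_dose_response(rates, totals)

    def test_dose_zero_equals_equilibrated_basal(self, base_ternary, base_curve):
        rates, totals = base_ternary
        eq = equilibrate(rates, totals)
        assert base_curve.responses[0] == pytest.approx(eq.state.bgStarSTE5, rel=1e-9)

    def test_response_nondecreasing_in_dose(self, base_curve):
        r = base_curve.responses
        assert np.all(np.diff(r) >= -1e-10 * r.max())

    def test_ligand_decoupled_curve_is_flat_at_basal(self, base_ternary):
        rates, totals = base_ternary
        deaf = rates.replace(kL_plus=0.0)
        curve = ternary_dose_response(
            rates=deaf, totals=totals, dose_grid=np.array([0.0, 1e-8, 1e-6, 1e-4])
        )
        assert curve.responses == pytest.approx(
            np.full(4, curve.responses[0]), rel=1e-6
        )

    def test_unsorted_grid_rejected(self, base_ternary):
        rates, totals = base_ternary
        with pytest.raises(ValueError):
            ternary_dose_response(rates, totals, dose_grid=np.array([1e-6, 1e-8]))


class TestConservationAlongTrajectories:
    def test_random_parameter_sets_conserve_over_full_trajectories(self, rng):
        """Randomised rates/totals: all four sums stay within 1e-8 relative
        along the ligand-response trajectory."""
        base, _ = default_ternary_rates()
        for _ in range(5):
            scale = {
                f.name: getattr(base, f.name) * 10.0 ** rng.uniform(-1, 1)
                for f in dataclasses.fields(TernaryRateSet)
            }
            rates = TernaryRateSet(**scale)
            totals = TernaryTotals(
                R_tot=10.0 ** rng.uniform(-10.5, -9.5),
                Ga_tot=10.0 ** rng.uniform(-10.5, -9.5),
                Gbg_tot=10.0 ** rng.uniform(-10.5, -9.5),
                Ste5_tot=10.0 ** rng.uniform(-10.5, -9.5),
            )
            x0 = initial_ternary_state(totals).as_array()
            sol = solve_ivp(
                lambda t, x: T._rhs_vec(x, rates, 1e-7), (0.0, 1000.0), x0,
                method="BDF", rtol=T.RTOL, atol=T.ATOL,
                t_eval=np.linspace(0, 1000, 11),
            )
            assert sol.success
            targets = conservation_sums(x0)
            for k in range(sol.y.shape[1]):
                sums = conservation_sums(sol.y[:, k])
                assert sums == pytest.approx(targets, rel=1e-8)
            assert sol.y.min() > -T.ATOL


class TestSweeps:
    @pytest.fixture(scope="class")
    def grid(self):
        return np.concatenate([[0.0], np.logspace(-12, -4, 9)])

    @pytest.fixture(scope="class")
    def factors(self):
        return np.logspace(math.log10(0.03), math.log10(30), 7)

    def test_receptor_sweep_emax_nondecreasing(self, base_ternary, grid, factors):
        rates, totals = base_ternary
        sw = sweep_component(rates, totals, "R_tot", factors=factors, dose_grid=grid)
        emax = sw.summary["emax"].to_numpy()
        assert np.all(np.diff(emax) >= -1e-9 * emax.max())

    def test_galpha_sweep_has_interior_fold_change_optimum(
        self, base_ternary, grid, factors
    ):
        rates, totals = base_ternary
        sw = sweep_component(rates, totals, "Ga_tot", factors=factors, dose_grid=grid)
        fc = sw.summary["fold_change"].to_numpy()
        assert 0 < int(np.argmax(fc)) < fc.size - 1

    def test_galpha_sweep_basal_nonincreasing(self, base_ternary, grid, factors):
        rates, totals = base_ternary
        sw = sweep_component(rates, totals, "Ga_tot", factors=factors, dose_grid=grid)
        basal = sw.summary["basal"].to_numpy()
        assert np.all(np.diff(basal) <= 1e-9 * basal.max())

    def test_gbg_sweep_has_interior_fold_change_optimum(
        self, base_ternary, grid, factors
    ):
        # raising the free dimer pool boosts basal faster than Emax, so the
        # ON/OFF ratio peaks at an intermediate Gbetagamma level
        rates, totals = base_ternary
        sw = sweep_component(rates, totals, "Gbg_tot", factors=factors, dose_grid=grid)
        fc = sw.summary["fold_change"].to_numpy()
        assert 0 < int(np.argmax(fc)) < fc.size - 1

    def test_unknown_component_rejected(self, base_ternary):
        rates, totals = base_ternary
        with pytest.raises(ValueError):
            sweep_component(rates, totals, "Ste5")


def test_bit_identical_determinism(base_ternary):
    rates, totals = base_ternary
    grid = np.concatenate([[0.0], np.logspace(-10, -5, 5)])
    c1 = ternary_dose_response(rates, totals, dose_grid=grid)
    c2 = ternary_dose_response(rates, totals, dose_grid=grid)
    assert np.array_equal(c1.responses, c2.responses)
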