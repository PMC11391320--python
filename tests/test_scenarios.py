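"""Factorial scenario grids, management interventions and sweeps."""

import math
from dataclasses import replace

import numpy as np
import pytest

from patchrecovery.growth_dynamics import LightScenario
from patchrecovery.recovery_time import SimConfig
from patchrecovery.scenarios import (
    Scenario,
    apply_management,
    best_action,
    build_network,
    default_sweep_factors,
    modified_registry,
    run_grid,
    run_scenario,
    sweep_parameter,
    years_saved,
)

LIGHTS = [LightScenario(1.0), LightScenario(0.5), LightScenario(0.25)]


def scenario(**kw):
    defaults = dict(
        species="zostera-like", model="dispersal", n_connected=1,
        light=LightScenario(1.0), management="none",
    )
    defaults.update(kw)
    return Scenario(**defaults)


class TestBuildNetwork:
    def test_star_structure(self, registry):
        growth = registry.growth("zostera-like")
        net = build_network(3, growth, LightScenario(1.0))
        assert net.Q.shape == (4, 4)
        assert np.array_equal(net.Q, net.Q.T)
        assert not np.diag(net.Q).any()
        assert net.Q[0].sum() == 3
        assert net.biomass[0] == 0.0
        assert np.allclose(net.biomass[1:], growth.B_max)

    def test_remnants_sit_at_light_specific_equilibrium(self, registry):
        growth = registry.growth("zostera-like")
        net = build_network(2, growth, LightScenario(0.25))
        assert np.allclose(net.biomass[1:], 0.25 * growth.B_max)

    def test_isolated_disturbed_patch(self, registry):
        net = build_network(0, registry.growth("zostera-like"), LightScenario(1.0))
        assert net.n_connected == 0


class TestManagement:
    def test_stabilize_is_noop_under_dispersal(self, registry):
        base = run_scenario(scenario(management="none"), registry)
        stab = run_scenario(scenario(management="stabilize"), registry)
        assert stab.annual_probability == base.annual_probability
        assert stab.distribution == base.distribution

    def test_stabilize_makes_recruitment_immediate(self, registry):
        stab = run_scenario(
            scenario(model="recruitment", management="stabilize"), registry
        )
        assert stab.annual_probability == 1.0
        assert stab.distribution.is_deterministic

    def test_seed_under_dispersal_recovers_at_growth_time(self, registry):
        seeded = run_scenario(scenario(management="seed"), registry)
        assert seeded.annual_probability == 1.0
        assert seeded.median == pytest.approx(seeded.distribution.translation)

    def test_seed_under_dispersal_lmax_policy(self, registry):
        policy = apply_management(
            scenario(management="seed"), registry, seed_dispersal_policy="lmax"
        )
        assert policy.annual_probability == registry.dispersal.L_max

    def test_seed_under_recruitment_saturates_supply(self, registry):
        seeded = run_scenario(
            scenario(model="recruitment", management="seed"), registry
        )
        assert seeded.annual_probability == pytest.approx(registry.recruitment.R_max)
        # at high connectivity the baseline already sits near saturation
        base_hi = run_scenario(
            scenario(model="recruitment", n_connected=10), registry
        )
        seed_hi = run_scenario(
            scenario(model="recruitment", n_connected=10, management="seed"), registry
        )
        assert seed_hi.annual_probability == pytest.approx(
            base_hi.annual_probability, rel=1e-3
        )

    def test_light_action_reruns_at_full_light(self, registry):
        stressed = scenario(light=LightScenario(0.25), management="light")
        relit = run_scenario(stressed, registry)
        normal = run_scenario(scenario(light=LightScenario(1.0)), registry)
        assert relit.annual_probability == pytest.approx(normal.annual_probability)
        assert relit.distribution == normal.distribution

    def test_unknown_action_rejected(self):
        with pytest.raises(ValueError, match="management"):
            scenario(management="dredge")


class TestRunScenario:
    def test_dispersal_median_strictly_decreasing_in_connectivity(self, registry):
        medians = [
            run_scenario(scenario(n_connected=n), registry).median
            for n in range(1, 11)
        ]
        assert all(a > b for a, b in zip(medians, medians[1:]))

    def test_recruitment_median_plateaus_by_three_patches(self, registry):
        medians = [
            run_scenario(
                scenario(model="recruitment", n_connected=n), registry
            ).median
            for n in range(1, 11)
        ]
        floor = medians[-1]
        assert medians[0] > floor
        # from three connected patches on, within 1% of the asymptotic minimum
        for m in medians[2:]:
            assert m <= medians[0]
            assert m == pytest.approx(floor, rel=0.01)

    def test_analytic_and_simulated_agree(self, registry):
        sc = scenario(n_connected=2, light=LightScenario(0.5))
        analytic = run_scenario(sc, registry, mode="analytic")
        simulated = run_scenario(
            sc, registry, mode="simulate", config=SimConfig(n_reps=100_000, seed=13)
        )
        for key in ("q2.5", "median", "q97.5"):
            tol = max(0.02 * analytic.summary[key], 0.05)
            assert abs(simulated.summary[key] - analytic.summary[key]) < tol

    def test_light_stress_slows_recovery_and_widens_spread(self, registry):
        for model in ("dispersal", "recruitment"):
            gaps = []
            for n in (1, 3, 10):
                normal = run_scenario(
                    scenario(model=model, n_connected=n), registry
                )
                stressed = run_scenario(
                    scenario(model=model, n_connected=n, light=LightScenario(0.25)),
                    registry,
                )
                assert stressed.median > normal.median
                spread = lambda r: r.summary["q97.5"] - r.summary["q2.5"]
                assert spread(stressed) >= spread(normal)
                gaps.append(stressed.median - normal.median)
            # the light-stress penalty shrinks as connectivity grows
            assert gaps[0] > gaps[1] > gaps[2]

    def test_recruitment_light_scenarios_converge_at_high_connectivity(self, registry):
        probs = [
            run_scenario(
                scenario(model="recruitment", n_connected=8, light=l), registry
            ).annual_probability
            for l in LIGHTS
        ]
        assert max(probs) - min(probs) < 0.01 * max(probs)

    def test_no_connections_without_management_never_recovers(self, registry):
        result = run_scenario(scenario(n_connected=0), registry)
        assert result.annual_probability == 0.0
        assert result.distribution.never_recovers
        assert math.isinf(result.median)

    def test_unknown_species_rejected(self, registry):
        with pytest.raises(KeyError, match="unknown species"):
            run_scenario(scenario(species="posidonia-like"), registry)


class TestYearsSaved:
    def test_identical_scenarios_save_zero(self, registry):
        base = run_scenario(scenario(), registry)
        assert years_saved(base, base) == 0.0

    def test_seed_under_dispersal_saves_median_waiting_time(self, registry):
        base = run_scenario(scenario(), registry)
        seeded = run_scenario(scenario(management="seed"), registry)
        lam = base.distribution.rate
        assert years_saved(seeded, base) == pytest.approx(math.log(2) / lam, rel=1e-9)

    def test_never_negative_across_grid(self, registry):
        for model in ("dispersal", "recruitment"):
            for n in (1, 3, 8):
                for light in LIGHTS:
                    base = run_scenario(
                        scenario(model=model, n_connected=n, light=light), registry
                    )
                    for action in ("seed", "stabilize", "light"):
                        managed = run_scenario(
                            scenario(
                                model=model, n_connected=n, light=light,
                                management=action,
                            ),
                            registry,
                        )
                        assert years_saved(managed, base) >= -1e-12

    def test_savings_largest_at_low_connectivity_and_low_light(self, registry):
        def saving(n, light):
            base = run_scenario(scenario(n_connected=n, light=light), registry)
            managed = run_scenario(
                scenario(n_connected=n, light=light, management="seed"), registry
            )
            return years_saved(managed, base)

        assert saving(1, LightScenario(0.25)) > saving(1, LightScenario(1.0))
        assert saving(1, LightScenario(1.0)) > saving(8, LightScenario(1.0))

    def test_mismatched_axes_rejected(self, registry):
        a = run_scenario(scenario(n_connected=1), registry)
        b = run_scenario(scenario(n_connected=2), registry)
        with pytest.raises(ValueError, match="n_connected"):
            years_saved(a, b)


class TestSweep:
    def test_unit_factor_reproduces_base(self, registry):
        base = scenario()
        table = sweep_parameter(base, registry, "tau", factors=[1.0])
        expected = run_scenario(base, registry)
        assert table.loc[0, "feasible"]
        assert table.loc[0, "median"] == pytest.approx(expected.median, rel=1e-12)

    def test_default_grid_is_nine_log_spaced_factors(self):
        factors = default_sweep_factors()
        assert len(factors) == 9
        assert factors[0] == pytest.approx(0.25)
        assert factors[-1] == pytest.approx(4.0)
        ratios = factors[1:] / factors[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_median_nondecreasing_in_tau_under_dispersal(self, registry):
        table = sweep_parameter(scenario(n_connected=2), registry, "tau")
        medians = table.loc[table.feasible, "median"].to_numpy()
        assert (np.diff(medians) >= -1e-9).all()

    def test_recruitment_with_many_patches_insensitive_to_tau(self, registry):
        table = sweep_parameter(
            scenario(model="recruitment", n_connected=10), registry, "tau"
        )
        medians = table.loc[table.feasible, "median"].to_numpy()
        assert medians.max() - medians.min() < 0.05 * medians.min()

    def test_infeasible_cells_flagged_not_dropped(self, registry):
        # L_max = 0.375 so factors > 1/0.375 violate the probability bound
        table = sweep_parameter(scenario(), registry, "L_max")
        assert len(table) == 9
        assert not table.feasible.all()
        bad = table.loc[~table.feasible]
        assert (bad.factor * registry.dispersal.L_max > 1).all()
        assert bad.reason.str.contains("L_max").all()

    def test_unknown_parameter_rejected(self, registry):
        with pytest.raises(ValueError, match="parameter"):
            sweep_parameter(scenario(), registry, "salinity")


class TestBestAction:
    def test_seed_wins_under_dispersal_at_low_connectivity(self, registry):
        ranking = best_action(scenario(n_connected=1), registry)
        assert "seed" in ranking.winners
        assert ranking.ranking[0][0] in ranking.winners

    def test_stabilize_wins_under_recruitment(self, registry):
        ranking = best_action(
            scenario(model="recruitment", n_connected=1), registry
        )
        assert ranking.winners == {"stabilize"}

    def test_stabilize_ties_with_none_under_dispersal(self, registry):
        ranking = best_action(
            scenario(n_connected=1), registry, actions=("none", "stabilize")
        )
        assert ranking.winners == {"none", "stabilize"}

    def test_winner_invariant_across_tau_sweep(self, registry):
        for model, n in (("dispersal", 1), ("recruitment", 1), ("dispersal", 8)):
            winners = set()
            for factor in default_sweep_factors():
                reg = modified_registry(registry, "tau", factor)
                ranking = best_action(scenario(model=model, n_connected=n), reg)
                winners.add(ranking.winners)
            assert len(winners) == 1


def test_run_grid_shape_and_columns(registry):
    df = run_grid(
        registry,
        species=["zostera-like"],
        n_connected=(1, 2),
        light_fractions=(1.0, 0.5),
        managements=("none", "seed"),
    )
    assert len(df) == 2 * 2 * 2 * 2  # model x n x light x management
    for col in ("annual_probability", "median", "q2.5", "q97.5", "t_grow"):
        assert col in df.columns
    assert (df["median"] >= df["t_grow"] - 1e-12).all()
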