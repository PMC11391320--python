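"""Scenario grids, management interventions and sensitivity sweeps.

The study design crosses species x light stress (1.0 / 0.5 / 0.25 of
normal light) x number of connected remnant patches (1-10) x
recolonization model (uncertain dispersal / uncertain recruitment) x
management action, on a star network: one disturbed patch connected to
``n`` identical remnant patches, each at the light-specific equilibrium
biomass.

Management actions translate to changes in the effective recolonization
probability or light level:

* ``seed`` (spread propagules / plant) saturates propagule supply at the
  disturbed patch: under uncertain dispersal the only stochastic step is
  removed (colonization immediate); under uncertain recruitment the
  probability rises to its supply-saturated maximum ``R_max``.
* ``stabilize`` (e.g. sediment stabilization) makes recruitment of
  available propagules certain: under uncertain recruitment colonization
  becomes immediate; under uncertain dispersal recruitment was already
  certain, so nothing changes.
* ``light`` (catchment action improving benthic light) removes the
  chronic light stress: the scenario is re-run at full light, which
  raises both remnant biomass (hence colonization probability) and the
  growth rate of the recovering patch.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .growth_dynamics import GrowthParams, LightScenario, equilibrium_biomass
from .recolonization import (
    DispersalParams,
    PatchNetwork,
    RecruitmentParams,
    annual_dispersal_probability,
    annual_recruitment_probability,
)
from .recovery_time import (
    RecoveryDistribution,
    SimConfig,
    analytic_distribution,
    simulate_recovery_times,
    summarize_samples,
)
from .registry import ParameterRegistry

__all__ = [
    "Scenario",
    "ScenarioResult",
    "EffectivePolicy",
    "MODELS",
    "MANAGEMENT_ACTIONS",
    "build_network",
    "apply_management",
    "run_scenario",
    "run_grid",
    "years_saved",
    "sweep_parameter",
    "modified_registry",
    "best_action",
    "ActionRanking",
    "SWEEPABLE_PARAMETERS",
    "default_sweep_factors",
]

MODELS = ("dispersal", "recruitment")
MANAGEMENT_ACTIONS = ("none", "seed", "stabilize", "light")
SWEEPABLE_PARAMETERS = ("L_max", "R_max", "tau", "nu", "r_max", "B_max")


@dataclass(frozen=True)
class Scenario:
    """One factorial cell: species x model x connectivity x light x action."""

    species: str
    model: Literal["dispersal", "recruitment"]
    n_connected: int
    light: LightScenario = LightScenario(1.0)
    management: str = "none"
    fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.management not in MANAGEMENT_ACTIONS:
            raise ValueError(
                f"management must be one of {MANAGEMENT_ACTIONS}, "
                f"got {self.management!r}"
            )
        if self.n_connected < 0:
            raise ValueError(f"n_connected must be >= 0, got {self.n_connected}")
        if not 0 < self.fraction < 1:
            raise ValueError(f"fraction must lie in (0, 1), got {self.fraction}")


@dataclass(frozen=True)
class EffectivePolicy:
    """Effective recolonization policy after a management action.

    ``light`` is the light scenario actually experienced (reset to full
    light by the ``light`` action) and ``annual_probability`` the
    effective annual colonization probability (1.0 when the action makes
    colonization immediate).
    """

    light: LightScenario
    annual_probability: float


@dataclass(frozen=True)
class ScenarioResult:
    scenario: Scenario
    annual_probability: float
    distribution: RecoveryDistribution
    summary: dict
    seed: int | None = None

    @property
    def median(self) -> float:
        return self.summary["median"]

    def statistic(self, statistic) -> float:
        if statistic == "median":
            return self.summary["median"]
        if statistic == "mean":
            return self.summary["mean"]
        if isinstance(statistic, (int, float)) and 0 < statistic < 1:
            return self.distribution.quantile(float(statistic))
        raise ValueError(f"unknown statistic {statistic!r}")


def build_network(
    n_connected: int, growth: GrowthParams, light: LightScenario
) -> PatchNetwork:
    """Star network: disturbed patch 0 linked to ``n_connected`` remnants.

    All remnant patches sit at the same light-specific equilibrium
    biomass, reflecting equal patch size and equal chronic stress across
    the patch network.
    """
    if n_connected < 0:
        raise ValueError(f"n_connected must be >= 0, got {n_connected}")
    size = n_connected + 1
    Q = np.zeros((size, size))
    Q[0, 1:] = 1.0
    Q[1:, 0] = 1.0
    biomass = np.full(size, equilibrium_biomass(growth, light))
    biomass[0] = 0.0
    return PatchNetwork(Q=Q, biomass=biomass, disturbed_index=0)


def _baseline_probability(
    scenario: Scenario, registry: ParameterRegistry, light: LightScenario
) -> float:
    growth = registry.growth(scenario.species)
    network = build_network(scenario.n_connected, growth, light)
    if scenario.model == "dispersal":
        return annual_dispersal_probability(network, registry.dispersal)
    return annual_recruitment_probability(network, registry.recruitment)


def apply_management(
    scenario: Scenario,
    registry: ParameterRegistry,
    seed_dispersal_policy: Literal["immediate", "lmax"] = "immediate",
) -> EffectivePolicy:
    """Resolve a scenario's management action into an effective policy.

    ``seed_dispersal_policy`` selects how propagule seeding interacts
    with the uncertain dispersal model: ``"immediate"`` (default)
    removes the stochastic dispersal step entirely; ``"lmax"`` instead
    caps the probability at ``L_max`` for robustness checks.
    """
    light = scenario.light
    if scenario.management == "light":
        light = LightScenario(1.0)
    p = _baseline_probability(scenario, registry, light)
    if scenario.management == "seed":
        if scenario.model == "dispersal":
            p = 1.0 if seed_dispersal_policy == "immediate" else registry.dispersal.L_max
        else:
            p = registry.recruitment.R_max
    elif scenario.management == "stabilize":
        if scenario.model == "recruitment":
            p = 1.0
        # dispersal model: recruitment is already certain; unchanged
    return EffectivePolicy(light=light, annual_probability=p)


def run_scenario(
    scenario: Scenario,
    registry: ParameterRegistry,
    mode: Literal["analytic", "simulate"] = "analytic",
    config: SimConfig | None = None,
    seed_dispersal_policy: Literal["immediate", "lmax"] = "immediate",
) -> ScenarioResult:
    """Compose network -> recolonization probability -> recovery-time law.

    ``analytic`` mode evaluates the translated-exponential law exactly
    and is deterministic; ``simulate`` draws a Monte Carlo sample under
    ``config`` and summarizes it empirically.
    """
    growth = registry.growth(scenario.species)
    policy = apply_management(scenario, registry, seed_dispersal_policy)
    dist = analytic_distribution(
        policy.annual_probability, growth, policy.light, scenario.fraction
    )
    if mode == "analytic":
        summary = dist.summary()
        seed = None
    elif mode == "simulate":
        config = config or SimConfig()
        sample = simulate_recovery_times(
            policy.annual_probability, growth, policy.light, scenario.fraction, config
        )
        summary = summarize_samples(sample)
        seed = config.seed
    else:
        raise ValueError(f"mode must be 'analytic' or 'simulate', got {mode!r}")
    return ScenarioResult(
        scenario=scenario,
        annual_probability=policy.annual_probability,
        distribution=dist,
        summary=summary,
        seed=seed,
    )


def _result_row(result: ScenarioResult) -> dict:
    s = result.scenario
    row = {
        "species": s.species,
        "model": s.model,
        "n_connected": s.n_connected,
        "light_fraction": s.light.light_fraction,
        "management": s.management,
        "fraction": s.fraction,
        "annual_probability": result.annual_probability,
        "rate": result.distribution.rate,
        "t_grow": result.distribution.translation,
    }
    row.update(result.summary)
    return row


def run_grid(
    registry: ParameterRegistry,
    species: Sequence[str],
    models: Sequence[str] = MODELS,
    n_connected: Sequence[int] = tuple(range(1, 11)),
    light_fractions: Sequence[float] = (1.0, 0.5, 0.25),
    managements: Sequence[str] = ("none",),
    fraction: float = 0.5,
    mode: Literal["analytic", "simulate"] = "analytic",
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Run a factorial grid and return one tidy row per scenario cell."""
    rows = []
    for sp, model, n, lf, mgmt in itertools.product(
        species, models, n_connected, light_fractions, managements
    ):
        scenario = Scenario(
            species=sp,
            model=model,
            n_connected=n,
            light=LightScenario(lf),
            management=mgmt,
            fraction=fraction,
        )
        rows.append(_result_row(run_scenario(scenario, registry, mode, config)))
    return pd.DataFrame(rows)


def years_saved(
    managed: ScenarioResult,
    baseline: ScenarioResult,
    statistic="median",
) -> float:
    """Reduction in a recovery-time statistic relative to no management.

    ``statistic(baseline) - statistic(managed)``; non-negative for every
    implemented action under this model.  Both results must describe the
    same species, model, connectivity and recovery threshold.
    """
    for attr in ("species", "model", "n_connected", "fraction"):
        a, b = getattr(managed.scenario, attr), getattr(baseline.scenario, attr)
        if a != b:
            raise ValueError(
                f"cannot compare scenarios differing in {attr}: {a!r} vs {b!r}"
            )
    return baseline.statistic(statistic) - managed.statistic(statistic)


def default_sweep_factors(n: int = 9) -> np.ndarray:
    """Log-spaced multipliers spanning a four-fold decrease to increase."""
    return np.geomspace(0.25, 4.0, n)


def modified_registry(
    registry: ParameterRegistry, parameter: str, factor: float
) -> ParameterRegistry:
    """Registry with one parameter multiplied by ``factor``.

    ``tau`` and ``nu`` are shared by the two colonization curves and are
    scaled in both; ``L_max``/``R_max`` scale their own curve; ``r_max``
    and ``B_max`` scale every species entry.  Invariant violations (e.g.
    a maximum probability above 1) propagate as ``ValueError``.
    """
    if parameter not in SWEEPABLE_PARAMETERS:
        raise ValueError(
            f"parameter must be one of {SWEEPABLE_PARAMETERS}, got {parameter!r}"
        )
    dispersal, recruitment, species = (
        registry.dispersal,
        registry.recruitment,
        dict(registry.species),
    )
    if parameter == "L_max":
        dispersal = replace(dispersal, L_max=dispersal.L_max * factor)
    elif parameter == "R_max":
        recruitment = replace(recruitment, R_max=recruitment.R_max * factor)
    elif parameter in ("tau", "nu"):
        dispersal = replace(dispersal, **{parameter: getattr(dispersal, parameter) * factor})
        recruitment = replace(
            recruitment, **{parameter: getattr(recruitment, parameter) * factor}
        )
    elif parameter == "r_max":
        species = {k: replace(g, r_max=g.r_max * factor) for k, g in species.items()}
    elif parameter == "B_max":
        species = {k: replace(g, B_max=g.B_max * factor) for k, g in species.items()}
    return ParameterRegistry(
        species=species,
        dispersal=dispersal,
        recruitment=recruitment,
        provenance=dict(registry.provenance),
        seed=registry.seed,
    )


def sweep_parameter(
    base: Scenario,
    registry: ParameterRegistry,
    parameter: str,
    factors: Sequence[float] | None = None,
    mode: Literal["analytic", "simulate"] = "analytic",
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Multiplicative sensitivity sweep of one parameter.

    Returns one row per multiplier; a multiplier whose scaled value
    violates a parameter invariant is flagged ``feasible=False`` (with
    the reason) rather than dropped.
    """
    if parameter not in SWEEPABLE_PARAMETERS:
        raise ValueError(
            f"parameter must be one of {SWEEPABLE_PARAMETERS}, got {parameter!r}"
        )
    if factors is None:
        factors = default_sweep_factors()
    rows = []
    for factor in factors:
        row = {"parameter": parameter, "factor": float(factor)}
        try:
            reg = modified_registry(registry, parameter, float(factor))
            result = run_scenario(base, reg, mode, config)
        except (ValueError, KeyError) as err:
            row.update({"feasible": False, "reason": str(err)})
        else:
            row.update({"feasible": True, "reason": ""})
            row.update(_result_row(result))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ActionRanking:
    """Full ranking of management actions by median recovery time.

    ``ranking`` lists (action, median) pairs sorted fastest first;
    ``winners`` is the set of actions tied for the fastest median (ties
    at relative tolerance 1e-9 are reported together, never broken
    arbitrarily).
    """

    ranking: tuple
    winners: frozenset

    @property
    def best(self) -> frozenset:
        return self.winners


def best_action(
    scenario: Scenario,
    registry: ParameterRegistry,
    actions: Sequence[str] = MANAGEMENT_ACTIONS,
    mode: Literal["analytic", "simulate"] = "analytic",
    config: SimConfig | None = None,
) -> ActionRanking:
    """Rank management actions by median recovery time for one cell."""
    if len(actions) < 2:
        raise ValueError("need at least two actions to rank")
    medians = {}
    for action in actions:
        result = run_scenario(replace(scenario, management=action), registry, mode, config)
        medians[action] = result.median
    ranking = tuple(sorted(medians.items(), key=lambda kv: kv[1]))
    best_median = ranking[0][1]
    winners = frozenset(
        a for a, m in medians.items() if math.isclose(m, best_median, rel_tol=1e-9)
    )
    return ActionRanking(ranking=ranking, winners=winners)
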