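"""Recovery-time laws: translated exponentials and a Monte Carlo simulator.

Recovery time of the disturbed patch decomposes into a stochastic
colonization waiting time plus a deterministic regrowth time:

* the waiting time until successful colonization is exponential with
  hazard ``lambda = -ln(1 - p)``, where ``p`` is the annual
  recolonization probability — chosen so the one-year survival of the
  continuous law matches the annual Bernoulli model exactly, while
  still allowing sub-annual recovery times;
* once colonized, the patch grows deterministically for ``t_grow``
  years until it crosses the recovery threshold (50% of the
  light-specific equilibrium biomass by default).

The recovery time is therefore exponentially distributed with rate
``lambda``, translated by ``t_grow``; its quantiles and moments are in
closed form, and the Monte Carlo simulator exists to validate them and
to support the discrete "annual" trial variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import stats

from .growth_dynamics import GrowthParams, LightScenario, time_to_fraction

__all__ = [
    "RecoveryDistribution",
    "RecoverySample",
    "SimConfig",
    "hazard_from_annual_probability",
    "analytic_distribution",
    "distribution_quantile",
    "simulate_recovery_times",
    "summarize_samples",
    "SUMMARY_QUANTILES",
]

# quantile convention: "95% quantiles" = (0.025, 0.975), "75%" = (0.125, 0.875)
SUMMARY_QUANTILES = (0.025, 0.125, 0.5, 0.875, 0.975)


@dataclass(frozen=True)
class RecoveryDistribution:
    """Translated-exponential recovery-time law.

    ``rate`` is the colonization hazard (1/year); ``translation`` the
    deterministic growth time t_grow (years).  Support is
    ``[translation, inf)``.  ``rate = inf`` encodes certain immediate
    colonization (recovery exactly at t_grow); ``rate = 0`` encodes the
    no-recovery sentinel (colonization probability 0).
    """

    rate: float
    translation: float

    def __post_init__(self) -> None:
        if self.rate < 0 or math.isnan(self.rate):
            raise ValueError(f"rate must be >= 0, got {self.rate}")
        if self.translation < 0:
            raise ValueError(f"translation must be >= 0, got {self.translation}")

    @property
    def never_recovers(self) -> bool:
        return self.rate == 0.0

    @property
    def is_deterministic(self) -> bool:
        return math.isinf(self.rate)

    def _frozen(self):
        return stats.expon(loc=self.translation, scale=1.0 / self.rate)

    @property
    def mean(self) -> float:
        if self.never_recovers:
            return math.inf
        if self.is_deterministic:
            return self.translation
        return float(self._frozen().mean())

    @property
    def variance(self) -> float:
        if self.never_recovers:
            return math.inf
        if self.is_deterministic:
            return 0.0
        return float(self._frozen().var())

    @property
    def median(self) -> float:
        return self.quantile(0.5)

    def quantile(self, q: float) -> float:
        """Recovery-time quantile ``translation - ln(1 - q) / rate``."""
        if not 0 < q < 1:
            raise ValueError(f"quantile level must lie in (0, 1), got {q}")
        if self.never_recovers:
            return math.inf
        if self.is_deterministic:
            return self.translation
        return float(self._frozen().ppf(q))

    def cdf(self, t: float) -> float:
        if self.never_recovers:
            return 0.0
        if self.is_deterministic:
            return 1.0 if t >= self.translation else 0.0
        return float(self._frozen().cdf(t))

    def summary(self) -> dict:
        """Closed-form summary on the same keys as :func:`summarize_samples`."""
        out = {f"q{100 * q:g}": self.quantile(q) for q in SUMMARY_QUANTILES}
        out["median"] = out.pop("q50")
        out["mean"] = self.mean
        out["fraction_censored"] = 0.0
        return out


@dataclass(frozen=True)
class SimConfig:
    """Monte Carlo settings: replicates, seed, censoring horizon, time mode.

    ``time_mode="continuous"`` draws exponential colonization waiting
    times; ``"annual"`` draws the colonization year from discrete annual
    Bernoulli trials (geometric).  Replicates whose recovery time exceeds
    ``max_years`` are flagged censored, never dropped.
    """

    n_reps: int = 100_000
    seed: int = 0
    max_years: float = 200.0
    time_mode: Literal["continuous", "annual"] = "continuous"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")
        if not self.max_years > 0:
            raise ValueError(f"max_years must be positive, got {self.max_years}")
        if self.time_mode not in ("continuous", "annual"):
            raise ValueError(f"unknown time_mode {self.time_mode!r}")


@dataclass(frozen=True)
class RecoverySample:
    """Monte Carlo recovery times with censoring flags and provenance."""

    times: np.ndarray
    censored: np.ndarray
    config: SimConfig

    @property
    def fraction_censored(self) -> float:
        return float(self.censored.mean())


def hazard_from_annual_probability(p: float) -> float:
    """Colonization hazard ``lambda = -ln(1 - p)`` (1/year).

    Chosen so the exponential one-year survival ``exp(-lambda)`` equals
    ``1 - p``, matching the annual Bernoulli model.  ``p = 1`` maps to
    the ``inf`` sentinel (immediate colonization) and ``p = 0`` to the
    ``0`` sentinel (no recovery).
    """
    if not 0 <= p <= 1:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    if p == 1.0:
        return math.inf
    return -math.log1p(-p)


def analytic_distribution(
    p: float,
    growth: GrowthParams,
    light: LightScenario,
    fraction: float = 0.5,
) -> RecoveryDistribution:
    """Exact recovery-time law for annual colonization probability ``p``.

    Combines the colonization hazard with the deterministic growth
    translation ``t_grow`` from :func:`~patchrecovery.growth_dynamics.
    time_to_fraction`; mean is ``t_grow + 1/lambda`` and quantiles
    ``t_grow - ln(1 - q)/lambda``.
    """
    rate = hazard_from_annual_probability(p)
    t_grow = time_to_fraction(growth, light, fraction)
    return RecoveryDistribution(rate=rate, translation=t_grow)


def distribution_quantile(dist: RecoveryDistribution, q: float) -> float:
    """Quantile of a recovery-time law (thin wrapper over the method)."""
    return dist.quantile(q)


def simulate_recovery_times(
    p: float,
    growth: GrowthParams,
    light: LightScenario,
    fraction: float = 0.5,
    config: SimConfig = SimConfig(),
) -> RecoverySample:
    """Monte Carlo sample of recovery times.

    Per replicate a colonization time is drawn — continuous mode: an
    exponential with hazard ``-ln(1-p)``; annual mode: the first
    successful year of annual Bernoulli(p) trials — and the
    deterministic growth time is added.  Identical seeds give identical
    samples.  Replicates exceeding ``config.max_years`` are censored at
    the horizon and flagged.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    t_grow = time_to_fraction(growth, light, fraction)
    rng = np.random.default_rng(config.seed)
    if p == 0.0:
        waits = np.full(config.n_reps, np.inf)
    elif config.time_mode == "continuous":
        if p == 1.0:
            waits = np.zeros(config.n_reps)
        else:
            rate = hazard_from_annual_probability(p)
            waits = rng.exponential(scale=1.0 / rate, size=config.n_reps)
    else:  # annual trials; colonization at the end of the first success year
        waits = rng.geometric(p, size=config.n_reps).astype(float)
    times = waits + t_grow
    censored = times > config.max_years
    times = np.where(censored, config.max_years, times)
    return RecoverySample(times=times, censored=censored, config=config)


def summarize_samples(sample: RecoverySample) -> dict:
    """Empirical summary: median, 75%/95% quantile pairs, mean, censoring.

    Quantiles use the linear-interpolation convention.  A quantile whose
    tail requirement overlaps the censored fraction is reported as NaN
    rather than a biased value; the censored fraction is always reported.
    """
    times = np.asarray(sample.times, dtype=float)
    if times.size == 0:
        raise ValueError("cannot summarize an empty sample")
    frac_cens = sample.fraction_censored
    out: dict = {}
    for q in SUMMARY_QUANTILES:
        if 1.0 - q <= frac_cens:
            out[f"q{100 * q:g}"] = math.nan
        else:
            out[f"q{100 * q:g}"] = float(np.quantile(times, q))
    out["median"] = out.pop("q50")
    out["mean"] = math.nan if frac_cens > 0 else float(times.mean())
    out["fraction_censored"] = frac_cens
    return out
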