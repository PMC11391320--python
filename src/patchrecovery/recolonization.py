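"""Annual recolonization-probability models over a patch network.

A disturbed patch (biomass 0, no seed bank) is connected to remnant
patches that supply propagules in proportion to their biomass.  Two
alternative sources of interannual stochasticity are modelled:

* **Uncertain dispersal** — whether propagules reach the disturbed patch
  each year is stochastic; arrivals recruit with certainty.  Each
  connected remnant patch contributes an independent per-patch dispersal
  probability (a logistic function of its biomass, capped at ``L_max``),
  and the annual recolonization probability is one minus the probability
  that every source fails.  It approaches 1 as connections accumulate.

* **Uncertain recruitment** — propagule arrival is deterministic but
  recruitment at the disturbed patch is stochastic.  The annual
  probability is a single logistic function of the *summed* biomass of
  all connected patches, saturating at ``R_max`` (which may be < 1).

Connectivity is a symmetric binary matrix Q; only patches with
``Q[i, j] = 1`` contribute (an unconnected patch contributes exactly
nothing, rather than the tiny nonzero term the raw formula would give
at zero biomass).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DispersalParams",
    "RecruitmentParams",
    "PatchNetwork",
    "logistic_probability",
    "annual_dispersal_probability",
    "annual_recruitment_probability",
    "calibrate_tau",
]


def _validate_curve(max_param: float, tau: float, nu: float, max_name: str) -> None:
    if not 0 < max_param <= 1:
        raise ValueError(f"{max_name} must lie in (0, 1], got {max_param}")
    if not tau > 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if not nu > 0:
        raise ValueError(f"nu must be positive, got {nu}")


@dataclass(frozen=True)
class DispersalParams:
    """Parameters of the per-patch biomass->dispersal-probability curve.

    ``L_max`` is the maximum annual probability of propagules dispersing
    from one source patch to the disturbed patch (the dispersal
    suitability parameter), ``tau`` the source biomass at which the
    probability is half of ``L_max`` (the productivity parameter: lower
    tau means more propagules per unit biomass), and ``nu`` the
    steepness of the curve (the threshold parameter).
    """

    L_max: float
    tau: float
    nu: float

    def __post_init__(self) -> None:
        _validate_curve(self.L_max, self.tau, self.nu, "L_max")


@dataclass(frozen=True)
class RecruitmentParams:
    """Parameters of the summed-biomass->recruitment-probability curve.

    ``R_max`` is the maximum annual recruitment probability when the
    propagule supply saturates (the recruitment suitability parameter);
    ``tau`` and ``nu`` are the half-saturation summed biomass and
    steepness, as in :class:`DispersalParams`.
    """

    R_max: float
    tau: float
    nu: float

    def __post_init__(self) -> None:
        _validate_curve(self.R_max, self.tau, self.nu, "R_max")


@dataclass(frozen=True)
class PatchNetwork:
    """A patch network: connectivity matrix, biomass vector, disturbed patch.

    ``Q`` is a symmetric 0/1 matrix with zero diagonal; ``biomass`` holds
    each patch's standing biomass (g dry weight m^-2); the disturbed
    patch starts at biomass 0 (no remnant habitat or seed bank).
    """

    Q: np.ndarray
    biomass: np.ndarray
    disturbed_index: int = 0

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        biomass = np.asarray(self.biomass, dtype=float)
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "biomass", biomass)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError(f"Q must be square, got shape {Q.shape}")
        if biomass.shape != (Q.shape[0],):
            raise ValueError(
                f"biomass length {biomass.shape} does not match Q {Q.shape}"
            )
        if not np.array_equal(Q, Q.T):
            raise ValueError("Q must be symmetric")
        if not np.isin(Q, (0.0, 1.0)).all():
            raise ValueError("Q entries must be 0 or 1")
        if np.diag(Q).any():
            raise ValueError("Q must have a zero diagonal")
        if (biomass < 0).any():
            raise ValueError("biomass must be non-negative")
        if not 0 <= self.disturbed_index < Q.shape[0]:
            raise IndexError(f"disturbed_index {self.disturbed_index} out of range")
        if biomass[self.disturbed_index] != 0:
            raise ValueError("the disturbed patch must start at biomass 0")

    @property
    def n_connected(self) -> int:
        """Number of remnant patches connected to the disturbed patch."""
        return int(self.Q[self.disturbed_index].sum())

    def connected_biomass(self) -> np.ndarray:
        """Biomass of each patch connected to the disturbed patch."""
        mask = self.Q[self.disturbed_index] == 1
        return self.biomass[mask]


def logistic_probability(
    biomass: float, max_param: float, tau: float, nu: float
) -> float:
    """Evaluate ``max_param / (1 + exp(-nu * (biomass - tau)))``."""
    return max_param / (1.0 + math.exp(-nu * (biomass - tau)))


def annual_dispersal_probability(
    network: PatchNetwork, params: DispersalParams
) -> float:
    """Annual probability of recolonization under uncertain dispersal.

    ``p_D = 1 - prod_j (1 - L_max / (1 + exp(-nu * (B_j - tau))))`` over
    connected remnant patches j.  Zero connections give the empty
    product, hence probability 0.
    """
    sources = network.connected_biomass()
    if sources.size == 0:
        return 0.0
    per_patch = params.L_max / (1.0 + np.exp(-params.nu * (sources - params.tau)))
    log_fail = np.log1p(-per_patch).sum()
    return float(-np.expm1(log_fail))


def annual_recruitment_probability(
    network: PatchNetwork, params: RecruitmentParams
) -> float:
    """Annual probability of recolonization under uncertain recruitment.

    ``p_R = R_max / (1 + exp(-nu * (summed connected biomass - tau)))``.
    Bounded by ``R_max`` no matter how many patches are connected.
    """
    summed = float(network.connected_biomass().sum())
    return logistic_probability(summed, params.R_max, params.tau, params.nu)


def calibrate_tau(
    target_probability: float,
    max_param: float,
    nu: float,
    reference_biomass: float,
) -> float:
    """Solve for tau so the logistic curve hits a target probability.

    Returns the tau for which
    ``max_param / (1 + exp(-nu * (reference_biomass - tau)))`` equals
    ``target_probability``; closed form
    ``tau = reference_biomass + ln(max_param / target - 1) / nu``.

    Raises if the target is not attainable (``target >= max_param``) or
    if the solution violates the ``tau > 0`` invariant (target too close
    to the maximum for the given reference biomass).
    """
    if not 0 < target_probability < max_param:
        raise ValueError(
            f"target probability {target_probability} must lie in "
            f"(0, max_param={max_param}) to be attainable"
        )
    tau = reference_biomass + math.log(max_param / target_probability - 1.0) / nu
    if not tau > 0:
        raise ValueError(
            f"calibration gives tau={tau} <= 0: the target {target_probability} "
            f"is too close to max_param={max_param} at reference biomass "
            f"{reference_biomass} and steepness nu={nu}"
        )
    return tau
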