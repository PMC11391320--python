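"""Deterministic logistic regrowth of habitat biomass under light limitation.

After a disturbed patch is successfully recolonized, its biomass grows
deterministically from a small founding biomass ``B0`` toward a
light-dependent equilibrium.  Growth is logistic: self-limitation (e.g.
self-shading in seagrass canopies) caps biomass at the carrying capacity,
and chronic low benthic light scales both the intrinsic growth rate and
the carrying capacity down.

The logistic ODE ``dB/dt = r(l) * B * (1 - B / B_eq(l))`` has the
closed-form solution used throughout this module, so time-to-threshold
questions ("how long until the patch exceeds 50% of its equilibrium
biomass?") are answered exactly rather than by numerical integration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict

import numpy as np

__all__ = [
    "GrowthParams",
    "LightScenario",
    "LIGHT_RESPONSES",
    "equilibrium_biomass",
    "growth_rate",
    "grow",
    "time_to_fraction",
]


# Registry of light-limitation functions g(l) mapping the fraction of
# normal benthic light to a multiplier on both r_max and B_max.  The
# default is the identity (proportional limitation); alternative forms
# can be registered without touching the rest of the model.
LIGHT_RESPONSES: Dict[str, Callable[[float], float]] = {
    "linear": lambda light: light,
}


@dataclass(frozen=True)
class GrowthParams:
    """Growth parameters for one habitat-forming species.

    Parameters
    ----------
    r_max : float
        Intrinsic per-year logistic growth rate at normal light (1/year).
    B_max : float
        Equilibrium (carrying-capacity) biomass at normal light
        (g dry weight m^-2).
    B0 : float
        Biomass assigned to the patch at the moment of successful
        colonization (g dry weight m^-2).  Must satisfy ``0 < B0 < B_max``.
    light_response : str
        Key into :data:`LIGHT_RESPONSES` selecting the light-limitation
        function applied to both the rate and the equilibrium.
    """

    r_max: float
    B_max: float
    B0: float
    light_response: str = "linear"

    def __post_init__(self) -> None:
        if not self.r_max > 0:
            raise ValueError(f"r_max must be positive, got {self.r_max}")
        if not self.B_max > 0:
            raise ValueError(f"B_max must be positive, got {self.B_max}")
        if not 0 < self.B0 < self.B_max:
            raise ValueError(
                f"B0 must lie in (0, B_max)={(0, self.B_max)}, got {self.B0}"
            )
        if self.light_response not in LIGHT_RESPONSES:
            raise ValueError(
                f"unknown light_response {self.light_response!r}; "
                f"registered: {sorted(LIGHT_RESPONSES)}"
            )


@dataclass(frozen=True)
class LightScenario:
    """Chronic light level as a fraction of normal benthic light.

    The factorial study design uses 1.0 (normal), 0.5 (stressed) and
    0.25 (severely stressed), but any value in (0, 1] is accepted.
    """

    light_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.light_fraction <= 1:
            raise ValueError(
                f"light_fraction must lie in (0, 1], got {self.light_fraction}"
            )


NORMAL_LIGHT = LightScenario(1.0)


def _g(params: GrowthParams, light: LightScenario) -> float:
    return LIGHT_RESPONSES[params.light_response](light.light_fraction)


def equilibrium_biomass(params: GrowthParams, light: LightScenario) -> float:
    """Light-specific equilibrium biomass ``B_eq(l) = B_max * g(l)``."""
    return params.B_max * _g(params, light)


def growth_rate(params: GrowthParams, light: LightScenario) -> float:
    """Light-specific intrinsic growth rate ``r(l) = r_max * g(l)`` (1/year)."""
    return params.r_max * _g(params, light)


def grow(
    B: float, params: GrowthParams, light: LightScenario, duration: float
) -> float:
    """Biomass after ``duration`` years of logistic growth from ``B``.

    Uses the closed-form logistic solution

    ``B(t) = B_eq / (1 + ((B_eq - B) / B) * exp(-r t))``

    with light-specific rate and capacity.  ``B = 0`` is an absorbing
    state (extinct stays extinct) and ``B = B_eq`` is the fixed point.
    Decline from above capacity is out of scope and rejected.
    """
    if duration < 0:
        raise ValueError(f"duration must be non-negative, got {duration}")
    B_eq = equilibrium_biomass(params, light)
    if B < 0 or B > B_eq * (1 + 1e-12):
        raise ValueError(f"biomass {B} outside [0, B_eq={B_eq}]")
    if B == 0.0:
        return 0.0
    r = growth_rate(params, light)
    # log-space form avoids overflow for large r*t
    ratio = (B_eq - B) / B
    return B_eq / (1.0 + ratio * math.exp(-r * duration))


def time_to_fraction(
    params: GrowthParams, light: LightScenario, fraction: float = 0.5
) -> float:
    """Years of deterministic growth from ``B0`` to ``fraction * B_eq(l)``.

    Inverting the logistic solution gives

    ``t_grow = (1/r(l)) * ln( fraction * (B_eq - B0) / (B0 * (1 - fraction)) )``

    which for the 50% recovery threshold reduces to
    ``(1/r(l)) * ln((B_eq - B0) / B0)``.  If ``B0`` already meets the
    threshold the growth time is 0 (with a warning, since it usually
    signals a mis-specified founding biomass).
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    B_eq = equilibrium_biomass(params, light)
    target = fraction * B_eq
    if params.B0 >= target:
        if params.B0 > target:
            warnings.warn(
                f"founding biomass B0={params.B0} already exceeds the "
                f"recovery threshold {target}; growth time is 0",
                stacklevel=2,
            )
        return 0.0
    r = growth_rate(params, light)
    return math.log(fraction * (B_eq - params.B0) / (params.B0 * (1 - fraction))) / r
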