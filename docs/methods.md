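# Methods

## Model structure and assumptions

The model tracks a single disturbed habitat patch embedded in a network of
remnant patches. Three assumptions shape everything downstream:

1. **Recolonization is an annual Bernoulli event.** Interannual variability in
   either propagule dispersal (uncertain-dispersal model) or propagule
   recruitment (uncertain-recruitment model) gives one colonization
   probability *p* per year. Propagule supply from a remnant patch is
   proportional to its biomass; the disturbed patch has no remnant habitat or
   seed bank, so *p* = 0 when no patch is connected.
2. **Growth after colonization is deterministic.** Biomass follows the
   logistic ODE with light-scaled rate and capacity; there is no environmental
   noise on growth and no re-disturbance during recovery.
3. **Patches are exchangeable.** In scenario grids all remnant patches share
   one equilibrium biomass and one light level (a star network). Arbitrary
   symmetric 0/1 connectivity matrices and heterogeneous biomass vectors are
   supported through the `recolonization` module and the CSV readers.

Under these assumptions the recovery time is exactly a translated
exponential: hazard λ = −ln(1 − p) plus the deterministic growth time
t_grow to the recovery threshold (default 50% of the light-specific
equilibrium). The package evaluates this law in closed form and keeps a
Monte Carlo simulator for validation and for the discrete-annual variant.

## Parameters

| Parameter | Meaning | Units | Placeholder default |
|---|---|---|---|
| r_max | intrinsic logistic growth rate at normal light | 1/year | 2.0 (zostera-like), 1.6 (halodule-like) |
| B_max | equilibrium biomass at normal light | g dry wt m⁻² | 600 (zostera-like), ≈718.6 (halodule-like, derived — see below) |
| B0 | biomass at the moment of colonization | g dry wt m⁻² | 1% of B_max |
| light_fraction ℓ | fraction of normal benthic light | — | 1.0 / 0.5 / 0.25 in the factorial design |
| L_max, R_max | maximum annual dispersal / recruitment probability | — | 0.375 (shared) |
| τ | biomass at half the curve maximum (productivity) | g dry wt m⁻² | ≈542.46 (calibrated) |
| ν | curve steepness (threshold) | per g dry wt m⁻² | 0.01 |
| fraction | recovery threshold as a fraction of B_eq(ℓ) | — | 0.5 |
| max_years | Monte Carlo censoring horizon | years | 200 |

Steepness ν = 0.01 sits between the extremes that make the curve an
implausible step (ν > 0.1) or implausibly flat (ν < 0.001) on a biomass scale
of hundreds of g dry wt m⁻². The 0.375 shared maximum follows from requiring
the single-meadow probability 0.24 to be 64% of the curve maximum.

## The placeholder registry: what it emulates and what it does not

Species-specific growth and colonization parameters belong in a user-supplied
registry; the bundled `generate_fixture_registry` is a clearly tagged
placeholder so the package runs self-contained. It encodes the structural
facts the analyses rely on:

- both species share one pair of colonization curves; they differ only through
  their growth parameters, i.e. through the biomass at which the shared curves
  are evaluated;
- calibration: one remnant meadow at equilibrium biomass recolonizes with
  annual probability 0.24 (zostera-like) and 0.32 (halodule-like). τ is solved
  in closed form from the zostera-like point; the halodule-like B_max is then
  *forced* to be the biomass where the shared curve reaches 0.32 — with one
  monotone curve, the species with the higher probability must sit at higher
  biomass. This makes the halodule-like placeholder a higher-biomass,
  slower-growing species, which real *Halodule uninervis* meadows are not;
  the placeholder preserves the calibration targets, not species realism;
- growth rates are set so the faster-growing zostera-like species overtakes
  once connectivity is high, while the halodule-like species (higher annual
  colonization probability) recovers faster from a single connected meadow,
  and so that a one-meadow median recovery lands in the empirically plausible
  few-year range (ln(99)/2.0 ≈ 2.3 years of regrowth plus a ~2.5-year median
  wait).

What passing tests on this registry show: the model's orderings
(connectivity, light stress, management, sensitivity) and its exact laws.
What they do not show: recovery-time magnitudes for any real meadow — those
require field-estimated r_max, B_max, and colonization-curve parameters. In
particular, the severe-light (ℓ = 0.25) scenarios push remnant biomass far
down the placeholder curves, so stress penalties and management savings are
much larger than any field-calibrated expectation; treat them as qualitative.

## Numerical choices

- **Hazard mapping.** λ = −ln(1 − p) makes the continuous exponential's
  one-year survival equal the annual Bernoulli failure probability exactly,
  while permitting sub-annual recovery times. A discrete `time_mode="annual"`
  (geometric trials, colonization at the end of the first successful year) is
  kept for cross-checking. p = 1 maps to an immediate-colonization sentinel
  (rate ∞, recovery exactly at t_grow); p = 0 to a no-recovery sentinel
  (rate 0, infinite quantiles).
- **Unconnected patches contribute exactly nothing.** The dispersal product
  runs only over patches with Q_ij = 1; including zero-biomass terms would
  give a spurious small probability from the logistic's nonzero intercept.
- **Closed-form logistic evaluation** uses the ratio form
  B_eq / (1 + ((B_eq − B)/B) e^(−rt)); B = 0 short-circuits. Growth above
  capacity is rejected (decline is out of scope). If B0 already exceeds the
  recovery threshold, t_grow = 0 with a warning.
- **Quantile conventions.** "95%" and "75%" intervals mean the (0.025, 0.975)
  and (0.125, 0.875) quantile pairs. Empirical quantiles use linear
  interpolation. A quantile whose tail overlaps the censored fraction of a
  Monte Carlo sample is reported as NaN, never as a biased number; the
  censored fraction is always reported.
- **Randomness.** One `numpy.random.Generator` per simulation run, seeded from
  `SimConfig.seed`; the seed is recorded in results and metadata. Identical
  seeds give bitwise-identical samples.
- **Ties in action rankings** (e.g. "stabilize" vs "none" under uncertain
  dispersal, which are identical by construction) are reported as a winner
  set at relative tolerance 1e-9, never broken arbitrarily.

## Design choices

- **Light-limitation function.** The default g(ℓ) = ℓ scales both the growth
  rate and the equilibrium, preserving the qualitative requirement that lower
  light means slower growth *and* a lower recovery target. `LIGHT_RESPONSES`
  is a registry, so alternative published light-response forms can be plugged
  in without touching the model.
- **Seeding under uncertain dispersal** is modelled as immediate colonization
  (supply saturation removes the only stochastic step); an alternative policy
  capping the probability at L_max is selectable
  (`seed_dispersal_policy="lmax"`) for robustness checks.
- **Sensitivity sweeps** use 9 log-spaced multipliers from 0.25× to 4×.
  Multipliers that violate a parameter invariant (e.g. L_max·m > 1) are
  flagged infeasible in the output table rather than dropped. τ and ν are
  shared by the two colonization curves and are scaled in both.
- **Temperature** is held at its reference level; no scenario varies it.
- A mixed dispersal+recruitment colonization model (summing the two hazards)
  would be a straightforward extension hook but is deliberately not
  implemented or tested here.

## Problem sizes

Analytic results are exact and instantaneous. Validation uses 10⁵ Monte Carlo
replicates per cell (quantile agreement within 2% relative or 0.05 years),
40 randomized parameter draws for the growth-vs-ODE check (relative error
below 1e−6 against RK45 at rtol 1e−10), and the full 1–10-connectivity,
three-light factorial grids. The whole suite runs in a few seconds on one
core.

## Known limitations

- No biomass feedback from the recovering patch to its own colonization
  probability, no time-varying hazards, no re-disturbance, no seasonal
  forcing, no within-patch spatial structure.
- Binary connectivity only; distance- or current-weighted dispersal is out of
  scope.
- Stressors act only on growth (rate and equilibrium), not on propagule
  survival or dispersal, and propagule production is assumed proportional to
  standing biomass.
- Placeholder parameter values are calibration-consistent, not
  species-accurate; all outputs carry provenance tags so placeholder runs are
  identifiable.
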