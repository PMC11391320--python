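# patchrecovery

How long does a disturbed coastal habitat patch — a seagrass meadow lost to a
flood, disease or heatwave — take to recover when recolonization depends on
propagules arriving from connected remnant patches? `patchrecovery` answers
this with a small metapopulation model aimed at restoration planners and
ecological modellers: it predicts recovery-time *distributions* (not just
means) under connectivity, dispersal, recruitment and chronic light-stress
constraints, compares management interventions, and sweeps parameter
sensitivities.

## The model

A disturbed patch (biomass 0, no seed bank) is connected to *n* remnant
patches via a symmetric binary matrix **Q**. Each year colonization succeeds
with probability *p*, given by one of two alternative stochastic models:

- **Uncertain dispersal** — arrival is stochastic, recruitment certain. Each
  connected patch *j* contributes independently:

  p_D = 1 − ∏_j [ 1 − L_max / (1 + e^(−ν(B_j − τ)) ) ]

- **Uncertain recruitment** — arrival is deterministic, recruitment
  stochastic, driven by the summed biomass of connected patches:

  p_R = R_max / (1 + e^(−ν(Σ_j B_j − τ)) )

Here L_max/R_max are the maximum annual probabilities (suitability), τ the
biomass at half-maximum (productivity: lower τ = more propagules per unit
biomass) and ν the steepness (threshold) of the curve. p_D → 1 with many
connections; p_R saturates at R_max.

Once colonized at founding biomass B₀, the patch regrows logistically,
dB/dt = r(ℓ) B (1 − B/B_eq(ℓ)), where the light fraction ℓ ∈ (0, 1] scales
both the intrinsic rate, r(ℓ) = r_max·ℓ, and the equilibrium,
B_eq(ℓ) = B_max·ℓ. The patch counts as recovered when it crosses a fraction
(default 50%) of its light-specific equilibrium, after a deterministic growth
time t_grow obtained in closed form.

The recovery time is therefore a **translated exponential**: waiting time with
hazard λ = −ln(1 − p), shifted by t_grow. Medians, means and quantiles are
exact; a seeded Monte Carlo simulator (continuous or discrete-annual trials)
cross-checks them. Management actions map onto the model: seeding/planting
saturates propagule supply, sediment stabilization makes recruitment certain,
and catchment action restores full light.

## Worked example

The bundled placeholder registry has two seagrass-like species sharing one
colonization curve, calibrated so a single remnant meadow at equilibrium
biomass recolonizes with annual probability 0.24 (zostera-like) or 0.32
(halodule-like):

```python
from patchrecovery import generate_fixture_registry, Scenario, run_scenario

reg = generate_fixture_registry(seed=0)
for n in (1, 10):
    r = run_scenario(Scenario(species="zostera-like", model="dispersal",
                              n_connected=n), reg)
    print(n, round(r.annual_probability, 3), round(r.median, 2),
          round(r.summary["q2.5"], 2), round(r.summary["q97.5"], 2))
```

prints

```
1 0.24 4.82 2.39 15.74
10 0.936 2.55 2.31 3.64
```

With one connected meadow the disturbed patch recovers in a median 4.8 years,
but the 95% interval (2.4–15.7 years) shows how uncertain a single propagule
source makes recovery; with ten connected meadows colonization is nearly
certain each year (p = 0.936) and recovery concentrates just above the 2.3-year
deterministic regrowth time. The CLI exposes the same machinery
(`patchrecovery analytic | simulate | manage-compare | sweep | fixtures`);
every run writes a results CSV, JSON metadata with provenance and seed, and a
log.

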