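# nitrodust

Heterogeneous kinetics of polycyclic aromatic hydrocarbon (PAH) nitration by
NO₂ on mineral dust, and the field signature it leaves in airborne
particulates.

Mineral dust aerosols — desert dusts and their clay-mineral components —
catalyse the conversion of surface-adsorbed pyrene (Py) into 1-nitropyrene
(1-NP), a probable carcinogen, far faster than the simple oxides usually
used as dust surrogates. `nitrodust` implements the full analysis chain
needed to quantify that chemistry from flow-reactor decay measurements and
to detect it in cascade-impactor field data:

* **Decay kinetics** — nonlinear least-squares fits of the Py fraction
  remaining, `[Py]_t/[Py]_0`, to a pseudo-first-order exponential
  `exp(−k_obs t)` or its plateau-shifted form
  `p + (1−p)·exp(−k_obs t)` (0 ≤ p < 1, the unreactive residual fraction),
  with nested-model selection by an extra-sum-of-squares F-test, plus
  benchmark summaries: percent Py degraded (D_Py) and 1-NP yield (Y_1-NP)
  at 2 h, dinitropyrene (DNP) presence at 12 h.
* **Collision theory** — the apparent reaction probability (uptake
  coefficient) γ = 4 k_obs / (σ ω [NO₂(g)]), with σ the effective Py
  cross-section (0.8 nm²) and ω the NO₂ thermal speed (mean-speed
  convention √(8RT/πM) by default, rms √(3RT/M) available); monolayer
  surface coverage θ = loading·N_A·σ / A_BET; e-folding lifetime τ = 1/k_obs.
* **Mechanism discrimination** — fits of k_obs vs gas-phase NO₂ to the
  Langmuir–Hinshelwood adsorbed-NO₂ model
  `k_obs = k_max·K·[NO₂] / (1 + K·[NO₂])` and the N₂O₄-route model
  `k_obs = k_max·K′·[NO₂]² / (1 + K′·[NO₂]²)`, compared by AICc and by
  their predictions at ambient concentrations (the quadratic route
  collapses below the hyperbolic one at ~100 ppbv), with delta-method
  uncertainty on extrapolated rates.
* **Field ratios** — size-fractionated 1-NP/BkF ratios
  (benzo[k]fluoranthene as an unreactive, non-volatile reference PAH),
  dust-period classification, and a Mann–Whitney U test that is exact by
  full enumeration for small untied samples.
* **Synthetic data** — seeded generators for all three input kinds with
  known ground truth, so every stage is testable end to end.

## Worked example

```python
import nitrodust as nd

# fit a desert-dust-like decay experiment (3 ppmv NO2, triplicates, 5% noise)
series = nd.generate_decay_series(nd.DecayScenario(k_true=8.6e-4, seed=1))
fit = nd.select_decay_model(series)
print(f"k_obs = {fit.k_obs:.3g} +/- {fit.k_obs_se:.2g} s^-1 ({fit.model} model)")

# collision-theory uptake coefficient at the lab concentration
gamma = nd.reaction_probability(fit.k_obs, nd.PY_NO2, series.conditions)
print(f"gamma = {gamma:.3g}")

# ambient extrapolation at 50 ppbv NO2
k_ambient = 6.7e-5  # s^-1, Langmuir-Hinshelwood prediction for desert dust
gas = nd.GasConditions.from_ppbv(50.0)
print(f"ambient gamma = {nd.reaction_probability(k_ambient, nd.PY_NO2, gas):.2g}")
print(f"lifetime = {nd.lifetime_hours(k_ambient):.1f} h")
```

prints

```
k_obs = 0.000837 +/- 2e-05 s^-1 (simple model)
gamma = 1.53e-07
ambient gamma = 7.3e-07
lifetime = 4.1 h
```

The fitted `k_obs` recovers the generating rate within one standard error;
`gamma` says roughly one in six million NO₂–surface collisions removes a
pyrene molecule at 3 ppmv; and at urban NO₂ levels (50 ppbv) the dust-bound
pyrene e-folding lifetime of ~4 h is competitive with its gas-phase loss to
OH radicals — which is why dust-surface nitration matters for ambient 1-NP.

A command-line pipeline wraps the same functions:

```sh
nitrodust synthesize --scenario scenario.yaml --outdir out/
nitrodust summarize --decay-csv out/decay.csv --outdir out/
nitrodust field --field-csv out/field.csv --outdir out/
```

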