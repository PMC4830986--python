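# Methods

## The system

Pyrene (Py) adsorbed at submonolayer coverage on a mineral substrate is
exposed to gaseous NO₂ in a flow reactor at constant temperature and low
relative humidity. The Py remaining, expressed as the fraction
`[Py]_t/[Py]_0`, decays pseudo-first-order because NO₂ is in vast excess and
its surface coverage is held constant by gas–surface equilibrium. The
products of interest are 1-nitropyrene (1-NP) and, on the most active
substrates, dinitropyrenes (DNPs). The field-side counterpart is a
cascade-impactor record of 1-NP and benzo[k]fluoranthene (BkF)
concentrations per aerodynamic size fraction and sampling period; since BkF
is unreactive and non-volatile, a rise of the 1-NP/BkF ratio above its
combustion-source baseline flags secondary, on-particle 1-NP formation.

## Decay models and fitting

Two nested models describe the decay:

* simple first order: `f(t) = exp(−k_obs·t)`
* plateau-shifted: `f(t) = p + (1−p)·exp(−k_obs·t)`, `p ∈ [0, 1)`

`[Py]_0` is fixed at 1 after normalization rather than floated; only `k_obs`
and the plateau are free parameters. The plateau captures the unreactive
residual seen on some substrates (site heterogeneity, inaccessible pores).
All replicate points enter an unweighted least-squares objective — replicate
means are not pre-averaged, and no weighting scheme is imposed because the
replicate noise is homogeneous by construction in the synthetic data and
unknown for bench data.

The simple model is fitted by Levenberg–Marquardt. The plateau model needs
`p` constrained to `[0, 1)`, which plain LM cannot do, so it uses bounded
trust-region least squares; an estimate within 1e−7 of a bound is flagged
as pinned. Starting values: `k₀ = ln(f_first/f_last)/t_span` floored at
1e−8 s⁻¹, `p₀ = min` observed fraction. Standard errors are the usual
asymptotic ones (Jacobian covariance scaled by residual variance).

Model choice uses the extra-sum-of-squares F-test at α = 0.05: the plateau
model is kept only when its RSS improvement is significant. With fewer than
four distinct times the simple model is forced (no residual degrees of
freedom for the extra parameter). When both fits are essentially exact
(noiseless data, RSS below 1e−30), parsimony wins unless the simple model's
RSS is materially larger. The α and the test itself are this package's
choice; bench practice typically decides by eye.

Benchmark summaries require an exact time match (default 7200 s for D_Py
and Y_1-NP, 43200 s for the DNP flag, detection threshold 0.5% of initial
Py); interpolation is refused because the decay is steep early on and a
silently interpolated benchmark would not be comparable across substrates.

## Collision theory

The apparent reaction probability converts `k_obs` to the fraction of
NO₂–surface collisions that remove a Py molecule:

    γ = 4·k_obs / (σ · ω · [NO₂(g)])

with σ = 0.8 nm² (effective Py cross-section), [NO₂(g)] the number density
(molecules m⁻³, from the ideal-gas law at the stated T, P) and ω the NO₂
thermal speed. Two speed conventions are supported because published uptake
tables are not always explicit about which constant entered the collision
frequency: the Maxwell–Boltzmann mean speed √(8RT/πM) (default, ~370 m s⁻¹
at 298 K) and the rms speed √(3RT/M) (~402 m s⁻¹). Recomputing the bundled
substrate survey from its printed `k_obs` values reproduces the printed γ
within ~5% on every row under the rms convention but runs ~2–12% high under
the mean convention, while the ambient-extrapolation benchmark
(γ = 7.3×10⁻⁷ at 50 ppbv) is matched within 1% by the mean convention.
Both are therefore kept, the default follows the standard kinetic-theory
definition, and the acceptance checks record which convention wins where.
γ > 1 warns rather than errors: as an *apparent* probability it may exceed
unity in stress tests without invalidating the arithmetic.

Initial fractional coverage is the monolayer-packing estimate
θ = loading·N_A·σ / A_BET with no surface-roughness or pore-accessibility
correction; analyses warn when θ ≥ 1 because the
coverage-independence of `k_obs` holds only in the submonolayer regime.
Lifetime is the e-folding time τ = 1/k_obs.

Physical constants are CODATA/exact-SI values, collected in
`nitrodust/constants.py`.

## Mechanism models

`k_obs` versus gas-phase NO₂ concentration c (number density) distinguishes
two surface mechanisms:

* **Adsorbed NO₂ (Langmuir–Hinshelwood)**: `k_obs = k_max·K·c/(1 + K·c)` —
  first order in NO₂ when K·c ≪ 1, zeroth order at saturation. K (m³) is
  the NO₂ gas-to-surface equilibrium constant, k_max the saturated rate.
* **N₂O₄ route**: NO₂ dimerizes in the gas phase ([N₂O₄] = K_dim·[NO₂]²)
  and the adsorbed dimer nitrates; in terms of NO₂ this gives
  `k_obs = k_max·K′·c²/(1 + K′·c²)` with the lumped K′ = K_dim·K_ads (m⁶) —
  second order at low concentration.

Fits run in number-density units so K keeps its physical meaning. Because
k_max (~10⁻³ s⁻¹) and K (~10⁻²⁰ m³, or ~10⁻⁴⁰ m⁶ for K′) are separated by
17–37 orders of magnitude, the solver works in log-parameters: this
conditions the Jacobian, enforces positivity without bounds, and lets
Levenberg–Marquardt converge from a half-saturation starting guess
(k_max₀ = 1.2×max k_obs; K₀ from the interpolated half-saturation
concentration). The covariance is computed in log space and mapped back by
the delta method. Inverse-variance weights are applied when a standard-error
column is present, otherwise the fit is unweighted.

Predictions at a new concentration carry a delta-method standard error
propagated through the full 2×2 covariance (validated against a parametric
bootstrap to within 10%). The apparent reaction order is analytic:
`1/(1+Kc)` and `2/(1+K′c²)`.

Discrimination combines the small-sample-corrected Akaike criterion (AICc,
Gaussian likelihood, 2 parameters) with the ratio of the two models'
predictions at a low reference concentration (default 100 ppbv): fitted to
data generated by adsorbed-NO₂ chemistry at ppmv levels, the quadratic model
necessarily underpredicts at ambient levels, which is the scientifically
decisive signature. Mechanism fits are validated by parameter recovery on
synthetic curves, not against any published fitted constants.

## Mann–Whitney U test

The dust-effect test compares 1-NP/BkF ratios between heavy-dust and
non-/low-dust periods. U is the rank-sum statistic of the first sample with
midranks for ties. For pooled samples of at most 12 untied values the p-value
is exact: all C(n_a+n_b, n_a) assignments of ranks are enumerated (924
labelings at worst). Larger or tied samples use the normal approximation
with the standard tie correction and a 0.5 continuity correction. The
two-sided p is twice the smaller one-sided p, capped at 1 — the sidedness of
the field hypothesis is not prescribed, so two-sided is the default.
Degenerate input (all pooled values identical) returns p = 1. Ratios with
zero or missing BkF become missing values, never infinities, and are
excluded with a reported count.

Period classification is a plain two-threshold rule on mean dust
concentration (heavy / low / none); real campaigns label storms from
LIDAR/PM₁₀ records, which is external information this package does not
reproduce.

## Synthetic data

The generators define the study conditions for every stochastic test:

* **Decay**: `f = [p + (1−p)e^(−kt)]·(1+ε)`, ε ~ N(0, CV), clipped at 0;
  defaults k = 8.6×10⁻⁴ s⁻¹ (desert-dust-like at 3 ppmv), triplicates,
  CV = 5%, time grid 0–4 h always including the 2 h benchmark. Noise is
  multiplicative because chromatographic quantification error scales with
  signal. Optional product tracks follow a consecutive first-order scheme
  Py → 1-NP → DNP with a branching fraction (default 0.6) of the reactive
  pool entering the nitro channel and a secondary rate k/5; these exercise
  the yield summaries and are generator-only, not a fitted model.
* **Rate curves**: either mechanism evaluated on a concentration grid
  (bench range 0.1–24 ppmv) with multiplicative noise; the SE column is set
  to k_obs×CV.
* **Field campaign**: five-stage impactor fractions (>7.0, 3.3–7.0,
  2.0–3.3, 1.1–2.0, ≤1.1 μm; coarse cutoff 2.0 μm), BkF lognormal about a
  30 pg m⁻³ baseline, 1-NP = BkF × baseline ratio (0.2) × independent
  lognormal noise (σ = 0.3), with the ratio multiplied by the dust
  enhancement (default 5) only in coarse fractions of heavy-dust periods —
  the fingerprint of mineral-dust nitration. Twelve 2-day periods, three of
  them heavy, mirror a month-long spring campaign.

All generators are pure functions of their scenario; one top-level seed
spawns per-stream children through `numpy.random.SeedSequence`, so output is
byte-identical across runs.

What passing these tests shows — and does not show. The generators emulate
the noise magnitude and design of the bench and field measurements, not
their systematic structure: no drift, no detection limits or censoring, no
correlated replicate error, no N₂O₅/HNO₃ or photochemical side-channels, no
atmospheric transport or deposition–resuspension of dust. Recovery and power
results therefore characterize the estimators under the stated idealized
conditions, not measurement campaigns at large.

## Numerical choices and degenerate inputs

* All-constant decay data return k_obs = 0 with a warning; rising "decay"
  pins the plateau and is flagged.
* Missing benchmark times, unknown product species, zero BET areas, empty
  Mann–Whitney groups, and concentrations outside their domains raise
  errors with unit-explaining messages; fractions slightly above 1 warn
  (measurement noise) rather than reject.
* CSV writers use `%.17g` and readers round-trip float parsing, so every
  write–read cycle is value-identical at double precision.
* AICc is +∞ when n ≤ 3 points (correction undefined), which simply
  removes the criterion, never crashes the comparison.

## Problem sizes

The Monte-Carlo studies use 500 replicates for simple-decay recovery, 200
for plateau recovery, 100 per arm for model selection, 50 for mechanism
discrimination, and 2000 for the null calibration of the exact Mann–Whitney
test (groups of six-and-six or smaller, where the enumeration path is
exercised). These sizes give Monte-Carlo standard errors comfortably below
the bands being checked while keeping the whole suite fast.

## Known limitations

* The speed-convention ambiguity above is documented, not resolved; both γ
  conventions are first-class.
* The F-test model-selection rule and the two-threshold dust classifier are
  this package's explicit choices where bench and field practice are
  informal.
* No mechanistic fitting of the 1-NP → DNP consecutive kinetics, of the
  directly formed asymmetric dimer (ONONO₂) route, or of HNO₃ nitration;
  DNP chemistry is reduced to a presence/absence flag.
* γ carries no surface-diffusion or pore-accessibility correction, and θ
  assumes ideal monolayer packing on the BET area.
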