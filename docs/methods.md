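# Methods

## Scope and conventions

`oxyresp` analyses chamber respirometry of small freshwater fishes. All
temperatures are °C, pressures kPa, concentrations mg O₂ L⁻¹, volumes L,
masses kg (body mass) or g (condition factor), and metabolic rates
mass-specific mg O₂ kg⁻¹ h⁻¹. Time inside a trace is seconds from trace
start; all windows are half-open `[start, end)`.

## Oxygen solubility and unit conversion

Equilibrium dissolved-oxygen concentration uses the Benson–Krause (1984)
freshwater equations in the USGS form: the 1-atm baseline
`ln C* = −139.34411 + 1.575701e5/T − 6.642308e7/T² + 1.2438e10/T³ −
8.621949e11/T⁴` (T in kelvin), an optional linear salinity factor, and the
barometric/vapour-pressure correction with `θ = 0.000975 − 1.426e−5 t +
6.436e−8 t²`. Partial pressure is proportional to concentration at fixed
conditions: `PO₂ = C / C_sat · 0.20946 (P_b − P_wv)`. The mole fraction of
O₂ in dry air is fixed at 0.20946. Valid ranges are enforced (0–40 °C,
80–110 kPa) because the solubility polynomial is only calibrated there.
Published table checkpoints (e.g. 9.09 mg/L at 20 °C and 1 atm) are
asserted in the test suite to 0.1%.

Note that the conventional field shorthand "6–8 mg/L ≈ 12–14 kPa, 3–4 mg/L
≈ 7–9 kPa" is only loosely consistent with the solubility model across
20–28 °C; the conversions here follow the physics and treat those pairings
as cross-checks with ±1.5 kPa slack, not as calibration targets.

## The simulator

The simulator encodes each fish as a `FishTruth`: body mass and length,
true SMR and MMR, critical tension, loss-of-equilibrium tension, and a
post-chase recovery half-life. Cohort draws centre on a 1.5 g, ~5.5 cm
juvenile (condition factor ≈ 0.9), SMR ≈ 250 mg kg⁻¹ h⁻¹, MMR/SMR ≈ 2.8,
*P*crit ≈ 6 kPa and LOE at 35–55% of *P*crit. The protocol defaults encode
the study design: 300 mL chambers, 20 min determinations, 2 min flushes,
~24 h runs, a 2 min chase + 40 s air exposure before the first
determination, and factorial treatments (20/24/28 °C × normoxia 7 mg/L vs
low oxygen 3.5 mg/L × 7/14/30 days acclimation). Sampling interval (1 s)
and Gaussian sensor noise (sd 0.02 mg/L) are declared defaults — loggers
vary and no canonical value exists.

Mechanics, chosen for exact recoverability:

* Oxygen uptake decays exponentially from MMR to SMR with the stated
  half-life, **held constant within each determination at its cycle-start
  value**. A 20-min cycle integrates the signal anyway, and this choice
  makes noiseless runs satisfy exact identities (first cycle ⇒ MMR, late
  cycles ⇒ SMR, mass balance to 1e−9) that the tests assert.
* Effective volume is chamber volume minus body mass at 1 g/mL (neutral
  buoyancy). Chamber O₂ falls linearly at
  `(uptake·BW + background·V_chamber)/V_eff`; flushes ramp linearly back to
  the bath concentration; determinations are clamped at the 1 mg/L protocol
  floor and flagged.
* The closed phase is piecewise in closed form: linear decline while
  PO₂ ≥ *P*crit (oxy-regulation at SMR), exponential below it (uptake
  proportional to PO₂ — conformity through the origin, the simplest model
  that makes the breakpoint well defined). The trace ends at the first
  sample at or below the LOE tension.
* All randomness flows from the scenario seed; per-fish substreams are
  spawned with `SeedSequence`, so cohorts are byte-reproducible.

What the simulator does **not** emulate: temperature scaling of metabolic
rate (temperature enters only through solubility and treatment labels),
drifting or autocorrelated sensor noise, incomplete flushing, activity
bursts, tank-level random effects, gill remodelling or any blood-oxygen
physiology. Passing recovery tests therefore demonstrates estimator
correctness under the stated noise model, not robustness to every field
artefact.

## Trace handling and cycle segmentation

Traces are CSV with a `# key=value` metadata header. Validation rejects
empty files, non-monotone time and negative O₂ with line numbers. With
phase labels present, contiguous `determination` runs become cycles;
without labels, flush onsets are detected as a rise over a 60 s window
exceeding 3× the sample noise sd (robustly estimated from first
differences via the MAD). Cycles deviating more than 25% from the nominal
determination length are dropped — this removes the truncated tail cycle,
so a 24 h run at 20+2 min yields ⌊1440/22⌋ = 65 cycles. The first
determination of an animal trace is the post-chase (MMR) cycle.

## Ṁo₂ extraction

The first 60 s of each determination are trimmed (mixing transient;
configurable) before the OLS fit. Endpoint concentrations are evaluated
from the fitted line at the window bounds — identical to the raw-endpoint
formulation in the noiseless limit and less noise-sensitive otherwise. A
constant-O₂ window is reported with slope 0 and r² defined as 0.
Background slopes are linearly interpolated between daily blanks, scaled
through the same V/t/BW factor (using the full chamber volume, since a
blank chamber holds no fish) and subtracted. Records whose background
exceeds 15% of the provisional resting rate (the lowest-10% mean of
corrected non-chase cycles) are flagged — strictly above, so exactly 15%
passes. QC flags (O₂ below 1 mg/L, r² < 0.90 by default, oxygen gain,
negative corrected uptake) never drop rows; they exclude cycles from
SMR/MMR estimation only.

## SMR, MMR, scope, condition

SMR averages exactly `k = ceil(0.10 n)` order statistics (minimum 1) of
the eligible corrected uptakes, ties resolved by stable cycle order; the
rounding rule is a declared choice since "lowest 10%" alone does not define
one. Eligible means QC-passing, non-chase cycles; an optional settling
window exclusion exists but defaults to off. MMR is the post-chase cycle's
corrected uptake, reported with an `mmr_qc` warning rather than suppressed
if that cycle failed QC. AAS = MMR − SMR (negative values flagged).
Fulton's K = 100 W/L³ with L in cm so typical juveniles sit near 1.

## Critical oxygen tension

Closed-phase traces are reduced to (PO₂, Ṁo₂) points by OLS slopes in
consecutive 2-min bins (binning mirrors determination-style slope fitting
and controls noise; instantaneous derivatives would be far noisier). A
bin's PO₂ is the fitted line's midpoint concentration converted to kPa;
bins with fewer than half a bin's samples — the truncated tail at LOE —
are dropped because their slope variance is orders of magnitude larger and
a single such point can dominate the fit. The fit is done in kPa.

The two-segment model `y = b0 + b1·x + b2·(x − ψ)₊` is linear given the
breakpoint ψ, so for each candidate ψ the 3×3 normal equations are solved
in closed form (vectorised over candidates; the response is mean-centred
for conditioning). Candidates are the observed PO₂ values inside the
5th–95th percentile window (edge guard against degenerate one-sided fits)
plus a uniform 101-point grid; the best brackets are then refined by
bounded scalar minimisation (the SSE profile is smooth between data points
but kinked at them, hence per-bracket refinement). Ties go to the smallest
breakpoint. Collinear data (single-line R² = 1 within 1e−10) return a
degenerate single-line fit with no breakpoint. The segmented SSE can never
exceed the single-line SSE because the single line lies inside the model
space (b2 = 0).

*P*crit is reported as the breakpoint (intersection of the two lines); the
SMR-crossing of the conforming segment is computed as a secondary
estimator, undefined when the conforming slope is non-positive and flagged
when SMR exceeds the regulating plateau (with a 0.1% margin so exact
equality is not flagged). The 95% CI is a percentile bootstrap over case
resamples; bootstrap refits use the grid stage only, since sub-grid
refinement is far below the resampling spread and triples the cost.
Degenerate refits are counted and excluded.

Loss of equilibrium is a pass-through of the annotated event sample: the
recorded concentration (as an observer would read the probe, i.e. the
measured value) and its tension at the trace temperature.

## Permutation ANOVA

The two-factor permutational univariate ANOVA computes sequential (Type I,
fixed order A, B, A×B) sums of squares by projecting the response onto
orthonormal bases of each term's incremental subspace (each dummy block is
residualised against all earlier terms and reduced by SVD — exact under
rank deficiency). Pseudo-F = (SS/df)/(SSE/df_E); on balanced designs this
equals the classical two-way F to machine precision, verified against an
independent ANOVA implementation. Inference permutes the raw observation
vector without restriction; the observed arrangement is included, so
p ≥ 1/(n_perm + 1). Defaults: 999 permutations. With zero residual df the
interaction is dropped and flagged. Post-hoc pairwise contrasts permute a
|t|-type statistic per level pair with Holm adjustment (a conventional,
conservative choice). The module operates on pooled per-fish data;
tank-level random effects are out of scope.

## Problem sizes and numerical choices

Test and acceptance runs use the study protocol with scaled cohort sizes
chosen to give stable Monte-Carlo estimates: 50 fish for metabolic-rate
and *P*crit recovery, 100–200 datasets for bootstrap coverage, 500–1000
null datasets × 999 permutations for ANOVA calibration (the permutation
engine is fully vectorised, so these run in seconds). Simulated
intermittent traces in tests sample at 5 s; closed-phase recovery uses the
1 s default. Breakpoint refinement uses `xatol = 1e−7`; equality
tolerances in tests are 1e−9 relative for exact identities and stated
Monte-Carlo bands otherwise.

## Known limitations

* The conformity line is forced through the origin in the simulator but
  not in the fit; real fish often show nonlinear (e.g. hyperbolic)
  conformity that a two-line model can only approximate.
* Background correction assumes blank-chamber respiration transfers
  unchanged to fish chambers; biofilm on the fish itself is not modelled.
* The SMR lowest-decile rule is sensitive to the number of eligible cycles
  when n < 10 (it degenerates to the minimum).
* Percentile bootstrap CIs for breakpoints are mildly anti-conservative;
  empirical coverage here is ~0.93–0.96 at nominal 0.95 under the default
  noise model.
* Unbalanced designs use Type I SS in the fixed order A, B, A×B; term
  order matters there and is the caller's responsibility.
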