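# oxyresp

Analysis toolkit for **intermittent-flow respirometry** of small fishes:
from raw chamber oxygen time series to per-cycle oxygen uptake (Ṁo₂),
standard and maximum metabolic rate, aerobic scope, critical oxygen tension
(*P*crit), loss-of-equilibrium hypoxia tolerance, and permutation-based
treatment inference. It is written for comparative and conservation
physiologists who run chamber respirometry on juvenile fish (the defaults
describe ~1.5 g fish in 300 mL chambers with 20 min sealed determinations
and 2 min flushes) and who want every estimator validated against simulated
fish with known physiology.

## The model

Each sealed determination yields an OLS depletion slope, converted to
mass-specific oxygen uptake with

```
Ṁo₂ = ([O₂]_t0 − [O₂]_t1) · (V / t) · (1 / BW)      [mg O₂ kg⁻¹ h⁻¹]
```

where *V* is the chamber volume minus the animal's volume (L), *t* the
elapsed time (h) and *BW* the body mass (kg). Blank-chamber (background)
respiration is interpolated between daily blanks and subtracted. Then:

* **SMR** — mean of the lowest 10% of QC-passing determinations
  (excluding the post-chase cycle);
* **MMR** — the first determination after an exhaustive 2-min chase plus
  40 s air exposure;
* **AAS** — absolute aerobic scope, MMR − SMR;
* **Fulton's K** — condition factor `K = 100 W / L³` (W in g, L in cm);
* ***P*crit** — breakpoint of a continuous two-segment regression of
  closed-phase Ṁo₂ against PO₂ (oxy-regulation above, oxy-conformity
  below), i.e. the intersection of the two fitted lines, with a
  case-resampling bootstrap CI and an alternative SMR-crossing estimator;
* **LOE** — the dissolved O₂ (and its tension) at loss of equilibrium;
* **perm_stats** — a two-factor permutational univariate ANOVA (pseudo-F,
  unrestricted permutations of the raw observations) with permutation
  pairwise post-hoc tests, for factorial designs such as temperature ×
  oxygen treatment.

Oxygen conversions between mg L⁻¹, kPa and % air saturation use the
Benson–Krause freshwater solubility equations with barometric and vapour
pressure corrections.

A built-in simulator generates both intermittent-flow and closed-phase
traces from fish with known ground-truth physiology, so every estimator in
the pipeline is exercised as a parameter-recovery problem.

## Worked example

```python
import oxyresp as ox

truth = ox.FishTruth(smr=250.0, mmr=700.0, pcrit_kpa=6.0, loe_po2_kpa=2.5)
protocol = ox.ProtocolConfig(sample_interval_s=5.0)
scenario = ox.ScenarioConfig(temperature_c=24.0, noise_sd=0.02, seed=7)

trace = ox.simulate_intermittent_trace(truth, protocol, scenario=scenario)
records = ox.extract_records(trace, protocol)
ox.background_correct(records, [0.0])
ox.qc_filter(records)
summary = ox.summarize_fish(records, body_mass_g=1.5, body_length_cm=5.5)

closed = ox.simulate_closed_phase(truth, protocol, scenario)
po2, mo2 = ox.closed_phase_mo2(closed)
fit = ox.fit_segmented(po2, mo2)
loe = ox.detect_loe(closed)
```

prints (via the obvious f-strings):

```
SMR = 248.8 mg O2/kg/h   (truth 250.0)
MMR = 698.1 mg O2/kg/h   (truth 700.0)
AAS = 449.4 mg O2/kg/h
Fulton K = 0.902
P_crit = 5.45 kPa   (truth 6.0)
LOE at 0.99 mg O2/L = 2.42 kPa after 320 min
```

The fitted SMR and MMR land within ~1% of the values the simulated fish
was given; the breakpoint estimate sits within the sampling spread expected
for a single fish at this noise level (mean absolute error across many fish
is ≈0.3 kPa); and loss of equilibrium is read back at the tension where the
simulated fish stopped maintaining posture.

The same pipeline is exposed as a CLI: `oxyresp simulate | segment |
extract | metrics | pcrit | stats | convert` (see `oxyresp --help`).

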