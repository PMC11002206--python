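# mitoflux

Quantification pipeline for colon mitochondrial bioenergetics in rodent
models of inflammatory bowel disease (IBD), built for physiologists who
measure mitochondrial function with high-resolution respirometry,
Amplex-Red fluorometry and spectrophotometric enzyme assays and want the
downstream arithmetic — fluxes, ratios, calibrations, normalizations,
disease scores, group statistics — reproducible and tested.

## What it computes

**Respiration.** Chamber oxygen concentration traces (nmol O₂/mL over
time) are segmented around the homogenate and ADP injection events.
Each state's oxygen flux is

> J_O₂ = −(dC/dt) · V  [nmol O₂/min]

and the respiratory control ratio RCR = J_O₂(state 3)/J_O₂(state 2)
indexes coupling: ~4 in healthy colon preparations, falling toward 1–2
with disease.

**mtROS and percent electron leak.** A linear calibration of Amplex-Red
fluorescence against known H₂O₂ additions converts a fluorescence slope
into J_H₂O₂ (nmol/min). With SOD present, superoxide production is
exactly twice the H₂O₂ rate, and each superoxide carries one leaked
electron while each O₂ reduced at complex IV accepts four:

> % electron leak = 100 · (2·J_H₂O₂) / (4·J_O₂)

**Enzyme activities.** Absorbance slopes become turnover rates via
Beer–Lambert (complex I: NADH, ε = 6.22 mM⁻¹cm⁻¹ at 340 nm; complex II:
DCPIP, 19.1 at 600 nm; complex III: cytochrome *c*, 18.7 at 550 nm;
citrate synthase: DTNB thiolate, 13.6 at 412 nm); complex IV is measured
as an oxygen flux. Inhibited non-enzymatic backgrounds are subtracted,
rates convert to electron flux (NADH/DCPIP 2 e⁻, cyt *c* 1 e⁻, O₂
4 e⁻), and everything normalizes to citrate synthase activity
(mitochondrial content), giving nmol e⁻/nmol citrate.

**Disease scoring.** The disease activity index sums 0–3 subscores for
percent weight loss (0: ≤2 %, 1: 3–6 %, 2: 7–12 %, 3: >12 %), stool
consistency and stool color, plus colon weight/length morphometrics.

**Statistics.** Mean ± SEM summaries, unpaired pooled-variance Student
t-tests, one-way ANOVA with Tukey HSD post-hoc, significance stars
(\* ≤0.05 … \*\*\*\* ≤0.0001), fold changes.

**Synthetic data.** A generator forward-models every assay (piecewise
linear latent signals + Gaussian noise; lognormal between-animal
variation) and whole sex × treatment cohorts encoding the disease effect
structure, so the entire pipeline is testable without animal data.

## Worked example

```python
import mitoflux as mf
from mitoflux.synthetic_data import TraceSpec

trace = mf.make_trace(TraceSpec(kind="respirometry", state2_flux=25.0,
                                state3_flux=100.0, volume_ml=2.0))
states = mf.segment_states(trace)
print(f"state-2 flux: {states.state2.j_o2:.1f} nmol O2/min")
print(f"state-3 flux: {states.state3.j_o2:.1f} nmol O2/min")
print(f"RCR: {states.rcr:.2f}")

cal = mf.fit_calibration([0, 0.5, 1, 2, 4], [50, 55, 60, 70, 90])
j = mf.h2o2_rate(10.0, cal, 2.0)
print(f"J_H2O2: {j:.2f} nmol/min, J_SO: {mf.so_rate(j):.2f} nmol/min")
print(f"percent leak: {mf.percent_electron_leak(j, states.state3.j_o2):.2f} %")
print(f"DAI weight subscore at 14% loss: {mf.weight_loss_subscore(14)}")
```

prints

```
state-2 flux: 25.0 nmol O2/min
state-3 flux: 100.0 nmol O2/min
RCR: 4.00
J_H2O2: 2.00 nmol/min, J_SO: 4.00 nmol/min
percent leak: 1.00 %
DAI weight subscore at 14% loss: 3
```

The synthetic trace was generated with state-2/state-3 fluxes of 25 and
100 nmol O₂/min; segmentation recovers both exactly, giving the
well-coupled RCR of 4. A 10 AU/min fluorescence slope under a
10 AU/µM calibration in a 2 mL chamber is 2 nmol H₂O₂/min, hence
4 nmol superoxide/min, and against the 100 nmol O₂/min state-3 flux a
1 % electron leak. A 14 % body-weight loss falls in the top rubric bin.

## Command line

```sh
mitoflux simulate --out study/ --seed 1        # synthetic study + config
mitoflux run --config study/config.yaml        # quantify + score + stats
mitoflux validate --config study/config.yaml   # schema check
```

`run` writes `quantification.csv` (per-animal fluxes, RCR, ROS),
`dai_scores.csv`, `comparisons.csv` (endpoint × contrast t-tests with
stars) and `run_log.json` (config hash, seed, QC flags). Identical
config and seed reproduce byte-identical outputs.

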