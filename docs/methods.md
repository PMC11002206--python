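# Methods

## Signal model and slope estimation

Every assay reduces to the slope of one instrument channel over a time
window. Traces are held as validated time series (strictly increasing
times in seconds, finite values, injection events inside the span) and
slopes are ordinary least-squares fits converted to per-minute units in
exactly one place, so the seconds/minutes boundary cannot drift.
No smoothing or filtering is applied before the fit: windows are chosen
to sit on linear segments, and the r² of each fit is reported so
non-linearity is visible rather than hidden.

Two slope modes exist. `fixed_window` fits the samples inside a stated
window. `steepest_window` scans every contiguous window of a fixed
duration (default 30 s, ≥ 10 samples at a 2 s sampling interval) and
keeps the one with maximum |slope|, ties broken to the earliest start so
results are deterministic; this serves assays whose fastest rate
immediately after a substrate addition is the quantity of interest
(e.g. NADH-driven complex I kinetics).

## Respirometry

State 2 opens when tissue homogenate is injected into the closed,
substrate-containing chamber; state 3 when ADP is added. The
nomenclature "state 2" (substrate, no ADP) is kept as used in colon
homogenate work; no re-labelling to state-4 conventions is applied.
Windows: the state-2 slope is measured over the 120 s (configurable)
immediately preceding the ADP event, starting no earlier than 60 s
(configurable settle time) after the homogenate injection; the state-3
slope over 120 s starting 60 s after ADP. The settle time exists because
injections transiently disturb the oxygen signal; the windows sit on the
steady-state segments nearest the transition. Flux is −slope × chamber
volume (2.1 mL by default for the O2k chamber); a negative flux (oxygen
rising) is reported but QC-flagged, never silently dropped, and a
non-positive state-2 flux makes the RCR undefined (an error, not a NaN).
Per-gram normalization happens only when homogenate-aliquot metadata is
present. Fatty-acid-oxidation traces without an ADP event are treated as
single-state fluxes.

## H₂O₂ calibration and percent electron leak

The calibration line of fluorescence against known H₂O₂ concentrations
is fitted **with** an intercept — blanks fluoresce — but only the slope
(AU/µM) enters rate conversion; a non-positive fitted slope is rejected
as an invalid calibration. Rates convert as
AU/min ÷ (AU/µM) = µM/min = nmol/mL/min, times chamber volume.

Stoichiometry: with SOD in the chamber, two superoxides dismutate to one
H₂O₂, so J_SO = 2·J_H₂O₂ exactly; each superoxide carries one leaked
electron and each O₂ fully reduced at complex IV accepts four. The leak
percentage uses electrons delivered to O₂ as the denominator
(100·2·J_H₂O₂ / 4·J_O₂). Whether the leaked electrons should be added to
the denominator is a genuine convention choice; both are implemented
(`LeakDenominator.TOTAL` adds them) and at leak below 2 % they differ by
under 0.05 percentage points, so the choice does not affect any
qualitative conclusion. Fluorescence slopes are measured over the same
window as the paired respiration state, since ROS and respiration are
recorded simultaneously.

## Enzyme kinetics

Beer–Lambert conversion: |dA/dt| / (ε·l) in mM/min, times assay volume
(mL) × 1000 for nmol/min. Extinction coefficients (mM⁻¹cm⁻¹): NADH 6.22
at 340 nm, DCPIP 19.1 at 600 nm, cytochrome *c* 18.7 at 550 nm, DTNB
thiolate 13.6 at 412 nm. A slope running against the assay's expected
direction is QC-flagged as a possible inverted trace. Inhibited
background rates come from separate traces and are subtracted; a
negative net rate is flagged, never clipped, so over-subtraction stays
visible. When no background trace is supplied the background defaults to
0 with a QC note.

Electron equivalences {NADH 2, DCPIP 2, cytochrome c 1, O₂ 4} are fixed
as standard redox bookkeeping: two-electron carriers, the one-electron
cytochrome *c*, four-electron O₂ reduction. Complex II accounting is the
same (2 e⁻) whether one follows succinate or DCPIP. Content
normalization divides per-gram electron flux by per-gram citrate
synthase rate; minutes and grams cancel, leaving nmol e⁻/nmol citrate.
The citrate-synthase plate-reader assay's effective pathlength and well
volume depend on the instrument and fill volume; they are required
config fields with defaults (1 cm, 0.25 mL) that deployments should
override.

## Disease activity

DAI = weight-loss subscore + stool-consistency subscore + stool-color
subscore, each 0–3, total 0–9. The weight bins are integer-labelled and
non-contiguous (≤2, 3–6, 7–12, >12 %), so percent loss is rounded to the
nearest integer before lookup, mapping every real input to exactly one
bin. Weight gain scores 0. The baseline is each animal's day-0 weight
(dosing starts on day 0), and scoring uses the same-day loss; a
`peak_dai` convenience column reports each animal's maximum. Colon
morphometrics are plain quotients (colon weight / body weight, colon
weight / colon length) with positivity checks.

## Statistics

Two-group comparisons use the unpaired pooled-variance Student t-test
(not Welch), two-sided; multi-group comparisons one-way ANOVA with a
Tukey HSD pairwise table attached when the omnibus p ≤ 0.05 (Tukey is
the standard companion of one-way ANOVA; uncorrected pairwise t is
available as a config switch). Summaries are mean ± SEM. No
multiple-testing correction is applied across endpoints. Stars:
\* ≤0.05, \*\* ≤0.01, \*\*\* ≤0.001, \*\*\*\* ≤0.0001. Degenerate
identical-group inputs define t = 0, p = 1 rather than NaN.

## Synthetic data: what it emulates, what it does not

Traces are piecewise-linear latent signals (segment slopes implied by
the target fluxes/activities and volumes, breaks at injection events)
plus i.i.d. Gaussian noise. The default respirometry schedule injects
homogenate at 60 s and ADP at 360 s into a 600 s trace sampled every
2 s; the chamber starts hyperoxygenated at 400 nmol/mL, as homogenate
protocols do, and a spec whose fluxes would drive the oxygen
concentration negative is rejected as infeasible. Weight trajectories
dip linearly to a sex-specific nadir (8 % loss in males, 11 % in
females) over days 2–3 and recover to the healthy growth curve
(+0.5 %/day) by day 7.

Cohorts draw each animal's endpoint as group mean × mean-one lognormal
noise (physiological endpoints are positive; mean-one preserves the
group means in expectation). The default effect multipliers encode the
disease structure: males lose mitochondrial content (citrate synthase
×0.6, cardiolipin ×0.7) and catalase (×0.6) with ~2-fold leak increases
(1.4-fold on the medium-chain fatty-acid substrate); females lose
respiration and RCR (×0.5) and complex I/IV activity (×0.6) with 2-fold
leak increases; control males sit at 0.7× control females on several
respiration and complex endpoints; mitoTEMPO arms partially restore the
female defects and leave males unchanged. Between-animal CV defaults to
15 %, a value at which the default effects are detectable at n ≥ 4–8 per
group while the statistics remain non-trivial; reported variances are
not available, so the CV is a documented free parameter.

The generator is phenomenological: it does not model electron-transport
kinetics, ROS chemistry, oxygen back-diffusion, instrument drift, or
injection artifacts (artifact spikes are off by default). Passing
roundtrip tests therefore demonstrates that the analysis inverts the
stated signal model exactly and behaves correctly under Gaussian noise —
not that it is robust to every failure mode of real instrument exports.

## Numerical and design notes

- Windows are closed intervals over sample times; a sample exactly on a
  piecewise break belongs to both adjacent linear segments (the latent
  signal is continuous), which keeps zero-noise roundtrips exact.
- All generation is seeded through `numpy.random.default_rng`; the same
  spec and seed give byte-identical outputs, and the pipeline writes a
  config hash and seed into its run log.
- Problem sizes in the test suite: noise-recovery checks use 200
  replicates, null-calibration checks 2000 simulated t-tests at n = 6
  per group, the permutation oracle enumerates all 924 relabelings at
  n = 6 + 6, and the cohort-convergence check uses one group of 10⁴
  animals.

## Known limitations

- Proprietary instrument formats are not parsed; traces enter as CSV in
  a declared dialect.
- Antioxidant-enzyme and ELISA kit chemistries are not modelled; those
  endpoints enter only as per-animal columns in the cohort table.
- No mixed-effects or repeated-measures modelling of daily weight
  curves; daily data feed only the DAI rubric.
- Km/Vmax kinetic fitting is out of scope; all enzyme measures are
  initial rates.
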