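# Methods

## Scope and design

The package implements the desk-side analysis chain of a longitudinal
db/db-mouse retinal study: stimulus calibration, scotopic ERG feature
extraction, oscillatory-potential (OP) isolation, Naka-Rushton
intensity–response fitting, extracellular-flux respiration parameters,
and the group statistics. Raw recordings from such studies are rarely
public, so a first-class synthetic-data module generates every input
with exact ground truth; all quantitative claims the test suite makes
are claims about this chain applied to that generator or to printed
summary statistics, not about any animal's raw data.

## Stimulus calibration

Flash strengths are scotopic energies in log cd·s/m². The conversion
to photoisomerizations per rod uses the standard rate constant
1 scot cd/m² = 516 R*/rod/s, i.e. R* = 10^I · 516 for a flash of
energy I; intensities are treated as flash energies, so no separate
duration scaling is applied. Light zones 1–4 (rod threshold,
rod–bipolar, mixed, cone-involved) are assigned by thresholds on log
intensity. Only the zone-3/4 boundary (−0.3 log cd·s/m², the top of
the rod operating range) is fixed by the protocol; the internal
boundaries default to −3.8 and −2.0, chosen to separate the protocol's
example stimuli (−4.32, −3.3, −1.3, +1.3), and are configurable. The
rod-range test is strict (< −0.3).

## Synthetic ERG model

The generator composes minimal smooth parametric shapes so that every
feature extractor has exact ground truth:

- **b-wave**: gamma-density-like transient
  f(t) = (t/t_p)^p · exp(p(1 − t/t_p)), unit peak at t_p (default
  70 ms, shape p = 8), scaled by B_max·NR(I) where NR is the
  Naka-Rushton function (defaults B_max = 600 µV, σ = 10⁻² cd·s/m²,
  n = 1).
- **a-wave**: negative lobe of the same gamma family (trough 15 ms,
  shape 4), present at zone-3/4 intensities with fixed amplitude
  (default 150 µV). The shape-4 lobe is broad enough that the 60 Hz
  measurement smoothing (below) attenuates its trough by under 2%.
- **OPs**: Gabor atoms at the OP carrier frequency (default 110 Hz),
  one per carrier period starting at 15 ms, envelope sigma of half a
  period, amplitudes op_gain × b-amplitude with a 0.85 per-wavelet
  decay.
- **pSTR**: slow positive gamma lobe (peak 110 ms, default 25 µV),
  present only at zone-1 intensities, where it dominates the tiny
  b-wave.
- **noise**: i.i.d. Gaussian, sd = noise_sd/√n_sweeps (sweep
  averaging; defaults 20 µV per sweep, 40 sweeps).

All stimulus-driven components are hard-zeroed before stimulus onset,
and the whole response is zero below a detection-threshold intensity
(default −5.0 log cd·s/m²), so a sub-threshold noise-free epoch is
identically zero. Sampling defaults: 2 kHz (Nyquist 1 kHz, well above
the 300 Hz band edge), 350 ms epochs with 50 ms pre-stimulus.

What the generator does **not** emulate: photoreceptor transduction
kinetics (no PIII model), cone intrusion at bright flashes, electrode
drift, mains interference, or inter-animal waveform variability.
Passing tests therefore demonstrate correctness of the measurement
chain, not robustness to every artifact of real recordings.

Seed policy: every generator is a pure function of (params, seed);
collections derive element seeds as SeedSequence([master, index]).

## Feature measurement

Epochs are baseline-corrected by subtracting the pre-stimulus mean
(≥ 10 ms of baseline required). A zero-phase 4th-order Butterworth
low-pass at 60 Hz is applied before peak localization so OP wavelets
cannot capture the b-peak; amplitudes are read from the smoothed trace
for consistency. Default windows: a-wave 3–50 ms, b-wave 20–150 ms,
pSTR 80–200 ms — standard murine scotopic timing, all configurable.
The a-wave amplitude is the trough depth below baseline; the b-wave is
measured trough-to-peak when the a-wave clears a noise gate (3× the
pre-stimulus sd, floor 1 µV) and baseline-to-peak otherwise (dim
flashes have no measurable a-wave); both conventions are selectable.
Flat traces yield zero amplitudes with a flag rather than an error.

## OP isolation

The band-pass is deliberately the literal protocol: FFT on the native
grid, hard rectangular mask zeroing every bin with |f| outside
[65, 300] Hz (band edges inclusive — components *beyond* the cut-offs
are eliminated, the cut-offs themselves survive), inverse FFT. No
zero-padding (padding moves bin frequencies; it is opt-in), no taper
by default (a windowed variant exists behind a flag); the ringing a
hard mask produces is accepted and quantified by the recovery tests.
Wavelets are local maxima in a 10–100 ms window with prominence above
3× the filtered pre-stimulus sd, taken in time order, first four kept.
Amplitude is peak minus the *following* trough; if none follows, the
preceding trough is used and the result flagged ("adjacent trough" is
ambiguous in common usage; the preceding-trough convention is
available as an option).

## Naka-Rushton fit

V(I) = B_max·Iⁿ/(Iⁿ + σⁿ) is fitted in linear intensity (the
hyperbola's natural variable) to rod-range points only, minimizing the
residual sum of squares with `scipy.optimize.least_squares` under
bounds B_max ∈ [0, 2·max amplitude], σ within the data range ±1 log
unit, n ∈ [0.5, 3]. A deterministic multi-start (five semisaturation
starts spaced across the bounded log range) makes the fit reproducible
without a seed; n can be fixed (e.g. at 1). Fits are validated against
a brute-force grid-search oracle: the fitted RSS never exceeds the
best grid candidate's.

## Respiration parameters

With phases basal → FCCP → rotenone/antimycin A: non-mitochondrial
OCR is the mean of the final phase; basal respiration is the last
basal-phase measurement minus non-mitochondrial; maximal is the
FCCP-phase maximum minus non-mitochondrial; spare capacity is maximal
minus basal (an exact identity). The last/max conventions follow the
flux-analyzer vendor's standard report and can be switched to phase
means. No oligomycin phase exists in this protocol, so ATP-linked
respiration and proton leak are deliberately absent. Negative derived
values (e.g. failed FCCP stimulation) are flagged, not clamped.
Protein normalization divides all four parameters by punch protein
mass (pmol/min/mg).

## Statistics

Orientation is fixed as (group 2 − group 1), i.e. (db/db − db/+) when
the control group is passed first. The pooled t from summaries uses
sd_i = SEM_i·√n_i, pooled variance ((n₁−1)sd₁² + (n₂−1)sd₂²)/(n₁+n₂−2)
and df = n₁+n₂−2; Welch's variant uses √(SEM₁²+SEM₂²) with
Welch–Satterthwaite df. Raw-sample tests are routed through the same
formulas, so summary and raw routes agree exactly (and match
`scipy.stats.ttest_ind` — the independent cross-check in the tests).
The pooled test is the default because reported degrees of freedom in
this literature are n₁+n₂−2 throughout. P-values are two-sided; no
multiplicity correction is applied, as none is standard in these
reports.

The mixed (split-plot) ANOVA decomposes a balanced complete
subjects × time table into group, subject-within-group,
time, time × group and time × subject-within-group sums of squares;
group is tested against subject-within-group, time and the interaction
against the within error. The Greenhouse–Geisser epsilon is computed
from the *pooled within-group* covariance of the time measures
(double-centered; ε = (tr S̃)²/((k−1)·tr S̃²), bounded in [1/(k−1), 1])
— the SPSS/JASP convention; pingouin computes epsilon without pooling
by group, so its epsilon differs slightly while all F statistics agree
to machine precision. Corrected within-subject p-values use
ε-rescaled numerator and denominator dfs. Simple main effects default
to the per-timepoint one-way ANOVA (for two groups, F = t² of the
pooled t); the omnibus-error variant (same numerator, omnibus
between-subjects error MS and df) is available. Repeated-measures and
"mixed-model" ANOVAs in this design are the same split-plot machinery.

A table of twelve published db/+ vs db/db comparisons (OP amplitudes,
retinal morphometry, respiration parameters; printed mean, SEM, n, t,
df) ships with the package; `reproduce_reference_tests` recomputes
each pooled t and df and reports deviations (tolerance |Δt| ≤ 0.05,
reflecting the 3-decimal printed precision).

Simple main effects reported for HbA1c in this literature are not
recoverable from printed summaries under either error-term convention
(the numerator/denominator convention used by the original GUI
software is not stated), so no reference row asserts them.

## Numerical choices and problem sizes

Tolerances: filter oracle properties at 1e-9 on integer-cycle
constructions; exact-model Naka-Rushton recovery at 0.1%; OP recovery
at one sample period for times and 10% for amplitudes (window-edge
leakage tolerated); summary-statistic identities at 1e-9–1e-12.
Simulation sizes are chosen to keep the whole suite fast while leaving
comfortable statistical margins: 200 replicate epochs for the
noise-scaling check, 200 noisy fits for B_max recovery (median within
5%), ten 200-subject cohorts for the epsilon check, and 10⁴ null
simulations at n = 10/group for type-I calibration (nominal 0.05,
acceptance band 0.04–0.06, ≈ 4.6 binomial sd).

## Known limitations

- The waveform model is phenomenological; parameter recovery results
  do not transfer to waveforms whose components overlap very
  differently (e.g. photopic responses).
- The hard spectral mask is periodic-extension based; epochs whose
  endpoints differ strongly from zero produce edge ringing (epochs
  here start and end near baseline).
- Trough-to-peak b-wave amplitudes include the a-wave at zone-3/4
  stimuli; a fitted B_max under that convention exceeds the b-wave
  lobe's own asymptote. Baseline-referenced measurement is provided
  where the distinction matters.
- The ANOVA requires a balanced complete design; missing cells raise
  rather than impute.
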