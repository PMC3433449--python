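# Methods

This note documents the models, measurement conventions and numerical choices
behind `cardiotrace`, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## Signals and conventions

A `Trace` is a uniformly sampled single-channel series: membrane potential in
mV (patch-clamp at a nominal 20 kHz, or catheter MAP), Fura-2 fluorescence
(per-channel or F340/F380 ratio at camera rate, default 20 Hz), or ECG.
Protocol events (pacing pulses, drug on/off, caffeine puffs) are annotations
with absolute times. All analysis parameters live in one `AnalysisConfig`
object so that a run is fully described by (trace, annotations, config).

Analysis operates on a centred moving-average copy of the trace
(`smooth_window_ms`, default 2 ms for voltage; 3 samples for ratio traces;
even window sizes are widened by one sample to stay centred). Level crossings
(APD, repolarization completion) are linearly interpolated between samples,
which makes durations sub-sample accurate and is what allows <0.5% feature
recovery at 20 kHz.

## AP detection and features

Upstrokes fire where the smoothed upstroke velocity exceeds
`derivative_threshold` (default 5 mV/ms) with a `refractory_ms` lockout
(default 100 ms). The velocity is a central difference spanning the smoothing
window rather than a per-sample gradient: at 20 kHz with 1 mV Gaussian noise
a per-sample gradient has ~4.5 mV/ms noise even after smoothing and would
cross the threshold spuriously, while the windowed difference reduces this to
~0.06 mV/ms. The activation time is the centre of the velocity-maximum
plateau near the crossing.

APD is referenced to the activation time (maximum dV/dt), the common
electrophysiology convention; the choice is recorded in the output metadata
(`apd_reference`). MDP and peak values are read from the smoothed trace: the
raw minimum over ~20 000 diastolic samples with 1 mV noise carries a −4 mV
extreme-value bias that would dominate the error budget, whereas the smoothed
minimum is biased by well under 1 mV.

The ventricular-like flag (APD₉₀/APD₅₀ < 2 plus a discernible plateau) is a
heuristic for subtype screening only and is excluded from all quantitative
claims.

Drug (adrenaline-type) effects are summarised within cell as
`100·(BPM_drug − BPM_base)/BPM_base`, `100·(APD_base − APD_drug)/APD_base`
and absolute ΔAPA / ΔMDP, comparing the means of the two conditions.

## Afterdepolarizations

An EAD is a depolarizing deflection between the AP peak and repolarization
completion; a DAD arises between repolarization completion and the next
activation. "Completion of repolarization" is operationalised as the crossing
of `peak − repol_complete_fraction·APA` (default 0.90, the APD₉₀ level):
a return-to-MDP criterion is fragile under noise, and the APD₉₀ surrogate is
both robust and configurable.

Candidates are local maxima of the smoothed trace between an AP peak and the
next activation; each needs a preceding local minimum, which excludes the
monotone repolarization limb itself. The candidate prominence floor is 60% of
the threshold amplitude (`ad_threshold_pct`·APA): far above smoothed noise,
but low enough that borderline events are still measured and judged on their
amplitude rather than silently dropped. Amplitude references follow how each
event interrupts the trace: an EAD is measured from the local minimum
preceding its peak on the repolarization limb; a DAD from the diastolic
baseline (median over the central half of the diastole before the event).
Extrema are located on the smoothed copy and then refined on the raw trace
around the located indices, which makes the measured amplitude of a
noise-free event exact. Events within `pace_artifact_ms` (2 ms) of a pacing
annotation are discarded as stimulus artifacts. Events are kept at
`relative_amplitude_pct ≥ ad_threshold_pct` (default 3% of the preceding
APA). Solitary-EAD takeoff potentials are reported, not filtered on.

Known limitation: with recording noise the raw-trace refinement inflates
reported event amplitudes by roughly twice the noise SD (about +1.5
percentage points of APA at 1 mV noise), so near-threshold classification
blurs accordingly on noisy data. Detection (yes/no) is unaffected by this at
realistic noise because of the prominence floor.

A burst episode is a maximal run of ≥2 consecutive upstrokes whose cycle
lengths fall below 50% of the trace median and whose intra-run diastolic
minima stay ≥10 mV depolarized relative to the trace MDP; the episode reports
its most negative diastolic potential and largest upstroke amplitude (peak
minus adjacent intra-run minimum).

## Ca²⁺ analysis

`compute_ratio` forms `(F340 − bg340)/(F380 − bg380)` from time-aligned
channels with per-channel scalar backgrounds and rejects non-positive
denominators. Transients are prominence-based peaks on the lightly smoothed
ratio; the prominence floor is the larger of 6.5× the smoothed-noise estimate
(robust MAD-of-differences, divided by √window because peak finding runs on
the smoothed trace) and 4% of the trace's 2–98 percentile spread. The
diastolic level before each transient is the median over the last quarter of
the preceding inter-transient interval (the whole pre-train segment for the
first transient); amplitude = raw peak − that level. The epoch from the first
caffeine annotation onward is excluded from spontaneous detection.

The caffeine response (SR content) is the maximum over 10 s after the puff
minus the median over the 2 s before it; both windows are configurable, and
the amplitude can be expressed raw or as ΔF/F₀ (normalised to the pre-puff
baseline). Fractional SR release is the mean of the last `n_last_transients`
(default 3) pre-caffeine amplitudes divided by the caffeine amplitude, in a
single consistent convention; with a shared baseline the ratio is identical
under both conventions.

Rhythm classification quantifies "irregular" and "varying" as coefficients of
variation of the inter-transient intervals and amplitudes, threshold 0.15 on
each axis (configurable): R (neither exceeds), Ra (amplitude only), I
(interval only), Ia (both). CV is scale-free, so the category is invariant to
uniform time rescaling.

## Repolarization-wave labelling

Within each beat's repolarization segment (25 ms after the upstroke to the
next activation), up to three prominence-ranked local maxima are retained and
re-sorted by time; heights are measured above the beat's 10th-percentile
baseline. A peak is *merged* with its predecessor when the inter-peak valley
exceeds `merge_valley_fraction` (default 0.90) of the smaller peak height — a
geometric proxy for two waves visually fusing. Labels are a pure function of
the per-beat merged flags: peak 1 is T1; peak 2 is T2 when it merges in at
least `min_evidence` beats (default 1, i.e. "occasionally"), else U; peak 3
is always U. No frequency threshold beyond ≥1 beat is imposed because merging
is rare and binary in the source taxonomy; the evidence count is reported so
stricter criteria can be applied downstream.

## Cohort statistics

`compare_groups` is the classical Student's t-test — pooled-variance unpaired
form (Welch behind a flag) and difference-based paired form — two-sided, with
star coding (\* P<0.05, \*\* P<0.01). Degenerate zero-variance inputs return
t = 0, P = 1 when means agree. Summaries are mean ± SEM (sd/√n). No multiple
testing correction is applied; reports carry the number of comparisons as a
footnote. Rhythm proportions sum to 1 with `abnormal = 1 − fraction(R)`.

## Synthetic generator

The generator emulates the statistical structure of the recordings, not their
biophysics (no ionic currents, no stochastic SR release).

**AP train.** Each beat is `MDP + APA·u(t)·r(t)`: a sigmoid upstroke `u`
(midpoint 0.5 ms, slope scale 0.12 ms) and a repolarization envelope `r` that
is an equal mix of two falling logistics whose midpoints are solved
(scipy `root`, residual <1e-9) so the analytic 50%/90% crossings, measured
from the upstroke midpoint, land exactly on the requested APD₅₀/APD₉₀. The
logistic widths scale with APD₉₀−APD₅₀ (8% and 20%); parameter sets whose
envelope cannot hold a plateau (r(0) < 0.995, i.e. strongly triangulated
shapes) are rejected rather than generated inaccurately. Defaults are the
control-line phenotype (41 BPM, 204.4/329.7 ms, 117.85 mV, −68.35 mV at
20 kHz); noise is additive Gaussian, added last, and generation is a pure
function of (params, seed).

**Event injection.** EADs and DADs replace the waveform inside the event
window with a cosine rise to `relative_amplitude_pct`·APA above the
grid-snapped window-start value and a cosine fall back to the trace: the
window start is a true local minimum and the injected amplitude is *exactly*
the local-minimum-to-peak measure the detector uses, which is what lets the
detection boundary be recovered to 0.01 percentage points by bisection.
EAD peaks are placed at `offset_fraction`·APD₉₀ after activation (validated
to precede repolarization completion); DAD peaks at `offset_fraction` of the
diastolic interval. Large EADs (≈10% APA) must sit on the phase-3 limb
(offset ≳0.6) — placed on the plateau they would top the AP peak itself.
Bursts elevate the diastolic baseline by `relative_amplitude_pct`·APA via a
cosine-shouldered plateau carrying `burst_n_upstrokes` miniature upstrokes of
`burst_upstroke_mV` at `width_ms` intra-burst cycle length.

**Ca²⁺ train.** Baseline `diastolic_level + drift·t`; transients are
peak-normalised double exponentials (rise τ 80 ms, decay τ 400 ms) at 20 Hz,
with truncated-normal intervals (floor 25% of the mean) and amplitudes
(floor 10% of the mean) at the requested CVs; default rate 0.5 Hz, amplitude
0.5 ratio units on a baseline of 1.0. The caffeine pulse (rise τ 150 ms,
decay τ 2 s, default amplitude 2.0) must follow the last spontaneous
transient and is annotated `caffeine_puff`. The intended rhythm category
follows from the parameter CVs against the 0.15 thresholds.

**Repolarization sequences.** Beats at a fixed cycle length (default 1 s,
1 kHz) carry a sharp upstroke spike plus 1–3 Gaussian repolarization peaks.
For merge-flagged beats, peak 2 is moved toward peak 1 by bisection until the
analytic valley fraction reaches 0.95 (safely above the 0.90 detection
criterion) while two distinct maxima remain; ground-truth peak times are the
maxima of the analytic curve. Templates whose unmerged valley fraction
already reaches 0.90 are rejected.

## What the closure tests show — and what they do not

The principal test harness is closure: noise-free generated traces, analysed
by the downstream modules, recover every ground-truth parameter (features to
<0.5% over a 24-point grid spanning the reported phenotype ranges ±30%, with
1 mV noise to <2%; detection boundaries to 0.01 pp; wave labels exhaustively
over all ≤6-beat merge patterns; rhythm classes at ≥95% over 200 trains).
Rhythm-classification runs use 20 transients per train — with ~10 beats the
sample CV is too noisy an estimator to reflect the underlying class near the
threshold, and recordings of this kind span many more beats. The residual
~3% confusion is Ra→Ia: transients clamped at the generator's amplitude
floor (10% of the mean, ≈4:1 SNR after smoothing) occasionally fall below
the detection floor, and the missed beat doubles one interval.

These tests validate the measurement chain, not the biology: real recordings
contain baseline wander, motion and photobleaching artifacts, cell-to-cell
waveform diversity, fused or subthreshold release events and pacing
artifacts that the generator only partially emulates (drift and noise are
modelled; wander and motion are not). Passing closure therefore demonstrates
correctness of the algorithms under the stated signal model, and the
configuration surface (thresholds, windows, fractions) is the intended
adaptation point for real data.

## Problem sizes and determinism

Default test and acceptance problem sizes — 8–10 beats per AP train, 24 grid
points, 200 Ca²⁺ trains, 126 repolarization sequences, 1000 null t-tests —
were chosen so the whole verification runs in well under a minute on one
core while keeping every estimate's sampling error far from its tolerance.
All stochastic stages take explicit integer seeds; identical (params, seed)
pairs produce bitwise-identical traces.
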