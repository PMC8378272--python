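# Methods

## Scope and model of the data

`cardiomps` analyzes single-channel optical recordings of beating cardiac
micro-tissues: a voltage-sensitive dye or a genetically encoded calcium
indicator imaged at a nominal 100 frames/s for 6 or 30 s. The measured
signal is modelled as

    F(t) = (F0 + A · s(t)) · exp(-β t) + ε(t)

with a baseline fluorescence offset `F0`, beat waveform `s(t)` scaled by an
amplitude `A`, multiplicative photobleaching at rate `β` (per second), and
additive Gaussian noise `ε` with standard deviation expressed as a fraction
of the beat amplitude. All downstream metrics are defined on the detrended,
amplitude-normalized signal.

## Per-beat metrics

**Detrending.** A rolling 10th-percentile envelope (default window 2 s)
tracks the diastolic baseline; a linear (voltage dye) or exponential
(calcium indicator, where bleaching dominates) drift model is fitted to the
envelope away from the window edges and then refined on the 20% of samples
closest to the fitted baseline. The fitted drift, anchored at its minimum,
is subtracted. The refinement step makes a drift-only input reproduce
exactly and removes the lag a rolling envelope otherwise introduces on
monotone inputs.

**Segmentation.** Peaks are found on a lightly smoothed copy of the signal
(centered boxcar, width 3 samples; linear segments are preserved exactly)
with a prominence threshold of 0.3 in units of the nominal beat amplitude,
a 200-ms refractory distance, and a minimum width of 2 samples. The
prominence threshold is deliberately *absolute* on the amplitude-normalized
scale: a range-relative threshold cannot separate noise from signal
(Gaussian noise peaks scale with the observed range), whereas on traces
scaled by the same tissue's drug-free control amplitude, 0.3 cleanly rejects
noise (σ ≈ 0.02) and sub-threshold afterdepolarizations while keeping
drug-weakened beats. The study pipeline performs exactly this scaling.

**Activation and baseline.** The activation reference is the point of
maximum upstroke velocity (max dF/dt), located as the largest first
difference between the previous peak and the current one with parabolic
sub-sample refinement. The per-beat baseline is the median of the 100-ms
diastolic window ending 20 ms before activation (robust to diastolic
events); when that window does not fit, the global 5th percentile is used.
Beat amplitude is read from the raw samples adjacent to the detected peak —
smoothing systematically underestimates sharp voltage upstrokes (a 20-ms
rise spans only two frames).

**APD.** APD at repolarization fraction r is the time from activation to
the first post-peak downward crossing of `baseline + (1-r)·amplitude`,
linearly interpolated between bracketing samples. If the signal never
reaches the threshold before the next activation the APD is *unresolved*:
the beat is excluded from APD and triangulation aggregates but kept for
arrhythmia analysis. Per-recording APD summaries use the median over
resolved beats (configurable). Expected accuracy at 100 Hz with noise
σ = 0.02: the crossing sits on a segment of slope `0.5A/(APD80-APD30)` per
ms, so the noise-propagated SD is `σ/√3 · (APD80-APD30)/0.5` ms plus a
frame-quantization term `10/√12` ms — about 3–5 ms for typical waveforms,
which the recovery benchmark confirms (median ≈ 3 ms, max ≈ 10–16 ms over
APD80 ∈ [200, 480] ms).

**Rate correction.** Fridericia: `cAPD = APD / RR^(1/3)` with RR in
seconds. For paced recordings that pass the capture check (mean rate within
5% of the stimulus frequency and RR coefficient of variation ≤ 5%, at least
3 beats) RR is the pacing period; otherwise the measured mean RR is used.

**Triangulation.** `(APD80 - APD30)/APD80`, computed per beat from raw
(uncorrected) APDs and summarized by the median. Values near 0 indicate a
plateau-shaped (square) action potential; rising values indicate plateau
loss, a proarrhythmic repolarization shape.

## Arrhythmia analysis

**EADs** are sought per beat in the phase-3 window (peak → APD90 crossing):
any local minimum followed by a rise of at least 5% of the parent beat
amplitude counts. Candidates are gated on the smoothed signal (at 80% of
the threshold, compensating known smoothing attenuation of narrow
deflections) and confirmed, and their amplitude measured, on raw samples
between the pre-event minimum and the event peak. **DADs** are positive
deflections in the diastolic window (APD90 → next activation) with
prominence in [10%, 60%) of the preceding beat amplitude; anything ≥ 60%
is a beat and is the segmenter's business. Event amplitude precision is
limited by single-frame noise to roughly ±0.025 (fraction of beat
amplitude).

**Shape irregularity** (the TdP-like trait of continuously changing
amplitude and configuration) is the larger of the population coefficients
of variation of beat amplitude and of APD50; it requires ≥ 4 beats and
flags above 0.2. Clean synthetic recordings sit below 0.05; ±40%
amplitude/APD modulation exceeds 0.3.

**Poincaré instability.** Successive APD80 values, each normalized to the
recording mean, form pairs `(APD_{n-1}, APD_n)`. The instability index is
the RMS perpendicular distance of the pairs from the identity line — an
SD1-style short-term variability on the normalized scale. It is 0 exactly
for a constant sequence, `ε·√2` for perfect alternans `a(1±ε)`, invariant
under uniform APD rescaling, and flagged unstable above 0.05 (5% of the
mean APD). The threshold operationalizes the qualitative distinction
between a tight cluster on the identity line and dispersed, disorganized
polygons; on synthetic data it separates i.i.d. jitter of 1–2% (index ≈
0.01–0.02) from ≥ 5% alternans with a wide margin.

**Classification.** Each tissue × dose is called exactly one of
`weak_or_silent`, `arrhythmic`, or `normal`, in that precedence order, from
the 30-s spontaneous calcium recording: weak-or-silent when no beats are
detected or the maximal beat amplitude is below 60% of the same tissue's
dose-0 amplitude; otherwise arrhythmic when any EAD or DAD is detected
(one event suffices by default; configurable) or shape irregularity
exceeds 0.2; otherwise normal. Weakness takes precedence so the categories
partition the cohort, matching how weak/silent and arrhythmic fractions
are reported side by side.

## Study orchestration

Tissues whose drug-free baseline APD80 is ≥ 500 ms are excluded (strict
`< 500 ms` inclusion; 500.0 exactly is excluded). Metric routing per
tissue × dose: APD80 and upstroke velocities from paced recordings when
capture passes (falling back to spontaneous), triangulation from
spontaneous voltage traces, beat rate / instability / classification from
the 30-s spontaneous calcium trace. Each tissue's corrected APD80 is
normalized to its own dose-0 value (dose 0 ≡ 1 exactly). Doses without
evaluable signal are reported as excluded with a reason, never imputed.

**Statistics.** One-way ANOVA plus Dunnett's many-to-one comparisons
against dose 0. Dunnett adjusted p-values are computed exactly from the
equicorrelated multivariate-t representation
`T_j = (√(1-λ_j²) U_j + λ_j W)/S`, `λ_j = √(n_j/(n_j+n_0))`, by
deterministic Gauss–Hermite × Gauss–Legendre quadrature (96 × 96 nodes;
agreement with the two-sided pooled t-test at k = 1 is ~1e-13, with
scipy's randomized-QMC implementation ~3e-5). Family-wise error under the
null is 0.05 by construction; the 10,000-simulation calibration in the
acceptance suite confirms it empirically. Arrhythmia incidence is compared
pairwise between doses with the chi-squared approximation on 2×2
(arrhythmic vs not) tables, without Yates correction by default (flag
available). Significance stars follow the usual 0.05/0.01/0.001/0.0001
ladder.

**Biomarkers.** For each marker, LOD = mean + 3·SD (sample SD, ddof 1) of
the negative controls; a marker is retained iff strictly more than 65% of
the non-missing study samples lie strictly above its LOD. Both boundaries
are strict by a literal reading of the rule; at least 2 negative controls
are required per marker.

## Synthetic data generator

The generator exists because no raw recordings accompany the protocol; it
emulates the statistical structure the analysis assumes, with analytic
ground truth.

**Beat template.** A scaled logistic upstroke (5–95% rise within
`upstroke_ms`: 20 ms voltage, 80 ms calcium; maximum slope at its midpoint,
which *is* the activation reference), then piecewise-linear repolarization
through `(APD30, 0.7A)` and `(APD80, 0.2A)`, reaching zero at
`APD80 + 0.5(APD80 - APD30)` so APD90 stays defined. Template APD30/APD80,
measured from activation per the analysis definition, equal their targets
exactly before noise.

**Events.** An injected EAD reverses repolarization: from the local
template level the trace rises by exactly `h·A` over a 30-ms half-cosine,
holds a 20-ms plateau (so the peak survives frame-rate smoothing), and
rejoins the template over 40 ms — the ground-truth rise equals `h` by
construction. (An additive Gaussian bump was rejected: on a steeply falling
repolarization its measurable rise depends on the local decay slope, so
"inject 15%" would not mean "a 15% deflection".) A DAD is a 100-ms hann
hump centered in the diastolic interval. Alternans scales APD30/APD80 and
amplitude of alternating beats by `1±ε`. Noise is additive Gaussian after
multiplicative exponential bleaching (default β = 0.005/s, chosen so a
30-s recording loses ~14% intensity — visible but not confounding).

**Cohorts.** Baseline tissue APD80 ~ Normal(350, 60) truncated to
[200, 600] ms — stated as an assumption; it makes a realistic minority
(~0.6%) violate the 500-ms screen. Baseline triangulation ~ Normal(0.35,
0.05) clipped to [0.2, 0.5]; spontaneous rate ~ Normal(0.75, 0.08) Hz
clipped to [0.55, 1.0]. Drug effects are monotone Hill curves in dose for
the APD multiplier, triangulation shift, amplitude factor, alternans, and
the probabilities of EADs, DADs and beating cessation; the HCQ-like preset
uses EC50 = 1 µM (the clinical Cmax), Emax multiplier 1.4, EADs emerging
around 10 µM and silencing near the 1000 µM top dose. Realized APD80 is
capped so repolarization completes within the shortest beat period of the
protocol (a tissue cannot repolarize past its cycle length). Randomness
derives from one seed through per-recording `SeedSequence` spawn keys, so
identical seeds give bit-identical cohorts and partial regeneration is
reproducible.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: motion artefacts, focal drift and segmentation
of real video; cell-to-cell heterogeneity within a tissue; rate-dependent
APD restitution (the drug effect enters as a static multiplier); correlated
(non-Gaussian, non-stationary) noise; conduction abnormalities; and any
mechanistic ion-channel pharmacology. Detector operating characteristics
quoted here are for this noise model at σ = 0.02.

## Numerical choices and degenerate inputs

Threshold crossings are linearly interpolated (sub-frame resolution at
100 Hz where one frame is 10 ms). When smoothing pulls a sharp peak below
a shallow APD threshold, repolarization to that level is treated as
immediate rather than unresolved. Constant traces cannot be normalized
(error); zero segmented beats is a valid result everywhere downstream;
fewer than 3 APDs make the Poincaré index "not evaluable" rather than an
error in classification. Chi-squared tables with a degenerate margin
(identical all-yes or all-no groups) return p = 1. The detrend exponential
fit falls back to linear if the nonlinear fit fails to converge.

## Problem sizes in the shipped benchmarks

The acceptance suite uses the sizes its checks state: 100 beats for APD
recovery, 200 event + 200 clean traces for detector calibration, 10,000
null simulations for the Dunnett calibration, 50 random panels for the LOD
oracle, and a 24-tissue cohort for the end-to-end dose-escalation recovery.
The cohort default elsewhere stays at 7 tissues (the protocol's cohort
size); 24 is used in that one benchmark because it asserts strict
monotonicity of a *sampled* incidence curve, and at n = 7 adjacent binomial
draws would violate monotonicity in a few percent of seeds even with a
perfect analysis. The 95% recovery band combines the noise-propagated APD
ratio SD (per tissue, averaged, divided by √n) with a fixed 1% allowance
for discretization effects that do not average out across tissues.

## Known limitations

Single-pixel (mean-ROI) analysis only — no conduction or activation maps;
no contractility/motion metrics; EAD/DAD amplitudes below ~5% of beat
amplitude are undetectable at this noise level and frame rate, and event
amplitude is only accurate to ±3% of beat amplitude; the weak-vs-arrhythmic
precedence means a tissue that is both weak and arrhythmic is counted as
weak; Fridericia correction assumes the cube-root rate law, which is a
convention, not a fitted model.
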