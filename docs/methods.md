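# Methods

This note documents the models, rules and design choices implemented in
`walkstress`, in the order data flows through the pipeline, together
with what the synthetic benchmark does and does not establish.

## Signal model and preprocessing

**EDA (4 Hz, µS).** The skin conductance signal is modeled as a slowly
drifting tonic level plus phasic skin conductance responses (SCRs). Both
the generator and the smoother use the biexponential Bateman shape
h(t) = e^(−t/τ₁) − e^(−t/τ₂) with the conventional sudomotor constants
τ₁ = 2 s, τ₂ = 0.75 s (peak-normalized in the generator; unit-sum as a
12-sample FIR smoothing kernel at 4 Hz). Smoothing is applied as a
causal convolution with left reflect padding: a unit impulse reproduces
the kernel in place, so response onsets are not shifted. Trips are
screened with three rules — mean EDA below 0.01 µS, zero detected SCRs,
or more than 25 SCRs per minute. The rate rule is interpreted per
minute; a per-trip total would make the screen depend on trip length.

**SCR detection.** The tonic estimate (SCL) is a 4 s rolling median of
the smoothed signal; peaks of the phasic residual locate candidate
responses. Because a centered median tracks a monotone rise almost
exactly, the residual understates amplitudes, so the event amplitude is
measured on the conductance itself: peak value minus the preceding
trough, found by walking back from the peak (keeping the running
minimum, stopping when values climb clearly above it, horizon 10 s).
Events below 0.01 µS — the common minimum SCR amplitude — are dropped.
On an isolated injected 0.5 µS response the detected amplitude is
≈ 0.42 µS (smoothing attenuation) with onset error ≤ 0.25 s.

**IMU (50 Hz, g).** Each axis passes a fourth-order zero-phase
Butterworth low-pass at 4 Hz. Interruptions (non-walking stretches) are
detected on the mean-removed acceleration magnitude with an STFT (3 s
Hann window, 50 % overlap): a frame is inactive when its one-sided
amplitude spectrum peaks below 0.5 within the 0.5–3 Hz gait band, and a
contiguous inactive run of at least 15 s becomes an interruption
interval. The amplitude is scaled so a sinusoid of amplitude A (in g)
reads ≈ A; the band, overlap and scaling were fixed once to make the
0.5 threshold unit-stable, and all three are exposed in configuration.
Window-edge leakage makes detected boundaries accurate to about one hop
(±1.5–3 s), which the recovery tests allow for. Visual-inspection steps
of field protocols are replaced by these deterministic rules (a
plot-export flag in the CLI supports manual review); a human-in-the-loop
step cannot be tested.

**BVP (64 Hz).** The published cutoff pair "0.4–0.6 Hz and 4–8 Hz" is
read as the transition edges of one cardiac band-pass: the implementation
passes ≈ 0.6–4 Hz (36–240 bpm) with a second-order zero-phase
Butterworth. Motion-artifact bursts are then suppressed by a discrete
wavelet transform (db4, 5 levels) with soft universal thresholding of
the detail coefficients (noise scale from the finest level's MAD).
Systolic peaks are detected with a 0.27 s minimum inter-beat interval
(≈ 220 bpm) and a height gate at half the 90th-percentile peak height,
which rejects diastolic secondary peaks. Instantaneous rate 60/IBI is
assigned at inter-beat midpoints, beats outside 30–220 bpm are dropped,
and a centered 5-beat moving average (a configurable width; no published
value exists) refines the series. On artifact-free synthetic pulse waves
the mean rate is recovered to well under 1 bpm.

## Features

Six families feed the spatial stage: SCL, EDA PSC, stride time, IMU PSC,
mean heart rate, BVP PSC; SCR amplitude and frequency additionally feed
the window statistics. Stride time is defined as two successive steps
(alternate heel-strike peaks on the largest-variance axis), emitted at
stride midpoints, with strides inside interruption intervals discarded.

**Bottom-up segmentation.** The saliency features require variable-length
segments. Classical bottom-up merging starts from 2-sample segments and
repeatedly merges the adjacent pair with the smallest increase in total
within-segment squared error until the cheapest merge would exceed a
cost cap. The cap — rather than a fixed segment count — preserves the
non-fixed-length character of the method; its default is twice the
series variance, a scale-free choice. On noiseless single-change-point
series the surviving boundary coincides with the exhaustive-search
optimum (verified 100/100 in the acceptance suite).

**PSC (physiological saliency cue).** For segment i with representative
attribute aᵢ (the segment mean) the cue is the distance-weighted
contrast PSC(i) = Σ_{j≠i} wᵢⱼ·|aᵢ − aⱼ|, wᵢⱼ ∝ 1/dᵢⱼ normalized over
j ≠ i, with dᵢⱼ the distance between segment centers in samples. Every
sample inherits its segment's value; a single segment yields an all-zero
cue. The saliency-detection literature admits several contrast forms;
the distance-weighted absolute contrast is the default here and an
unweighted variant is provided (`distance_weighted=False`). The
implementation is checked against an independent brute-force sum to
1e-9. EDA PSC is computed over the smoothed 4 Hz signal; IMU PSC over
the stride-time series and BVP PSC over the heart-rate series, since a
per-segment representative attribute must be comparable across segments
and those series are the representative gait/cardiac attributes.

## Stimulus-anchored statistics

The passage time t₀ of a report is the time of the GPS fix nearest the
reported position (reports farther than 40 m from the route are
excluded). For window length L the nonstimuli value is the feature mean
over [t₀ − L, t₀) and the stimuli value over [t₀, t₀ + L) — reactivity
follows passage, so the post-window carries the effect. Pairs are
excluded when a window crosses the trip boundary, when the stimuli
window overlaps an earlier report's stimuli window (the earlier-t₀
report wins, making exclusion order-independent), or when less than half
of either window is valid after interruption removal. Lengths sweep
5–240 s in 1 s steps.

The linear mixed-effects model y_ij = μ + β·x_ij + u_i + e_ij (subject
random intercept) is fitted by REML with a Wald p-value for β; a
singular fit falls back to pooled OLS with a flag. When between-subject
variance is zero the REML estimate equals the pooled OLS slope to
numerical precision, which the tests assert at 1e-6. Per stimulus type,
Welch's unequal-variance two-sample t-test compares stimuli vs
nonstimuli means at α = 0.05. No multiple-testing correction is applied
across the length grid; the full grid of raw p-values is persisted, and
the reported per-feature length is the smallest L with LME p < 0.05
(the selection rule among significant lengths is otherwise
under-determined, so the grid lets users apply their own).

Calibration on data drawn from the generative model itself: type-I error
0.042 at α = 0.05 over 500 null fits, 95 % Wald-CI coverage 0.96 over
50 replicates of β = 0.5 (30 subjects × 20 pairs).

## Spatial stage

Street centerlines are cut into consecutive POI segments of the chosen
length; a final remainder shorter than half the target merges into the
previous span (street ends are otherwise unspecified), so spans
partition each street exactly. Each segment carries a flat-capped 40 m
buffer. Feature points are z-normalized within each trip before
aggregation — between-subject baselines (tonic level, resting heart
rate) are nuisance information a collective-distress classifier should
not exploit — and assigned to the segment whose centerline is nearest
among the buffers containing the point (ties to the lower segment id,
distances rounded at 1 nm for determinism). Per segment and feature the
mean and SD are kept (12 aggregates over 6 families). A segment is
labeled *stimuli* iff at least one report falls to it under the same
rule.

Gaussian Naive Bayes (features are continuous aggregates) runs under
stratified fivefold cross-validation with a fixed seed; per-class
recalls are pooled over folds and UAR = (recall_stimuli +
recall_nonstimuli)/2 is the headline score, chance 0.5 under any class
imbalance — no resampling or reweighting is applied. Folds stratify at
segment level; the same subject can appear in training and test folds
(as in typical field-study designs), and a subject-grouped mode is
available. Missing aggregates are imputed with the training-fold mean;
segments with no feature at all are dropped. If the minority class is
smaller than the fold count, the fold count shrinks to keep both
classes in every fold (warned).

## Synthetic benchmark: what it emulates and what it does not

The generator reproduces the statistical structure the analysis relies
on: Poisson background SCRs (3/min) of 0.1–0.4 µS on a drifting ~2 µS
tonic level; quasi-periodic gait at 2 Hz (fundamental amplitude 0.8 g —
a waist-worn vertical oscillation clearly above the 0.5 interruption
threshold — with harmonics and optional zero-motion pauses); a pulse
wave with a raised-cosine systolic peak per beat (sufficient for beat
detection, deliberately not a cardiovascular model); GPS at 1 fix / 3 s
along random non-backtracking walks over a planar street grid. Stimulus
passages (within 15 m of a stimulus on the walked path) inject, after a
2 s delay and for 30 s: `scr_burst_count` extra SCRs of
`extra_scr_amp_uS`, a stride period lengthened by
`stride_slowdown_frac`, and a heart-rate bump of `hr_bump_bpm`. The
30 s effect duration covers the published 5–10 s reactivity onset plus
recovery and corresponds to ≈ 42 m at 1.4 m/s, commensurate with the
40 m segment scale. Reports sit at the true stimulus position plus
isotropic Gaussian error (σ = 5 m), reflecting the known deviation
between actual and reported stimulus locations. One integer seed
determines everything; per-subject and per-trip substreams are spawned
deterministically.

The canonical benchmarks fix the study conditions: *strong-effect* —
30 subjects, 5–10 trips each, 300 s trips, a 40-street grid (100 m
streets), stimulus density 2.5/km, effects (0.5 µS × 3 SCRs, 20 %
slowdown, +8 bpm); *null* — identical but all effects zero. The reduced
sweep configuration (12 subjects, 3–6 trips) keeps the ten-seed
segment-length sweep at desk scale. These sizes are the package's own
desk-scale choices; per-subject trip counts in the field range far
wider.

What passing tests show: the pipeline recovers injected multi-modal
effects end-to-end (UAR ≈ 0.9 at 40 m under the strong benchmark),
behaves at chance under the matched null, and its statistical stage is
calibrated. What they do not show: performance on real recordings —
real EDA has nonstationary tonic dynamics and electrode artifacts, real
gait varies in cadence and amplitude, real stimuli have heterogeneous
and lagged effects (heart rate especially), and reporting behaviour is
far noisier than a Gaussian position error. Absolute synthetic UAR
values therefore say nothing about field accuracy; the value of the
benchmark is in the *contrasts* (strong vs null, combined vs single
modality, trend over segment length) and in the exact primitive-level
oracles.

## Numerical and degenerate-input conventions

Half-open time windows [a, b) on seconds since trip start; channels are
trimmed to their common span at load (alignment is idempotent; overlap
< 60 s flags the trip unusable). Resampling is never performed — each
extractor works at native rate. Interval sets are disjoint, sorted,
merged when closer than one STFT hop. Fewer than 3 detected beats, or a
flat BVP signal, yield an empty heart-rate series with a warning; a
walking bout with fewer than 4 step peaks emits no strides; a constant
series segments to a single segment with zero PSC. Distance ties in
segment assignment break to the lower segment id. Text outputs are
written at full float precision and parsed with round-trip precision,
so write-then-read is bit-exact.

## Known limitations

- The PSC contrast form and the bottom-up stopping rule are documented
  conventions (configurable), not uniquely determined by prior art.
- The equirectangular projection used for WGS84 inputs is adequate at
  neighborhood scale only (sub-meter over a few km).
- Subject-level leakage across CV folds is possible in the default
  (segment-stratified) mode; use the subject-grouped mode to exclude it.
- The generator's stride slowdown does not slow walking speed (cadence
  and speed are decoupled for simplicity), and effect magnitudes are
  free parameters, not calibrated to any field population.
- Heart-rate effects are injected instantaneously; lagged cardiac
  reactivity is not modeled.
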