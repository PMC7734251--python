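# Methods

## Signal model

Gait EMG is modelled per channel as stationary Gaussian noise whose
one-sided power spectrum is a Gaussian bump of width σ = 150 Hz centred at

    cf(F) = center_freq_rest · (1 − κ·F),

truncated to the 60–2000 Hz analysis band, multiplied by a periodic stride
gate. The noise is synthesized directly in the frequency domain (random
complex coefficients scaled by the square root of the target spectrum,
inverse real FFT, exact RMS normalisation per window), so the MPF of a
generated segment equals cf(F) up to band-edge truncation — this is what
makes the generator usable as an analytic oracle for the measurement
chain: with the defaults (`center_freq_rest` = 800 Hz, κ ≤ 0.18, so
cf ≥ 656 Hz) the truncation bias is negligible and the empirical MPF
matches cf within 3 %.

The stride gate is locked to absolute session time (stride rate derived
from belt speed / 0.13 m stride length ≈ 2 strides/s at 16 m/min), with
10-ms raised-cosine ramps. Burst amplitude defaults to 0.5 mV nominal peak
(≈ 2.5 noise SD), matching the ± 0.5 mV scale of intramuscular
gastrocnemius recordings during running. The affected (AF) limb's duty
fraction defaults to 0.35 of the stride; the unaffected (UN) limb's duty
is `duty · (1 + asymmetry)`, so a positive asymmetry produces the
post-stroke pattern of longer UN bursts and a negative symmetry index:
SI = −a/(2+a)·200 % for asymmetry a (a = 0.4 ↔ SI ≈ −33 %).

Two noise floors are distinct by design: the inter-burst electrode floor
inside a gait recording (0.005 mV RMS, flat in band) and the resting
segment used for thresholding (0.010 mV RMS total). The difference
represents the low-level postural muscle tone a resting animal maintains
on top of pure electrode noise; it is also what makes the resting
mean + 1.5 SD rule a conservative burst threshold — with a smoothed
envelope, 1.5 resting SDs sit only slightly above the resting mean, and a
threshold computed on tone-free noise identical to the gait floor would
chatter on gap noise. Neither floor is characterised by the source
system's published description; both are free parameters fixed here once.

## Fatigue dynamics

The latent fatigue state F ∈ [0, 1] accumulates linearly during running
(`accumulation_rate`, default 1/1000 s⁻¹) and recovers exponentially
during rest (`recovery_tau`, default 60 s). Two parameters suffice to
reproduce both observed morphologies: a monotone rise to a plateau under
forced running, and a sawtooth under closed-loop control. κ (default
0.18) is the maximum fractional MPF compression, so the forced-running
drop rate plateaus near 18 %; with the default accumulation rate the 11 %
threshold is crossed after ≈ 10 min of continuous running and F saturates
at ≈ 16.7 min — both anchored to the reported behaviour of the real
system. A 3-min rest at τ = 60 s leaves e⁻³ ≈ 5 % of the pre-rest state.

Within one 4-s window F is treated as constant at its midpoint value
(quasi-stationary: F changes by ≤ 0.004 per window at the default rate).

Note one small bias this model makes visible: the 20-s baseline itself is
recorded while F is already rising, so the measurable plateau drop rate is
κ(1−F_b)/(1−κF_b) rather than κ exactly (F_b = mean baseline-window F).
At the default accumulation rate F_b ≈ 0.01 and the bias is ≈ 0.2 % of κ;
desk-scale tests that accelerate fatigue keep the accumulation slow enough
during the first 20 s for the same reason.

## Measurement chain

* **Filtering** — fourth-order Butterworth 60–2000 Hz, applied as SOS.
  Offline analysis is zero-phase (forward–backward) so group delay does
  not shift burst onsets; a causal mode mirrors the streaming system.
* **MPF** — Welch PSD on each 4-s window (1-s Hann segments, 50 %
  overlap), spectral integration clipped to the filter band so estimator
  leakage cannot bias the centroid; a raw periodogram is selectable for
  cross-checks. A zero-power window yields NaN (undefined), never 0.
  The controller's online value and the offline replay use the identical
  per-window chain, so replay agreement is exact rather than approximate.
* **Envelope** — 25-ms centered moving average of the rectified signal;
  the window shrinks at the edges instead of padding, so no fabricated
  samples enter threshold or burst statistics. (Whether the original
  system's window was centered or trailing is not documented; centered is
  this package's choice.)
* **Bursts** — maximal runs of envelope ≥ threshold; gaps < 10 ms merged,
  runs < 15 ms discarded (both exposed in config; events shorter than
  that at ≈ 2 strides/s are noise). Intervals are half-open `[onset,
  offset)` in seconds from session start. Detection is verified against a
  brute-force per-sample scan and scores F1 ≥ 0.95 against generator
  ground truth with 30-ms boundary tolerance.
* **Artifacts** — manual visual inspection is replaced by an automated
  surrogate: samples above a clip level (suggested: 3 × the 99.9th
  amplitude percentile of a clean calibration segment) dilated by 50 ms;
  flagged spans are excluded from MPF windows and burst statistics.

## Session control

The controller's native clock is the 4-s MPF window; there is no
sub-window triggering. The baseline is the mean of the first five windows
(20 s) and serves the entire session — after a rest, drop rates are still
referenced to it, which reproduces the observed pattern of post-rest drop
rates re-approaching the threshold from below. Rests are exact on the
simulation clock (180 s, not window-quantised); consecutive triggers are
allowed; belt-stop latency is zero. A session completes when accumulated
treadmill-on time reaches the 30-min dose, so FAT-C and FOR-T deliver
identical dose and speed and differ only in fatigue management. Every log
is auditable: `replay_session` recomputes all windows offline and flags
any trigger below threshold, any missed stop, and any rest without a
matching trigger.

## Outcome trajectories

`simulate_study` emulates group-level recovery shapes, not any specific
published group means: mNSS decays exponentially from an integer day-2
baseline (> 6, the recruitment rule) toward a group asymptote
(CTRL τ = 6 d → 6.5; FOR-T τ = 5 d → 4.5; FAT-C τ = 4.5 d → 2.5, reflecting
the ordering fatigue-controlled < forced < control at day 14), rounded and
clipped to [0, 18], and decomposed into motor/sensory/beam/reflex
subscales respecting their 6/2/6/4 maxima. SI starts near −40 % and rises
linearly at +3 %/day in FAT-C, +0.5 %/day in FOR-T, capped at zero; CTRL
has no SI (no treadmill). Day-2 values are the recruitment measurement
(noise-free). These defaults make the downstream covariate-adjusted group
comparison at n = 11/group detect the FAT-C vs FOR-T difference in ≥ 80 %
of replicates, which is the design's working regime, but the absolute
trajectory levels are illustrative.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: motor-unit structure and superposition,
amplitude non-stationarity within a burst, crosstalk between limbs,
electrode drift and motion artifacts (unless injected), stride-rate
variability, rat non-compliance ("gentle nudges"), dropout/mortality, and
any coupling between signal-level fatigue and behavioural scores beyond
the configured group parameters.

## Statistics

The effect size accompanying every F test is partial eta-squared,
SS_effect/(SS_effect + SS_error) — the conventional companion statistic of
ANOVA/ANCOVA tables. Factorial models use type-III sums of squares with
sum-to-zero contrasts (group sizes become unbalanced under attrition);
ANCOVA fits a single pooled covariate slope with no slope-by-group term;
a constant covariate degenerates to ANOVA with a warning. Normality
screening is a one-sample KS test against a normal with estimated moments
(conservative p-values; adequate for screening). One-way ANOVA across
days within a group treats repeated measures from the same subjects as
independent — this mirrors the analysis battery being modelled and is a
known limitation, not a recommendation; a mixed-effects model would be the
modern alternative and is out of scope.

## Numerical and reproducibility choices

All randomness flows from explicit `numpy.random.Generator` seeds;
per-subject generators derive from the master seed via CRC-32 of the
subject id (stable across runs and execution order), per-session seeds add
the day. Identical (inputs, seed) give byte-identical signals and tables.
Default simulation rate is 5000 Hz (Nyquist-valid for the 2000-Hz band
edge) with 40 kHz supported for acquisition-fidelity runs. EDF export
quantises to 16-bit with the physical range rounded up to the 8-character
header field, so round-trip error is bounded by one quantisation step.

Problem sizes: unit and property tests use 1–6-min sessions with
accelerated fatigue (accumulation 0.005–0.03 s⁻¹) chosen to preserve the
trigger/rest geometry at desk scale; the acceptance suite and the
acceptance script run full 30-min-dose sessions at the default full-scale
parameters; the statistics calibration uses 10,000 null replicates at
n = 11 × 3 groups; power checks use 200 study replicates.

## Known limitations

Besides the generator gaps above: burst-boundary accuracy is limited to
roughly half the envelope window (the threshold crossing of a smoothed
edge); the SI reducer is the per-session mean burst duration (total
duration is implemented and agrees when burst counts are near-equal, but
the original definition is ambiguous); baseline windows are assumed
artifact-free; and the fatigue state is one-dimensional — it cannot
represent differential fatigue of the two limbs within one session.
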