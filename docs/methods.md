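# Methods

This note documents the models, parameter choices and numerical conventions
behind `circawear`, and what the synthetic-data tests do and do not show
about real recordings.

## The synthetic cohort

The generator (`circawear.cohort`) produces per-subject-day streams at the
device's native geometry: tri-axial acceleration at 25 Hz over 08:00–20:00,
dual-channel PPG at 100 Hz and 1 Hz SpO₂ over 00:00–06:00, a sleep diary
(bed time before midnight, wake time after 06:00, so the fixed analysis
windows always apply), and five subjective scale scores.

**Nights.** The cardiac component is a pulse train whose pulse-to-pulse
(PP) intervals are modulated by a low-frequency oscillation at 0.1 Hz and a
respiratory-coupled high-frequency oscillation at the subject's respiratory
rate, plus 2 ms white beat-to-beat jitter. The HF modulation depth follows
a baseline of 55 ms plus a Gaussian bump (σ = 1.2 h) of subject-specific
amplitude centred on the subject's HRV peak hour — the nocturnal HRV peak.
The LF amplitude is √(LF/HF target) times the HF amplitude, scaled by a
calibration constant of 0.78 because linear interpolation of the tachogram
attenuates the HF band more than the LF band (measured on ideal beat
sequences); an Ornstein–Uhlenbeck process (τ = 600 s) multiplies the LF
amplitude through `exp(jitter · OU)` to model sympathovagal instability.
The waveform is a fundamental plus a 0.3-amplitude second harmonic — one
dominant maximum per cycle, an asymmetric upstroke, and no secondary peaks
after band-pass conditioning. A respiratory sinusoid is mixed into the two
PPG channels with gains (0.25, 0.75) against cardiac gains (1.0, 0.55), so
a two-source separation can recover it. SpO₂ is generated directly (the
device computes it in firmware): a slowly wandering baseline (10-min knots)
with trapezoidal desaturation episodes (25% fall, 50% hold, 25% recovery;
duration U(20, 120) s; depth = subject depth + U(0, 1) points, always > 4)
placed as a Poisson process with ≥ 300 s separation, so event boundaries
are analytically known.

**Days.** Per-minute intensity follows a bimodal diurnal template — morning
peak at 08:30, trough at 13:30, evening rebound near 18:00 — multiplied by
lognormal minute noise; "vigorous" minutes (3× intensity) occur with
probability proportional to the subject's high-activity fraction, and
morning minutes are damped with the subject's morning low-activity bias.
The vertical axis carries gravity plus a 1.9 Hz oscillation with the minute
intensity as envelope.

**Group presets.** Subject parameters are drawn from per-group normal
distributions (`GROUP_DEFAULTS`). The `realistic` preset targets published
elderly-cohort summary ranges (control rMSSD ~70–90 ms, LF/HF ~0.6, ODI
~4–5/h, SpO₂ baseline ~98); the MCI arm differs by a flattened HRV peak
(12 vs 55 ms), jittered peak phase, larger LF/HF jitter (0.25 vs 0.05),
more and deeper desaturations, a lower SpO₂ baseline (96.9 vs 98.2), lower
high-activity fraction and a positive morning low-activity bias. The
`separable` preset widens every gap and shrinks within-group spread so
planted contrasts dominate sampling noise on small cohorts; it is the
preset used for end-to-end recovery tests. Scale features are drawn from
group-specific distributions (education 12 ± 3 vs 9 ± 2.5 years, PSQI
5.4 ± 2.8 vs 7.2 ± 4.4, etc.; chronic-disease counts Poisson 0.9 vs 1.6).

All randomness flows from one integer seed through `SeedSequence` children
keyed by (subject, day), so cohorts are byte-identical across calls and
recordings can be generated lazily (a 40-night cohort never needs to be in
memory at once).

**What the generator does not emulate:** motion artifacts coupled between
accelerometer and PPG, posture, sleep staging, realistic PPG morphology
variation, SpO₂ quantization, or inter-night within-subject drift beyond
fresh noise draws. Passing recovery tests therefore shows the pipeline is
correct and sensitive under the stated signal model, not that it is robust
to every failure mode of field data.

## Screening and conditioning

A stream is rejected (never an exception) if it fails, in order: coverage
of its analysis window (daytime 08:00–20:00, night 00:00–06:00 —
`outside_window`/`truncated`), more than 50% zero-or-missing samples
(`null_signal`), or SD below 1e-4 of full scale on every channel
(`flat_signal`).

Acceleration is band-passed with a zero-phase 4th-order Butterworth filter.
The nominal 15 Hz upper corner exceeds the 12.5 Hz Nyquist limit at 25 Hz
sampling, so the corner is clipped to 0.45 × rate (11.25 Hz) with a
warning — this honours the filter's intent without an unstable design.
Zero-phase (forward–backward) application keeps features time-aligned
across streams.

EEMD denoising adds 100 white-noise realisations (SD = 0.2 × signal SD;
the ensemble count and noise scale are explicit defaults), decomposes each
by cubic-spline sifting (Cauchy stopping criterion 0.2, ≤ 10 sifts per
mode), averages IMFs across the ensemble by index, and reconstructs from
the averaged IMFs whose periodogram peak falls in a physiological band —
cardiac (0.66–3.0 Hz, 40–180 bpm for an elderly cohort) and/or respiratory
(0.1–0.5 Hz). EEMD cost grows super-linearly with signal length and
linearly with the ensemble count, so the cohort-scale indicator pipeline
defaults to an equivalent zero-phase Butterworth cardiac band-pass
(`denoise="bandpass"`); the EEMD path is exercised and validated on short
segments (tone recovery at 0 dB SNR, two-tone reconstruction error < 15%).

## Daytime activity definitions

Counts: vertical acceleration resampled to 30 Hz; per 1-s block of 30
samples, count = round(Σ clip(max(|a| − 0.05 g, 0), 0, 2 g) / 0.01 g).
The dead-band, ceiling and resolution are configurable — count scales are
device-specific and these constants are this repository's definition.
PA(minute) = Σ of 60 per-second counts. Non-wear: maximal zero-PA runs
strictly longer than 90 min. Activity states use the 40th/70th/90th
percentiles (linear interpolation) of the pooled wear-minute PA of the
analysis set — pooling makes states comparable across subjects (a
per-subject variant is a one-line change at the call site). Intervals are
half-open with ties going upward at p90 (PA ≥ p90 is "high", so the
90–100% band includes the maximum; a degenerate all-equal pool classifies
every minute "high" by the same branch order). Rhythm curves are compressed
by medians of 5-point blocks (720 → 144 points; a trailing partial block
takes its own median) and summarised as per-period means, min–max
normalised per record to [0, 1] when comparability across records is
needed — the normalisation convention is a repository interpretation.

## Nocturnal indicators

Pulse peaks: local maxima above a rolling threshold (60th percentile per
60-s block) with a 300 ms refractory period; PP intervals gated to
(250, 3000) ms, removals logged. Per 30-s window: HR = 60000 / mean PP;
rMSSD = √(mean of squared successive PP differences), needing ≥ 3
intervals; SpO₂ = in-window mean. LF power (0.04–0.15 Hz) is not estimable
from 30 s of data, so spectral indicators are computed on a 5-min trailing
buffer ending at each window, keeping the 30-s output grid — standard HRV
practice. The tachogram is resampled at 4 Hz by linear interpolation;
band power is the integral of the one-sided periodogram over the band
(a unit in-band sinusoid yields A²/2 = 0.5). Respiratory rate whitens the
two-channel window and rotates to maximise non-Gaussianity (the excess
kurtosis of any rotation of whitened data is a closed form in the joint
4th-order moments, so the scan is exact and cheap); the separated
component's globally dominant frequency must fall in 0.1–0.5 Hz, else a
band-filtered single-channel fallback is used (logged).

Desaturations follow the ODI4 convention: the baseline is the running
maximum over the preceding 120 s; an event starts when SpO₂ drops strictly
more than 4 percentage points (absolute points, not relative percent) below
baseline; the baseline freezes at event start; the event ends on recovery
to within 2 points or at a 300-s cap. ODI counts events starting in each
hour; hourly band occupancy (≥ 95 / 90–95 / < 90) partitions all samples.
Hours without events report OD duration 0 rather than missing, so the
oxygen feature group of an event-free night is all-zero rather than
imputed.

Z-scoring always takes externally supplied (mean, SD) — per night for
descriptive curves, training-fold-only in the modelling path — and never
refits on evaluation data.

## Feature table

36 sliding windows (20-min length, 10-min stride) start at 00:00, 00:10,
…, 05:50; each is intersected with the night, so the final window is
truncated to 10 min. This is the only start convention that both covers
the night and yields 36 windows (only 35 full 20-min windows fit in 6 h).
7 indicator groups × 36 medians + the 28-feature oxygen group (ODI, OD
duration, %SpO₂ ≥ 95, %SpO₂ 90–95 — six hourly values and the whole-night
mean each) = 280 physiological features. The oxygen group uses the 90–95%
band as its fourth indicator, which closes the 4 × 7 = 28 arithmetic.
Missing values are imputed with training-fold column medians inside the
evaluation loop. Modes: `P` (280 columns, one row per record), `P+S`
(+ 5 scale columns), `S` (5 scale columns, exactly one row per subject).

## Selection and evaluation

Per feature group, a random forest is fit under stratified 10-fold CV at
the record level and permutation importance (10 repeats) is computed on
each test fold; importances average over repeats and folds. Note the
stratification is at the record level although subjects contribute several
records — selection mirrors the analysis sequence it reproduces and runs
once on the full matrix before LOSO; the subject-held-out evaluation that
follows is the leakage-safe stage. The top-5 per group become candidates
(ties break by column order) and candidates strictly above the candidate
median are retained: 40 distinct candidate importances yield exactly 20
features; an all-tied candidate set retains none (warned).

Evaluation is leave-one-subject-out with pooled held-out probabilities —
single-subject test folds are often single-class, so per-fold AUC is
undefined and pooling is the coherent aggregate. Grid search maximises
pooled AUC (default grid: 50–300 learners × learning rate 0.01–0.1 × depth
2–5; ties break by grid order). Thresholded metrics use a fixed 0.5 cut
with MCI as positive class; importances come from a final all-data refit,
rescaled so the top feature is 100. Every per-fold fit (imputation
medians, z-scoring, the model) uses training rows only and records its
provenance for auditing.

Two numerical choices matter here. First, all fits use class-balanced
sample weights: each LOSO fold's training prior shifts away from the
held-out subject's class, boosted models track that prior, and pooled over
folds this manufactures an anti-correlation between scores and labels;
balancing pins the no-information prediction at 0.5 per fold. Second,
XGBoost runs with `tree_method="exact"`, because histogram binning places
split thresholds on training data points and misassigns held-out values
that fall inside the class gap on small matrices.

Even so, pooled leave-one-out AUC is known to be pessimistically biased at
small sample sizes (the held-out subject's feature neighbourhood is
depleted from its own class). The no-signal control therefore reports the
*mean* pooled AUC over 12 subject-level label permutations using a fixed
mid-capacity probe model with stochastic subsampling
(100 trees, rate 0.05, depth 2, subsample 0.8 — subsampling decorrelates
fits from the leave-one-out structure and centres the null near 0.5);
values slightly below 0.5 remain expected.

## Group statistics

Categorical contrasts use the Pearson chi-square on 2×2 counts without
continuity correction — this convention exactly reproduces the published
worked statistics (5.055 for chronic-disease burden, 0.629 for sex),
whereas the corrected statistic does not. Continuous per-period summaries
use the two-sided Mann-Whitney U with normal approximation, tie correction
and continuity correction; z is signed by the first group's rank-sum
deficit. Exact enumeration (via scipy) serves only as a small-n test
oracle. Per-period comparisons are reported unadjusted for multiplicity,
matching per-period significance flags in this analysis style. The
implementation's type-I error at α = 0.05 is 0.044–0.045 over 2000 null
simulations at n = 30/30.

## Problem sizes used in the checks

End-to-end recovery runs on a `separable` cohort of 20 subjects per arm
with 2 nights each (80 records), a reduced 2×2×2 hyperparameter grid, and
selection at 5 permutation repeats with 50-tree forests; these sizes keep
the whole suite comfortably reproducible on a single CPU while leaving the
AUC criterion far from its boundary. Parameter recovery (HR ± 1 bpm,
RR ± 1 breath/min, ODI exact) uses one noise-free night per arm. The
acceptance script (`scripts/acceptance.py`) re-derives all of these from
the seed it is given.

## Known limitations

- The count mapping constants are repository definitions, not a device
  calibration; absolute PA values are only meaningful relative to the
  pooled percentile thresholds.
- LF/HF absolute levels depend on tachogram interpolation; the generator
  is calibrated so *measured* ratios land on target, and the MCI arm's
  measured ratio sits slightly below its nominal parameter because the
  jitter enters multiplicatively.
- The EEMD path is validated on segments, not whole nights; whole-night
  denoising uses the band-pass route.
- S-mode classification with one row per subject leaves very few rows at
  synthetic-cohort sizes; it is exercised structurally, not as a
  performance claim.
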